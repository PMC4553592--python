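"""End-to-end run configuration and orchestration.

A run takes frames (from disk or the synthetic generator), detects flicker
events with the interval filter, masks shimmering episodes and the mouth
zone, pools the trigger registry into per-phase trigger-site maps, and
compiles rate/intensity cohort statistics per experimental phase.  All
randomness flows from one top-level seed; rerunning an identical config
yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from . import io as nio
from .assessment_grid import (AssessmentGrid, RegionMask, apply_mask, build_grid,
                              polygon_mask)
from .cohort_stats import (bin_rate_classes, build_rate_intensity_table,
                           class_midpoints, cohort_difference, fit_exponential,
                           relf_metrics, spearman_rate_intensity)
from .flicker_events import (EventFilterConfig, activity_fraction, detect_events_grid,
                             detect_shimmer_episodes, filter_events)
from .motion_field import square_series, to_luma
from .synthetic_nest import (CohortSpec, MouthZoneSpec, SceneConfig, WaveSpec,
                             render_square_series, write_ground_truth)
from .trigger_map import (TriggerEntry, TriggerRegistry, partition_cohorts,
                          pool_trigger_activity, scale_map)

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """Parsed run configuration (see ``RunConfig.from_yaml`` for the schema)."""

    output_dir: Path
    seed: int = 0
    fps: float = 50.0
    square_px: int = 12
    frames_path: Optional[Path] = None
    scene: Optional[SceneConfig] = None
    detect: EventFilterConfig = field(default_factory=EventFilterConfig)
    shimmer_frac_threshold: float = 0.15
    shimmer_min_len_frames: int = 3
    mask_squares: Tuple[Tuple[int, int], ...] = ()
    mask_polygon: Optional[Tuple[Tuple[float, float], ...]] = None
    registry_path: Optional[Path] = None
    phases: Optional[Dict[str, Tuple[int, int]]] = None
    write_frames: bool = False
    reducer: str = "mean"

    def __post_init__(self) -> None:
        if self.scene is None and self.frames_path is None:
            raise ValueError("config needs either a synthetic 'scene' or a 'frames' path")
        if self.phases:
            intervals = sorted(self.phases.values())
            for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
                if not a0 < a1 or b0 < a1:
                    raise ValueError("phase intervals must be non-overlapping, start < end")
            last = intervals[-1]
            if not last[0] < last[1]:
                raise ValueError("phase intervals must satisfy start < end")

    @classmethod
    def from_yaml(cls, path: PathLike, seed: Optional[int] = None) -> "RunConfig":
        """Load a run config from YAML.

        Top-level keys: ``output_dir``, ``seed``, ``fps``, ``square_px``,
        ``frames`` (path) or ``scene`` (SceneConfig fields; cohorts/waves/
        mouth_zone as nested mappings), ``detect`` (threshold,
        max_duration_frames, min_gap_s), ``shimmer`` (frac_threshold,
        min_len_frames), ``mask_squares``, ``mask_polygon``, ``registry``
        (path), ``phases`` (name -> [start, end) frame interval),
        ``write_frames``, ``reducer``.
        """
        raw = nio.load_yaml(path)
        base = Path(path).parent
        if seed is None:
            seed = int(raw.get("seed", 0))
        fps = float(raw.get("fps", 50.0))
        square_px = int(raw.get("square_px", 12))

        scene = None
        if "scene" in raw:
            scene = _scene_from_dict(raw["scene"], fps=fps, square_px=square_px,
                                     seed=seed)
            fps, square_px = scene.fps, scene.square_px

        det = raw.get("detect", {})
        detect = EventFilterConfig(
            detect_threshold=float(det.get("threshold", 2.0)),
            max_duration_frames=int(det.get("max_duration_frames", 3)),
            min_gap_s=float(det.get("min_gap_s", 1.0)),
            fps=fps)
        shim = raw.get("shimmer", {})
        phases = None
        if "phases" in raw:
            phases = {str(k): (int(v[0]), int(v[1])) for k, v in raw["phases"].items()}

        def _resolve(p: Optional[str]) -> Optional[Path]:
            if p is None:
                return None
            p = Path(p)
            return p if p.is_absolute() else base / p

        return cls(
            output_dir=_resolve(raw.get("output_dir", "nestflick_out")),
            seed=seed, fps=fps, square_px=square_px,
            frames_path=_resolve(raw.get("frames")),
            scene=scene, detect=detect,
            shimmer_frac_threshold=float(shim.get("frac_threshold", 0.15)),
            shimmer_min_len_frames=int(shim.get("min_len_frames", 3)),
            mask_squares=tuple((int(r), int(c)) for r, c in raw.get("mask_squares", [])),
            mask_polygon=tuple((float(x), float(y)) for x, y in raw["mask_polygon"])
            if "mask_polygon" in raw else None,
            registry_path=_resolve(raw.get("registry")),
            phases=phases,
            write_frames=bool(raw.get("write_frames", False)),
            reducer=str(raw.get("reducer", "mean")),
        )


def _scene_from_dict(d: dict, fps: float, square_px: int, seed: int) -> SceneConfig:
    cohorts = tuple(
        CohortSpec(squares=tuple((int(r), int(c)) for r, c in c_.get("squares", [])),
                   flicker_rate=float(c_.get("flicker_rate", 0.1)),
                   amplitude_mean=float(c_.get("amplitude_mean", 8.0)),
                   amplitude_sd=float(c_.get("amplitude_sd", 1.5)),
                   duration_probs=tuple(c_.get("duration_probs", (0.5, 0.3, 0.2))),
                   min_gap_s=float(c_.get("min_gap_s", 1.2)))
        for c_ in d.get("cohorts", []))
    waves = tuple(
        WaveSpec(trigger_square=tuple(w["trigger_square"]),
                 start_frame=int(w["start_frame"]),
                 speed=float(w.get("speed", 1.0)),
                 participation_prob=float(w.get("participation_prob", 0.9)),
                 flip_amplitude=float(w.get("flip_amplitude", 12.0)),
                 max_radius=w.get("max_radius"))
        for w in d.get("waves", []))
    mouth = None
    if "mouth_zone" in d and d["mouth_zone"]:
        mz = d["mouth_zone"]
        mouth = MouthZoneSpec(squares=tuple((int(r), int(c)) for r, c in mz["squares"]),
                              amplitude=float(mz.get("amplitude", 6.0)))
    return SceneConfig(
        grid_rows=int(d["grid_rows"]), grid_cols=int(d["grid_cols"]),
        n_frames=int(d["n_frames"]),
        square_px=int(d.get("square_px", square_px)),
        fps=float(d.get("fps", fps)),
        background_lum=int(d.get("background_lum", 140)),
        bee_lum=int(d.get("bee_lum", 110)),
        noise_sd=float(d.get("noise_sd", 0.5)),
        mouth_zone=mouth, cohorts=cohorts, waves=waves,
        seed=int(d.get("seed", seed)))


def _phase_of_frame(frame: int, phases: Dict[str, Tuple[int, int]]) -> Optional[str]:
    for name, (start, end) in phases.items():
        if start <= frame < end:
            return name
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> detect -> map -> analyze; write all outputs.

    Returns the summary dictionary that is also written to
    ``<output_dir>/summary.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: per-square Δlum series -------------------------------
    gt = None
    if config.scene is not None:
        scene = config.scene
        if config.write_frames:
            from .synthetic_nest import iter_frames
            frames, gt = iter_frames(scene)
            nio.write_frames(frames, out / "frames")
            series, _ = render_square_series(scene, reducer=config.reducer)
        else:
            series, gt = render_square_series(scene, reducer=config.reducer)
        grid = scene.grid
        write_ground_truth(gt, out / "ground_truth.csv")
    else:
        if not Path(config.frames_path).exists():
            raise FileNotFoundError(f"frames path missing: {config.frames_path}")
        frame_iter = nio.iter_frames_from(config.frames_path)
        first = to_luma(next(frame_iter))
        grid = build_grid(first.shape, config.square_px)

        def _chain():
            yield first
            yield from frame_iter
        series = square_series(_chain(), grid, reducer=config.reducer)

    n_diff = series.shape[0]
    n_frames = n_diff + 1

    # ---- stage 2: masks, episodes, events ------------------------------
    masks: List[RegionMask] = []
    mask_sqs = set(config.mask_squares)
    if config.scene is not None and config.scene.mouth_zone is not None:
        mask_sqs |= set(config.scene.mouth_zone.squares)
    if mask_sqs:
        masks.append(RegionMask(excluded=frozenset(mask_sqs), label="mouth_zone"))
    if config.mask_polygon:
        masks.append(polygon_mask(grid, config.mask_polygon))
    active = apply_mask(grid, masks)

    frac = activity_fraction(series, config.detect.detect_threshold,
                             active_squares=active)
    episodes = detect_shimmer_episodes(frac,
                                       frac_threshold=config.shimmer_frac_threshold,
                                       min_len_frames=config.shimmer_min_len_frames,
                                       first_frame_index=1)
    events = detect_events_grid(series, config.detect, first_frame_index=1)
    events = filter_events(events, episodes, active)

    nio.write_events_csv(events, out / "events.csv")
    nio.write_episodes_csv(episodes, out / "episodes.csv")

    # ---- stage 3: trigger registry and per-phase maps ------------------
    phases = config.phases or {"all": (0, n_frames)}
    if config.registry_path is not None:
        registry = nio.read_registry_csv(config.registry_path)
    elif gt is not None:
        entries = []
        for wave_id, sq, start in gt.trigger_registry:
            phase = _phase_of_frame(start, phases) or "all"
            entries.append(TriggerEntry(wave_id=wave_id, phase_label=phase, source=sq))
        registry = TriggerRegistry(tuple(entries))
    else:
        registry = TriggerRegistry(())
    nio.write_registry_csv(registry, out / "registry.csv")

    # ---- stage 4: per-phase cohort statistics --------------------------
    summary: dict = {
        "n_frames": int(n_frames), "fps": config.fps,
        "grid": {"rows": grid.rows, "cols": grid.cols, "square_px": grid.square_px},
        "n_active_squares": len(active),
        "n_events_total": len(events),
        "n_shimmer_episodes": len(episodes),
        "n_registered_triggers": len(registry),
        "phases": {},
    }
    if gt is not None and gt.clipped:
        summary["luminance_clipped"] = True

    for name, (start, end) in phases.items():
        phase_reg = registry.for_phase(name) if registry.phases() else registry
        pooled = pool_trigger_activity(phase_reg, grid, phase_label=None)
        scaled = scale_map(pooled)
        partition = partition_cohorts(pooled, active)
        nio.write_matrix_csv(pooled.activity, out / f"trigger_activity_{name}.csv")
        nio.write_heatmap_png(scaled, out / f"trigger_activity_{name}.png")

        phase_events = [e for e in events if start <= e.onset_frame < end]
        t_ref = (end - start) / config.fps
        records = build_rate_intensity_table(phase_events, partition, t_ref,
                                             phase_label=name)
        records.to_csv(out / f"records_{name}.csv", index=False)
        table = bin_rate_classes(records)
        table.to_csv(out / f"rate_classes_{name}.csv", index=False)

        flick_squares = {e.square for e in phase_events}
        relf = relf_metrics(flick_squares, partition, len(active)) if active else None

        fits: Dict[str, Optional[dict]] = {}
        for cohort in ("ts", "nts"):
            sub = table[(table["cohort"] == cohort) & (table["mean_fi"] > 0)]
            if len(sub) >= 2:
                fit = fit_exponential(class_midpoints(sub), sub["mean_fi"].to_numpy())
                fits[cohort] = {"a": fit.a, "b": fit.b, "r_squared": fit.r_squared,
                                "n_points": fit.n_points}
            else:
                fits[cohort] = None

        nonzero = records[records["rate_hz"] > 0]
        spearman = None
        if len(nonzero) >= 3 and nonzero["rate_hz"].nunique() > 1 \
                and nonzero["intensity_fi"].nunique() > 1:
            rho, p = spearman_rate_intensity(nonzero["rate_hz"].to_numpy(),
                                             nonzero["intensity_fi"].to_numpy())
            spearman = {"rho": rho, "p_value": p}

        comparison = None
        if {"ts", "nts"} <= set(table["cohort"].unique()):
            comp = cohort_difference(table)
            comparison = {"n_positive": comp.n_positive, "n_negative": comp.n_negative,
                          "chi2": comp.chi2, "p_value": comp.p_value}

        summary["phases"][name] = {
            "frames": [int(start), int(end)],
            "t_ref_s": t_ref,
            "n_events": len(phase_events),
            "n_ts_squares": len(partition.ts_squares),
            "n_nts_squares": len(partition.nts_squares),
            "max_trigger_activity": pooled.max_activity,
            "relf": None if relf is None else {
                "total": relf.relf_total, "ts": relf.relf_ts, "nts": relf.relf_nts},
            "exp_fits": fits,
            "spearman": spearman,
            "cohort_comparison": comparison,
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    provenance = {
        "nestflick_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "detect": {"threshold": config.detect.detect_threshold,
                   "max_duration_frames": config.detect.max_duration_frames,
                   "min_gap_s": config.detect.min_gap_s, "fps": config.detect.fps},
        "shimmer": {"frac_threshold": config.shimmer_frac_threshold,
                    "min_len_frames": config.shimmer_min_len_frames},
        "phases": {k: list(v) for k, v in phases.items()},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return summary
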