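"""Synthetic nest videos with exact ground truth.

No public video footage of Giant Honey Bee nests exists for this kind of
analysis, so every downstream stage is exercised against synthetic frame
stacks whose statistical structure mirrors what the pipeline assumes:

* each test square holds one bee, rendered as a filled ellipse;
* flickers are 1-3-frame luminance transients of a single bee, generated by
  a renewal process (exponential inter-event times shifted above a minimum
  gap, reflecting the > 1 s repetition interval of natural flickering);
* shimmering waves are radial cascades of single-frame abdomen flips
  expanding from a trigger square at constant speed (Chebyshev distance),
  with Bernoulli participation of the reached bees;
* the mouth zone shows sustained motion on every frame (as fanning and
  foraging traffic does), which the interval filter must reject;
* additive Gaussian sensor noise, 8-bit quantization with saturation.

An event of duration d must raise the per-square mean |Δlum| above
threshold on exactly d difference frames.  A plain luminance step would
show up on only two difference frames (rise and fall), so the renderer
instead *toggles* the bee ellipse between two luminance postures on each of
the d event frames.  A consequence faithful to real abdomen posture is that
odd-duration events leave the bee in the flipped posture; the renderer
picks the toggle direction that stays inside the 8-bit range and flags
clipping when that is impossible.

Ground-truth amplitudes are re-recorded as the *realized* per-square mean
|Δlum| after integer quantization of the pixel step, so detection oracles
compare against exactly what is on screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .assessment_grid import AssessmentGrid
from .flicker_events import FlickerEvent
from .trigger_map import TriggerEntry, TriggerRegistry

Square = Tuple[int, int]

EVENT_KINDS = ("flicker", "wave_flip", "sustained")


# --------------------------------------------------------------------------
# Scene specification


@dataclass(frozen=True)
class CohortSpec:
    """A set of squares sharing one flicker regime.

    ``flicker_rate`` is the target long-run rate per square (events/s);
    amplitudes are the per-square mean |Δlum| of single events, drawn
    normally (floored at 0.5); ``duration_probs`` weight durations 1-3
    frames; ``min_gap_s`` is the enforced minimum between event onsets on
    one square.
    """

    squares: Tuple[Square, ...]
    flicker_rate: float = 0.1
    amplitude_mean: float = 8.0
    amplitude_sd: float = 1.5
    duration_probs: Tuple[float, float, float] = (0.5, 0.3, 0.2)
    min_gap_s: float = 1.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "squares", tuple(tuple(s) for s in self.squares))
        if self.flicker_rate < 0:
            raise ValueError("flicker_rate must be >= 0")
        if self.amplitude_mean <= 0 or self.amplitude_sd < 0:
            raise ValueError("amplitude parameters invalid")
        if len(self.duration_probs) != 3 or abs(sum(self.duration_probs) - 1) > 1e-9:
            raise ValueError("duration_probs must be 3 probabilities summing to 1")
        if self.min_gap_s < 0:
            raise ValueError("min_gap_s must be >= 0")


@dataclass(frozen=True)
class WaveSpec:
    """One shimmering wave expanding radially from a trigger square."""

    trigger_square: Square
    start_frame: int
    speed: float = 1.0  # squares per frame (Chebyshev metric)
    participation_prob: float = 0.9
    flip_amplitude: float = 12.0
    max_radius: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trigger_square", tuple(self.trigger_square))
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not 0 <= self.participation_prob <= 1:
            raise ValueError("participation_prob must lie in [0, 1]")
        if self.flip_amplitude <= 0:
            raise ValueError("flip_amplitude must be positive")


@dataclass(frozen=True)
class MouthZoneSpec:
    """Squares with sustained (every-frame) motion, e.g. fanning traffic."""

    squares: Tuple[Square, ...]
    amplitude: float = 6.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "squares", tuple(tuple(s) for s in self.squares))
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class SceneConfig:
    """Full specification of a synthetic nest video."""

    grid_rows: int
    grid_cols: int
    n_frames: int
    square_px: int = 12
    fps: float = 50.0
    background_lum: int = 140
    bee_lum: int = 110
    noise_sd: float = 0.5
    mouth_zone: Optional[MouthZoneSpec] = None
    cohorts: Tuple[CohortSpec, ...] = ()
    waves: Tuple[WaveSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cohorts", tuple(self.cohorts))
        object.__setattr__(self, "waves", tuple(self.waves))
        if self.grid_rows < 3 or self.grid_cols < 3:
            raise ValueError("grid must be at least 3x3")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.square_px < 3:
            raise ValueError("square_px must be >= 3 (the bee ellipse needs pixels)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0 <= self.bee_lum <= 255 or not 0 <= self.background_lum <= 255:
            raise ValueError("luminances must be 8-bit")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

        def _check(sq: Square, what: str) -> None:
            r, c = sq
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise ValueError(f"{what} square {sq} outside grid")

        if self.mouth_zone is not None:
            for sq in self.mouth_zone.squares:
                _check(sq, "mouth-zone")
        for cohort in self.cohorts:
            for sq in cohort.squares:
                _check(sq, "cohort")
        for w in self.waves:
            _check(w.trigger_square, "wave trigger")

    @property
    def grid(self) -> AssessmentGrid:
        return AssessmentGrid(rows=self.grid_rows, cols=self.grid_cols,
                              square_px=self.square_px)

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return (self.grid_rows * self.square_px, self.grid_cols * self.square_px)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class GTEvent:
    """One ground-truth motion event (amplitude = realized per-square mean |Δlum|)."""

    square: Square
    onset_frame: int
    duration_frames: int
    amplitude: float
    kind: str
    wave_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}")
        self.square = tuple(self.square)


@dataclass
class GroundTruth:
    """Exact event log and trigger registry of a synthetic scene."""

    events: List[GTEvent]
    trigger_registry: List[Tuple[str, Square, int]]  # (wave_id, square, start_frame)
    clipped: bool = False

    def flickers(self) -> List[GTEvent]:
        return [e for e in self.events if e.kind == "flicker"]

    def flicker_squares(self) -> set:
        return {e.square for e in self.flickers()}

    def to_registry(self, phase_label: str = "all") -> TriggerRegistry:
        return TriggerRegistry(tuple(
            TriggerEntry(wave_id=w, phase_label=phase_label, source=sq)
            for w, sq, _ in self.trigger_registry))


# --------------------------------------------------------------------------
# Stochastic event sampling


def simulate_flicker_process(rate: float, min_gap_s: float, n_frames: int,
                             fps: float,
                             seed: Union[int, np.random.Generator, None] = None,
                             ) -> List[int]:
    """Sample flicker onset frames from a gap-enforced renewal process.

    Inter-event times are ``min_gap_s + Exponential(mean = 1/rate - min_gap_s)``
    so that the long-run rate converges to ``min(rate, 1/min_gap_s)`` and
    consecutive onsets are always more than ``min_gap_s * fps`` frames apart.
    Returns sorted onset frame indices in ``[0, n_frames)``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if fps <= 0:
        raise ValueError("fps must be positive")
    if min_gap_s < 0:
        raise ValueError("min_gap_s must be >= 0")
    if rate == 0 or n_frames <= 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_excess = max(1.0 / rate - min_gap_s, 1e-9)
    duration_s = n_frames / fps
    gap_frames = int(math.floor(min_gap_s * fps))
    onsets: List[int] = []
    t = rng.exponential(1.0 / rate)  # first arrival: no preceding event
    while t < duration_s:
        f = int(t * fps)
        if onsets and f <= onsets[-1] + gap_frames:
            # the continuous interval is legal (> min_gap by construction) but
            # quantized onto an inadmissible frame: move to the first legal one
            f = onsets[-1] + gap_frames + 1
        if f < n_frames:
            onsets.append(f)
        t += min_gap_s + rng.exponential(mean_excess)
    return onsets


def _sample_events(config: SceneConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw all ground-truth events (requested, pre-quantization amplitudes)."""
    events: List[GTEvent] = []
    registry: List[Tuple[str, Square, int]] = []
    durations = np.array([1, 2, 3])

    for cohort in config.cohorts:
        for sq in sorted(cohort.squares):
            onsets = simulate_flicker_process(cohort.flicker_rate, cohort.min_gap_s,
                                              config.n_frames, config.fps, rng)
            for onset in onsets:
                if onset < 1:  # motion on frame 0 has no preceding frame
                    continue
                d = int(rng.choice(durations, p=cohort.duration_probs))
                d = min(d, config.n_frames - onset)
                if d < 1:
                    continue
                amp = max(float(rng.normal(cohort.amplitude_mean, cohort.amplitude_sd)), 0.5)
                events.append(GTEvent(square=sq, onset_frame=onset,
                                      duration_frames=d, amplitude=amp,
                                      kind="flicker"))

    for i, wave in enumerate(config.waves):
        wave_id = f"w{i}"
        r0, c0 = wave.trigger_square
        registry.append((wave_id, (r0, c0), wave.start_frame))
        reached: List[Tuple[int, Square]] = []
        for r in range(config.grid_rows):
            for c in range(config.grid_cols):
                dch = max(abs(r - r0), abs(c - c0))
                if wave.max_radius is not None and dch > wave.max_radius:
                    continue
                arrival = wave.start_frame + int(round(dch / wave.speed))
                if 1 <= arrival < config.n_frames:
                    reached.append((dch, (r, c)))
        for dch, sq in sorted(reached):
            if dch > 0 and rng.random() >= wave.participation_prob:
                continue
            arrival = wave.start_frame + int(round(dch / wave.speed))
            events.append(GTEvent(square=sq, onset_frame=arrival,
                                  duration_frames=1, amplitude=wave.flip_amplitude,
                                  kind="wave_flip", wave_id=wave_id))

    if config.mouth_zone is not None:
        for sq in sorted(config.mouth_zone.squares):
            events.append(GTEvent(square=sq, onset_frame=1,
                                  duration_frames=config.n_frames - 1,
                                  amplitude=config.mouth_zone.amplitude,
                                  kind="sustained"))

    events.sort(key=lambda e: (e.square, e.onset_frame, e.kind))
    return GroundTruth(events=events, trigger_registry=registry)


# --------------------------------------------------------------------------
# Rendering


def _ellipse_offsets(square_px: int) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel offsets (ys, xs) of the bee ellipse within one square."""
    s = square_px
    c = (s - 1) / 2.0
    a, b = 0.40 * s, 0.30 * s  # semi-axes: bee body slightly wider than tall
    yy, xx = np.mgrid[0:s, 0:s]
    inside = ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0
    ys, xs = np.nonzero(inside)
    if ys.size == 0:  # degenerate tiny square: use the center pixel
        ys, xs = np.array([s // 2]), np.array([s // 2])
    return ys, xs


def _build_schedule(config: SceneConfig, gt: GroundTruth,
                    ) -> Tuple[Dict[int, List[Tuple[int, int, int]]], bool]:
    """Turn events into per-frame absolute ellipse offsets; realize amplitudes.

    Returns ``(schedule, clipped)`` where ``schedule[frame]`` lists
    ``(row, col, offset)`` paint instructions and ``clipped`` flags any
    luminance saturation.  Event amplitudes in ``gt`` are overwritten with
    the realized (quantized) per-square mean |Δlum|.
    """
    ys, xs = _ellipse_offsets(config.square_px)
    frac = ys.size / config.square_px ** 2
    lo, hi = -config.bee_lum, 255 - config.bee_lum
    schedule: Dict[int, List[Tuple[int, int, int]]] = {}
    clipped = False

    by_square: Dict[Square, List[GTEvent]] = {}
    for ev in gt.events:
        by_square.setdefault(ev.square, []).append(ev)

    for sq in sorted(by_square):
        offset = 0
        for ev in sorted(by_square[sq], key=lambda e: e.onset_frame):
            delta = max(int(round(ev.amplitude / frac)), 1)
            ev.amplitude = delta * frac
            if offset + delta <= hi:
                sign = 1
            elif offset - delta >= lo:
                sign = -1
            else:
                clipped = True
                sign = 1 if (offset + delta - hi) <= (lo - (offset - delta)) else -1
            high = offset + sign * delta
            for k in range(ev.duration_frames):
                value = high if k % 2 == 0 else offset
                schedule.setdefault(ev.onset_frame + k, []).append(
                    (sq[0], sq[1], value))
            if ev.duration_frames % 2 == 1:
                offset = high
    return schedule, clipped


def _simulate(config: SceneConfig,
              ) -> Tuple[GroundTruth, Dict[int, List[Tuple[int, int, int]]],
                         np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    child_events, child_noise = ss.spawn(2)
    gt = _sample_events(config, np.random.default_rng(child_events))
    schedule, clipped = _build_schedule(config, gt)
    gt.clipped = clipped
    return gt, schedule, np.random.default_rng(child_noise)


def sample_scene(config: SceneConfig) -> GroundTruth:
    """Ground truth only (realized amplitudes), without rendering pixels.

    Useful for statistics on large scenes where the pixel stack itself is
    not needed; identical to the ground truth returned by the render
    functions for the same config.
    """
    gt, _, _ = _simulate(config)
    return gt


def _iter_rendered(config: SceneConfig,
                   schedule: Dict[int, List[Tuple[int, int, int]]],
                   rng_noise: np.random.Generator) -> Iterator[np.ndarray]:
    h, w = config.frame_shape
    s = config.square_px
    ys, xs = _ellipse_offsets(s)
    canvas = np.full((h, w), config.background_lum, dtype=np.int16)
    for r in range(config.grid_rows):
        for c in range(config.grid_cols):
            canvas[r * s + ys, c * s + xs] = config.bee_lum
    for t in range(config.n_frames):
        for r, c, off in schedule.get(t, ()):
            canvas[r * s + ys, c * s + xs] = config.bee_lum + off
        if config.noise_sd > 0:
            noisy = canvas + rng_noise.normal(0.0, config.noise_sd, canvas.shape)
            yield np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
        else:
            yield np.clip(canvas, 0, 255).astype(np.uint8)


def iter_frames(config: SceneConfig) -> Tuple[Iterator[np.ndarray], GroundTruth]:
    """Streaming renderer: ``(frame iterator, ground truth)``."""
    gt, schedule, rng_noise = _simulate(config)
    return _iter_rendered(config, schedule, rng_noise), gt


def render_frames(config: SceneConfig) -> Tuple[np.ndarray, GroundTruth]:
    """Materialize the whole 8-bit frame stack ``(n_frames, H, W)``.

    Bit-identical for identical configs (incl. seed).  For long
    high-resolution scenes prefer :func:`render_square_series`, which
    streams frames without storing the stack.
    """
    frames, gt = iter_frames(config)
    stack = np.stack(list(frames), axis=0)
    return stack, gt


def render_square_series(config: SceneConfig, reducer: str = "mean",
                         ) -> Tuple[np.ndarray, GroundTruth]:
    """Render and reduce to the per-square Δlum series in one streaming pass.

    Returns ``(series, ground_truth)`` with ``series`` of shape
    ``(n_frames - 1, rows, cols)``; ``series[j]`` is the per-square
    aggregated |difference| between frames ``j`` and ``j + 1`` (so motion at
    ground-truth onset ``t`` appears at series index ``t - 1``).
    """
    if reducer not in ("mean", "sum"):
        raise ValueError("reducer must be 'mean' or 'sum'")
    gt, schedule, rng_noise = _simulate(config)
    rows, cols, s = config.grid_rows, config.grid_cols, config.square_px
    series = np.empty((config.n_frames - 1, rows, cols), dtype=float)
    prev: Optional[np.ndarray] = None
    for t, frame in enumerate(_iter_rendered(config, schedule, rng_noise)):
        cur = frame.astype(np.int16)
        if prev is not None:
            blocks = np.abs(cur - prev).reshape(rows, s, cols, s)
            series[t - 1] = blocks.mean(axis=(1, 3)) if reducer == "mean" \
                else blocks.sum(axis=(1, 3))
        prev = cur
    return series, gt


# --------------------------------------------------------------------------
# Ground-truth IO and detector scoring

_GT_COLUMNS = ["kind", "wave_id", "square_row", "square_col",
               "onset_frame", "duration_frames", "amplitude"]


def write_ground_truth(gt: GroundTruth, path: Union[str, Path]) -> None:
    """Write events and trigger registry to one CSV (kind 'trigger' rows carry
    the registry; their onset_frame is the wave start)."""
    rows = [{"kind": e.kind, "wave_id": e.wave_id or "",
             "square_row": e.square[0], "square_col": e.square[1],
             "onset_frame": e.onset_frame, "duration_frames": e.duration_frames,
             "amplitude": e.amplitude} for e in gt.events]
    rows += [{"kind": "trigger", "wave_id": w, "square_row": sq[0],
              "square_col": sq[1], "onset_frame": start, "duration_frames": 0,
              "amplitude": 0.0} for w, sq, start in gt.trigger_registry]
    pd.DataFrame(rows, columns=_GT_COLUMNS).to_csv(path, index=False)


def read_ground_truth(path: Union[str, Path]) -> GroundTruth:
    df = pd.read_csv(path, keep_default_na=False)
    events, registry = [], []
    for row in df.itertuples(index=False):
        sq = (int(row.square_row), int(row.square_col))
        if row.kind == "trigger":
            registry.append((str(row.wave_id), sq, int(row.onset_frame)))
        else:
            events.append(GTEvent(square=sq, onset_frame=int(row.onset_frame),
                                  duration_frames=int(row.duration_frames),
                                  amplitude=float(row.amplitude), kind=str(row.kind),
                                  wave_id=str(row.wave_id) or None))
    return GroundTruth(events=events, trigger_registry=registry)


def events_from_truth(gt: GroundTruth) -> List[FlickerEvent]:
    """Convert ground-truth flickers to the detector's event representation.

    The per-event summed Δlum is amplitude x duration (each event frame
    contributes the realized per-square mean |Δlum|), which is exactly what
    run-length detection reports on the noise-free rendering.
    """
    return [FlickerEvent(square=e.square, onset_frame=e.onset_frame,
                         duration_frames=e.duration_frames,
                         peak_dlum=e.amplitude,
                         sum_dlum=e.amplitude * e.duration_frames)
            for e in gt.flickers()]


def benchmark_scene(seed: int = 0, noise_sd: float = 0.5,
                    n_frames: int = 3000) -> SceneConfig:
    """Reference detection-benchmark scene: a quiescent 48 x 73 nest.

    One minute of 50 fps footage on the smaller field nest's grid, with a
    single flicker cohort of 170 scattered squares at 0.05 events/s per
    square (about 500 events in total) and default amplitudes well above
    the 2.0 detection threshold.  ``noise_sd`` is the additive Gaussian
    sensor noise in luminance units.
    """
    rows, cols = 48, 73
    rng = np.random.default_rng(20120833)  # fixed square layout; seed drives events
    idx = rng.choice(rows * cols, size=170, replace=False)
    squares = tuple((int(i) // cols, int(i) % cols) for i in sorted(idx))
    return SceneConfig(grid_rows=rows, grid_cols=cols, n_frames=n_frames,
                       square_px=8, fps=50.0, noise_sd=noise_sd,
                       cohorts=(CohortSpec(squares=squares, flicker_rate=0.05),),
                       seed=seed)


def cohort_contrast_scene(seed: int = 0, amplitude_ts: float = 8.0,
                          amplitude_nts: float = 5.0,
                          duration_s: float = 120.0,
                          ) -> Tuple[SceneConfig, TriggerRegistry]:
    """Scene with a designed ts > nts intensity contrast, plus its registry.

    A 30 x 30 nest: 25 trigger sources on a regular lattice define the ts
    cohort (source + Moore neighbourhood, 225 squares); 225 of the
    remaining squares form the nts cohort.  Both cohorts share the same
    heterogeneous rate structure (eight rate levels, 0.05-0.4 events/s, so
    the squares populate many 0.03 Hz rate classes) but ts events are
    drawn with a higher mean amplitude.  Returns the scene and the
    single-entry-per-source trigger registry that reproduces the designed
    partition via trigger pooling.
    """
    rows = cols = 30
    sources = [(r, c) for r in range(2, 30, 6) for c in range(2, 30, 6)]
    ts_squares = sorted({(r + dr, c + dc) for r, c in sources
                         for dr in (-1, 0, 1) for dc in (-1, 0, 1)})
    rest = [(r, c) for r in range(rows) for c in range(cols)
            if (r, c) not in set(ts_squares)]
    rng = np.random.default_rng(20120834)  # fixed layout; seed drives events
    nts_idx = rng.choice(len(rest), size=len(ts_squares), replace=False)
    nts_squares = sorted(rest[i] for i in nts_idx)

    rates = [0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4]
    cohorts = []
    for squares, amp in ((ts_squares, amplitude_ts), (nts_squares, amplitude_nts)):
        for k, rate in enumerate(rates):
            chunk = tuple(squares[k::len(rates)])
            if chunk:
                cohorts.append(CohortSpec(squares=chunk, flicker_rate=rate,
                                          amplitude_mean=amp, amplitude_sd=1.0))
    config = SceneConfig(grid_rows=rows, grid_cols=cols,
                         n_frames=int(round(duration_s * 50.0)), square_px=6,
                         fps=50.0, noise_sd=0.0, cohorts=tuple(cohorts), seed=seed)
    registry = TriggerRegistry(tuple(
        TriggerEntry(wave_id=f"w{i}", phase_label="all", source=sq)
        for i, sq in enumerate(sources)))
    return config, registry


@dataclass(frozen=True)
class MatchResult:
    """Recall/precision of detected events against ground-truth flickers."""

    n_truth: int
    n_detected: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 1.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 1.0


def match_events(truth: Sequence[GTEvent], detected: Sequence[FlickerEvent],
                 max_onset_diff: int = 0) -> MatchResult:
    """Greedy per-square matching of detections to ground-truth flickers.

    A detection matches an unmatched truth event in the same square whose
    onset differs by at most ``max_onset_diff`` frames.
    """
    truth_by_sq: Dict[Square, List[GTEvent]] = {}
    for ev in truth:
        truth_by_sq.setdefault(tuple(ev.square), []).append(ev)
    for evs in truth_by_sq.values():
        evs.sort(key=lambda e: e.onset_frame)
    used: Dict[Square, List[bool]] = {sq: [False] * len(evs)
                                      for sq, evs in truth_by_sq.items()}
    n_matched = 0
    for det in sorted(detected, key=lambda e: (tuple(e.square), e.onset_frame)):
        sq = tuple(det.square)
        for i, ev in enumerate(truth_by_sq.get(sq, [])):
            if not used[sq][i] and abs(ev.onset_frame - det.onset_frame) <= max_onset_diff:
                used[sq][i] = True
                n_matched += 1
                break
    return MatchResult(n_truth=len(truth), n_detected=len(detected),
                       n_matched=n_matched)
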