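"""Readers and writers for the pipeline's on-disk formats.

Frames: numbered 8-bit grayscale PNGs in a directory, or one multi-page
TIFF.  Tables: plain CSV.  Trigger maps: CSV matrices plus white-to-red
heatmap PNGs (255 = per-phase maximum).  Configs: YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from matplotlib.colors import LinearSegmentedColormap

from .flicker_events import FlickerEvent, ShimmerEpisode
from .trigger_map import TriggerEntry, TriggerRegistry, TriggerSiteMap

PathLike = Union[str, Path]

_EVENT_COLUMNS = ["square_row", "square_col", "onset_frame", "duration_frames",
                  "peak_dlum", "sum_dlum"]

#: Fig-4-style rendering scale: white (single wave) to red (per-phase maximum).
WHITE_RED = LinearSegmentedColormap.from_list("white_red",
                                              [(1, 1, 1), (1, 0, 0)])


# ---------------------------------------------------------------- frames ---

def write_frames(stack: Iterable[np.ndarray], path: PathLike,
                 fmt: str = "png") -> List[Path]:
    """Write a frame stack as numbered PNGs in a directory or one TIFF."""
    path = Path(path)
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, np.stack([np.asarray(f, dtype=np.uint8)
                                         for f in stack], axis=0))
        return [path]
    if fmt != "png":
        raise ValueError("fmt must be 'png' or 'tiff'")
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, frame in enumerate(stack):
        p = path / f"frame_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        written.append(p)
    return written


def iter_frames_from(path: PathLike) -> Iterator[np.ndarray]:
    """Iterate grayscale frames from a PNG directory or a (multi-page) TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg"))
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        for p in files:
            yield np.asarray(iio.imread(p))
    elif path.suffix.lower() in (".tif", ".tiff"):
        for frame in tifffile.imread(path):
            yield np.asarray(frame)
    else:
        raise FileNotFoundError(f"frames path {path} is neither a directory nor a TIFF")


# ---------------------------------------------------------------- tables ---

def write_events_csv(events: Sequence[FlickerEvent], path: PathLike) -> None:
    rows = [{"square_row": e.square[0], "square_col": e.square[1],
             "onset_frame": e.onset_frame, "duration_frames": e.duration_frames,
             "peak_dlum": e.peak_dlum, "sum_dlum": e.sum_dlum} for e in events]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path: PathLike) -> List[FlickerEvent]:
    df = pd.read_csv(path)
    return [FlickerEvent(square=(int(r.square_row), int(r.square_col)),
                         onset_frame=int(r.onset_frame),
                         duration_frames=int(r.duration_frames),
                         peak_dlum=float(r.peak_dlum), sum_dlum=float(r.sum_dlum))
            for r in df.itertuples(index=False)]


def write_episodes_csv(episodes: Sequence[ShimmerEpisode], path: PathLike) -> None:
    pd.DataFrame([{"start_frame": e.start_frame, "end_frame": e.end_frame}
                  for e in episodes],
                 columns=["start_frame", "end_frame"]).to_csv(path, index=False)


def read_episodes_csv(path: PathLike) -> List[ShimmerEpisode]:
    df = pd.read_csv(path)
    return [ShimmerEpisode(start_frame=int(r.start_frame),
                           end_frame=int(r.end_frame))
            for r in df.itertuples(index=False)]


def write_registry_csv(registry: TriggerRegistry, path: PathLike) -> None:
    pd.DataFrame([{"wave_id": e.wave_id, "phase": e.phase_label,
                   "square_row": e.source[0], "square_col": e.source[1]}
                  for e in registry.entries],
                 columns=["wave_id", "phase", "square_row", "square_col"]
                 ).to_csv(path, index=False)


def read_registry_csv(path: PathLike) -> TriggerRegistry:
    df = pd.read_csv(path, keep_default_na=False)
    return TriggerRegistry(tuple(
        TriggerEntry(wave_id=str(r.wave_id), phase_label=str(r.phase),
                     source=(int(r.square_row), int(r.square_col)))
        for r in df.itertuples(index=False)))


def write_matrix_csv(matrix: np.ndarray, path: PathLike) -> None:
    """(rows x cols) matrix with 0-based row/col headers."""
    pd.DataFrame(np.asarray(matrix)).to_csv(path, index_label="row")


def read_matrix_csv(path: PathLike) -> np.ndarray:
    return pd.read_csv(path, index_col="row").to_numpy(dtype=float)


# --------------------------------------------------------------- heatmaps ---

def write_heatmap_png(m: Union[TriggerSiteMap, np.ndarray], path: PathLike,
                      upscale: int = 6) -> None:
    """Render a per-square map on the white-to-red 0-255 scale."""
    arr = m.activity if isinstance(m, TriggerSiteMap) else np.asarray(m, dtype=float)
    peak = arr.max()
    norm = arr / peak if peak > 0 else arr
    rgb = (WHITE_RED(norm)[..., :3] * 255).astype(np.uint8)
    rgb = np.repeat(np.repeat(rgb, upscale, axis=0), upscale, axis=1)
    iio.imwrite(Path(path), rgb)


# ----------------------------------------------------------------- config ---

def load_yaml(path: PathLike) -> dict:
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return data


def dump_yaml(data: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
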