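"""Frame-difference motion fields.

Motion of surface bees is quantified as the absolute luminance change
(|Δlum|, 0-255) between two subsequent frames, per pixel and aggregated per
test square.  Δlum = 0 is motionlessness; Δlum = 255 the maximal attainable
motion intensity.  Color frames are converted to luma (Rec. 601 weights)
before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np

from .assessment_grid import AssessmentGrid

#: Rec. 601 luma weights for RGB -> grayscale conversion.
REC601 = (0.299, 0.587, 0.114)

#: Pixel strength classes used when rendering segmented difference images
#: (weak / medium / strong motion patches).
STRENGTH_NONE, STRENGTH_WEAK, STRENGTH_MEDIUM, STRENGTH_STRONG = 0, 1, 2, 3


@dataclass(frozen=True)
class DifferenceImage:
    """Per-pixel non-negative luminance difference, tagged by the later frame."""

    values: np.ndarray
    frame_index: Optional[int] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any() or (v > 255).any():
            raise ValueError("difference values must lie in [0, 255]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MotionMask:
    """Binary motion mask with an optional weak/medium/strong class per pixel."""

    mask: np.ndarray
    strength: np.ndarray


ArrayOrDiff = Union[np.ndarray, DifferenceImage]


def _values(diff: ArrayOrDiff) -> np.ndarray:
    if isinstance(diff, DifferenceImage):
        return diff.values
    return np.asarray(diff, dtype=float)


def to_luma(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to Rec. 601 luma; grayscale passes through."""
    arr = np.asarray(frame, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
        return REC601[0] * r + REC601[1] * g + REC601[2] * b
    raise ValueError(f"expected HxW or HxWx3/4 frame, got shape {arr.shape}")


def frame_difference(f1: np.ndarray, f2: np.ndarray,
                     frame_index: Optional[int] = None) -> ArrayOrDiff:
    """Absolute per-pixel luminance difference |f2 - f1|.

    Commutative in its inputs.  Returns a bare array, or a
    :class:`DifferenceImage` when ``frame_index`` (index of the later frame)
    is given.
    """
    a, b = to_luma(f1), to_luma(f2)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    diff = np.abs(b - a)
    if frame_index is None:
        return diff
    return DifferenceImage(values=diff, frame_index=frame_index)


def segment(diff: ArrayOrDiff, seg_threshold: float = 2.0,
            strength_bounds: Tuple[float, float] = (10.0, 40.0)) -> MotionMask:
    """Segment a difference image into black-and-white motion areas.

    A pixel is motion iff its difference >= ``seg_threshold``.  Masked pixels
    are classified weak (< ``strength_bounds[0]``), medium, or strong
    (>= ``strength_bounds[1]``).
    """
    if seg_threshold <= 0:
        raise ValueError("seg_threshold must be positive")
    lo, hi = strength_bounds
    if not lo < hi:
        raise ValueError("strength_bounds must be strictly ascending")
    v = _values(diff)
    mask = v >= seg_threshold
    strength = np.full(v.shape, STRENGTH_NONE, dtype=np.uint8)
    strength[mask & (v < lo)] = STRENGTH_WEAK
    strength[mask & (v >= lo) & (v < hi)] = STRENGTH_MEDIUM
    strength[mask & (v >= hi)] = STRENGTH_STRONG
    return MotionMask(mask=mask, strength=strength)


def square_luminance(diff: ArrayOrDiff, grid: AssessmentGrid,
                     reducer: str = "mean") -> np.ndarray:
    """Aggregate a difference image to one Δlum value per test square.

    ``reducer="mean"`` (default) gives the mean absolute pixel difference in
    the square, keeping the 0-255 scale independent of resolution;
    ``reducer="sum"`` gives mean x pixels-per-square.
    """
    if reducer not in ("mean", "sum"):
        raise ValueError("reducer must be 'mean' or 'sum'")
    v = _values(diff)
    oy, ox = grid.origin
    h, w = grid.pixel_shape
    if v.ndim != 2 or v.shape[0] < oy + h or v.shape[1] < ox + w:
        raise ValueError(
            f"grid ({grid.rows}x{grid.cols} squares of {grid.square_px} px at "
            f"origin {grid.origin}) does not fit image of shape {v.shape}")
    region = v[oy:oy + h, ox:ox + w]
    blocks = region.reshape(grid.rows, grid.square_px, grid.cols, grid.square_px)
    if reducer == "mean":
        return blocks.mean(axis=(1, 3))
    return blocks.sum(axis=(1, 3))


def square_series(frames: Iterable[np.ndarray], grid: AssessmentGrid,
                  reducer: str = "mean") -> np.ndarray:
    """Per-square Δlum time series for a frame stack.

    Returns an array of shape ``(n_frames - 1, rows, cols)`` where entry
    ``[j]`` is the aggregated difference between frames ``j`` and ``j + 1``
    (i.e. motion first visible in frame ``j + 1``).
    """
    out = []
    prev: Optional[np.ndarray] = None
    for frame in frames:
        cur = to_luma(frame)
        if prev is not None:
            out.append(square_luminance(np.abs(cur - prev), grid, reducer=reducer))
        prev = cur
    if prev is None or not out:
        raise ValueError("need at least two frames")
    return np.stack(out, axis=0)
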