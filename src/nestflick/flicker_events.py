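"""Flicker event detection with interval filtering.

A flicker is a brief dorso-ventral abdomen flip of a single surface bee.  In
the per-square Δlum time series it appears as a run of 1-3 supra-threshold
difference frames (Δlum > 2.0, i.e. up to 60 ms at 50 fps), typically
repeated after more than one second.  Longer supra-threshold runs are other
motion -- fanning, walking, dancing -- and yield no flicker event.  Frames
during which a shimmering wave sweeps the nest are masked out, since flicker
detection is not possible while most squares move at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

Square = Tuple[int, int]


@dataclass(frozen=True)
class EventFilterConfig:
    """Interval-filter parameters for flicker detection.

    detect_threshold
        Strict per-square Δlum threshold (events require Δlum > threshold).
    max_duration_frames
        Longest supra-threshold run still counted as a flicker; longer runs
        are classified as sustained motion and rejected.
    min_gap_s
        Refractory window: events whose onsets are closer than this are
        merged into the earlier event.
    fps
        Frame rate, used to convert the refractory window to frames.
    """

    detect_threshold: float = 2.0
    max_duration_frames: int = 3
    min_gap_s: float = 1.0
    fps: float = 50.0

    def __post_init__(self) -> None:
        if self.detect_threshold <= 0:
            raise ValueError("detect_threshold must be positive")
        if self.max_duration_frames < 1:
            raise ValueError("max_duration_frames must be >= 1")
        if self.min_gap_s < 0:
            raise ValueError("min_gap_s must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def gap_frames(self) -> float:
        """Refractory window in frames."""
        return self.min_gap_s * self.fps

    def max_duration_ms(self) -> float:
        """Upper event-duration bound in milliseconds (e.g. 3 frames @ 50 fps = 60 ms)."""
        return self.max_duration_frames / self.fps * 1000.0


@dataclass(frozen=True)
class FlickerEvent:
    """A detected flicker: a short supra-threshold pulse in one test square."""

    square: Square
    onset_frame: int
    duration_frames: int
    peak_dlum: float
    sum_dlum: float

    @property
    def end_frame(self) -> int:
        """Exclusive end: first frame after the event."""
        return self.onset_frame + self.duration_frames


@dataclass(frozen=True)
class ShimmerEpisode:
    """A contiguous stretch of frames dominated by a shimmering wave.

    ``start_frame``/``end_frame`` are half-open (``end_frame`` exclusive).
    """

    start_frame: int
    end_frame: int
    participating: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.end_frame > self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    def overlaps(self, onset: int, duration: int) -> bool:
        return onset < self.end_frame and onset + duration > self.start_frame


def _true_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """(start, length) of maximal runs of True in a 1-D boolean array."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_events(series: Sequence[float], cfg: EventFilterConfig,
                  square: Square = (0, 0),
                  first_frame_index: int = 0) -> List[FlickerEvent]:
    """Run-length flicker detection on one square's Δlum series.

    Maximal runs of frames with Δlum > ``cfg.detect_threshold`` become
    events when their length is <= ``cfg.max_duration_frames``; longer runs
    are sustained motion and yield nothing.  Events whose onsets fall closer
    than ``cfg.gap_frames`` are merged into the earlier event (the merged
    event keeps the earlier onset and duration and accumulates peak/sum).

    ``first_frame_index`` is the frame index of ``series[0]`` -- pass 1 when
    the series was built from frame differences indexed by the later frame.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be 1-D")
    if not np.isfinite(arr).all():
        raise ValueError("series must be finite")
    if (arr < 0).any():
        raise ValueError("series must be non-negative")

    events: List[FlickerEvent] = []
    for start, length in _true_runs(arr > cfg.detect_threshold):
        if length > cfg.max_duration_frames:
            continue  # sustained motion (e.g. fanning), not a flicker
        seg = arr[start:start + length]
        events.append(FlickerEvent(
            square=square,
            onset_frame=first_frame_index + start,
            duration_frames=length,
            peak_dlum=float(seg.max()),
            sum_dlum=float(seg.sum()),
        ))

    merged: List[FlickerEvent] = []
    for ev in events:
        if merged and ev.onset_frame - merged[-1].onset_frame < cfg.gap_frames:
            prev = merged[-1]
            merged[-1] = replace(prev,
                                 peak_dlum=max(prev.peak_dlum, ev.peak_dlum),
                                 sum_dlum=prev.sum_dlum + ev.sum_dlum)
        else:
            merged.append(ev)
    return merged


def detect_events_grid(series_stack: np.ndarray, cfg: EventFilterConfig,
                       first_frame_index: int = 1) -> List[FlickerEvent]:
    """Flicker detection over a whole grid.

    ``series_stack`` has shape ``(n_diff_frames, rows, cols)``.  Events are
    returned sorted by (row, col, onset).
    """
    stack = np.asarray(series_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("series_stack must be (frames, rows, cols)")
    events: List[FlickerEvent] = []
    _, rows, cols = stack.shape
    for r in range(rows):
        for c in range(cols):
            events.extend(detect_events(stack[:, r, c], cfg, square=(r, c),
                                        first_frame_index=first_frame_index))
    return events


def activity_fraction(series_stack: np.ndarray, threshold: float,
                      active_squares: Optional[Set[Square]] = None) -> np.ndarray:
    """Per-frame fraction of (active) squares whose Δlum exceeds ``threshold``."""
    stack = np.asarray(series_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("series_stack must be (frames, rows, cols)")
    supra = stack > threshold
    if active_squares is not None:
        sel = np.zeros(stack.shape[1:], dtype=bool)
        for r, c in active_squares:
            sel[r, c] = True
        if not sel.any():
            raise ValueError("no active squares")
        supra = supra[:, sel]
        return supra.mean(axis=1)
    return supra.reshape(supra.shape[0], -1).mean(axis=1)


def detect_shimmer_episodes(activity: np.ndarray, frac_threshold: float = 0.15,
                            min_len_frames: int = 3,
                            first_frame_index: int = 0) -> List[ShimmerEpisode]:
    """Mask stretches of frames where a wave sweeps the nest.

    ``activity`` is either a 1-D per-frame active-square fraction, or a
    boolean matrix (frames x squares, possibly frames x rows x cols) from
    which the fraction and the participating squares are derived.  Frames
    with fraction >= ``frac_threshold`` are grouped into maximal runs; runs
    of at least ``min_len_frames`` frames become episodes (sorted, disjoint,
    half-open frame intervals).
    """
    if not 0 <= frac_threshold <= 1:
        raise ValueError("frac_threshold must lie in [0, 1]")
    if min_len_frames < 1:
        raise ValueError("min_len_frames must be >= 1")
    arr = np.asarray(activity)
    part_matrix: Optional[np.ndarray] = None
    square_labels: Optional[List[Square]] = None
    if arr.ndim == 1:
        frac = arr.astype(float)
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
    elif arr.ndim in (2, 3):
        part_matrix = arr.reshape(arr.shape[0], -1).astype(bool)
        if arr.ndim == 3:
            rows, cols = arr.shape[1], arr.shape[2]
            square_labels = [(r, c) for r in range(rows) for c in range(cols)]
        else:
            square_labels = [(0, k) for k in range(arr.shape[1])]
        frac = part_matrix.mean(axis=1)
    else:
        raise ValueError("activity must be 1-D fractions or 2/3-D boolean matrix")

    episodes: List[ShimmerEpisode] = []
    for start, length in _true_runs(frac >= frac_threshold):
        if length < min_len_frames:
            continue
        participating: frozenset = frozenset()
        if part_matrix is not None:
            hit = part_matrix[start:start + length].any(axis=0)
            participating = frozenset(square_labels[k] for k in np.nonzero(hit)[0])
        episodes.append(ShimmerEpisode(
            start_frame=first_frame_index + start,
            end_frame=first_frame_index + start + length,
            participating=participating,
        ))
    return episodes


def filter_events(events: Iterable[FlickerEvent],
                  episodes: Iterable[ShimmerEpisode] = (),
                  active_squares: Optional[Set[Square]] = None) -> List[FlickerEvent]:
    """Drop events in masked squares or overlapping a shimmer episode.

    Idempotent; the output is always a subset of the input.
    """
    episodes = list(episodes)
    out: List[FlickerEvent] = []
    for ev in events:
        if active_squares is not None and tuple(ev.square) not in active_squares:
            continue
        if any(ep.overlaps(ev.onset_frame, ev.duration_frames) for ep in episodes):
            continue
        out.append(ev)
    return out
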