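"""Trigger-site maps and the ts/nts cohort partition.

Shimmering waves are launched from trigger sites (ts): small cohorts of
surface bees around a source square.  Each registered wave contributes a
trigger-activity value of 1.0 to its source square and its eight Moore
neighbours (clipped at the nest border), activities are pooled over waves
per experimental phase, and the pooled map is scaled to its maximum for
rendering.  Active squares with non-zero pooled activity form the ts cohort;
all other active squares are non-trigger sites (nts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .assessment_grid import AssessmentGrid

Square = Tuple[int, int]
GridLike = Union[AssessmentGrid, Tuple[int, int]]


def _grid_shape(grid: GridLike) -> Tuple[int, int]:
    if isinstance(grid, AssessmentGrid):
        return grid.shape
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid shape must be positive")
    return (int(rows), int(cols))


@dataclass(frozen=True)
class TriggerEntry:
    """One registered trigger event: a wave launched from a source square."""

    wave_id: str
    phase_label: str
    source: Square


@dataclass(frozen=True)
class TriggerRegistry:
    """Registry of wave source squares (one entry per trigger event)."""

    entries: Tuple[TriggerEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def phases(self) -> List[str]:
        seen: Dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.phase_label)
        return list(seen)

    def for_phase(self, phase_label: Optional[str]) -> "TriggerRegistry":
        if phase_label is None:
            return self
        return TriggerRegistry(tuple(e for e in self.entries
                                     if e.phase_label == phase_label))


@dataclass(frozen=True)
class TriggerSiteMap:
    """Pooled per-square trigger activity, optionally scaled to [0, 1]."""

    activity: np.ndarray
    phase_label: Optional[str] = None
    scaled: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.activity, dtype=float)
        if arr.ndim != 2:
            raise ValueError("activity must be a (rows, cols) matrix")
        if (arr < 0).any():
            raise ValueError("activity must be non-negative")
        object.__setattr__(self, "activity", arr)

    @property
    def max_activity(self) -> float:
        return float(self.activity.max()) if self.activity.size else 0.0


@dataclass(frozen=True)
class CohortPartition:
    """Disjoint ts/nts split of the active nest squares."""

    ts_squares: frozenset
    nts_squares: frozenset

    def __post_init__(self) -> None:
        ts = frozenset(tuple(s) for s in self.ts_squares)
        nts = frozenset(tuple(s) for s in self.nts_squares)
        if ts & nts:
            raise ValueError("ts and nts cohorts must be disjoint")
        object.__setattr__(self, "ts_squares", ts)
        object.__setattr__(self, "nts_squares", nts)

    def cohort_of(self, square: Square) -> Optional[str]:
        square = tuple(square)
        if square in self.ts_squares:
            return "ts"
        if square in self.nts_squares:
            return "nts"
        return None


def assign_trigger_site(source: Square, grid: GridLike) -> Dict[Square, float]:
    """The nine-square trigger site of one wave: source + 8 Moore neighbours.

    Each receives trigger-activity value 1.0; neighbours outside the grid
    are clipped, so a corner source yields 4 squares and an edge source 6.
    """
    rows, cols = _grid_shape(grid)
    r0, c0 = source
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"source {source} outside {rows}x{cols} grid")
    return {(r, c): 1.0
            for r in range(max(r0 - 1, 0), min(r0 + 2, rows))
            for c in range(max(c0 - 1, 0), min(c0 + 2, cols))}


def pool_trigger_activity(registry: TriggerRegistry, grid: GridLike,
                          phase_label: Optional[str] = None) -> TriggerSiteMap:
    """Sum trigger-site assignments of all registered waves (in a phase).

    An empty phase gives an all-zero map (flagged by ``max_activity == 0``).
    """
    rows, cols = _grid_shape(grid)
    activity = np.zeros((rows, cols), dtype=float)
    for entry in registry.for_phase(phase_label).entries:
        for (r, c), v in assign_trigger_site(entry.source, (rows, cols)).items():
            activity[r, c] += v
    return TriggerSiteMap(activity=activity, phase_label=phase_label, scaled=False)


def scale_map(m: TriggerSiteMap) -> TriggerSiteMap:
    """Scale pooled activity to its per-phase maximum (order-preserving).

    An all-zero map stays all-zero (no division).  The scaled values lie in
    [0, 1]; multiply by 255 for the white-to-red render scale.
    """
    peak = m.max_activity
    scaled = m.activity / peak if peak > 0 else m.activity.copy()
    return TriggerSiteMap(activity=scaled, phase_label=m.phase_label, scaled=True)


def partition_cohorts(m: TriggerSiteMap,
                      active_squares: Iterable[Square]) -> CohortPartition:
    """ts = active squares with any trigger activity; nts = the rest.

    Invariant under :func:`scale_map` (scaling preserves zero/non-zero).
    """
    active = {tuple(sq) for sq in active_squares}
    rows, cols = m.activity.shape
    ts = {sq for sq in active
          if 0 <= sq[0] < rows and 0 <= sq[1] < cols and m.activity[sq] > 0}
    return CohortPartition(ts_squares=frozenset(ts),
                           nts_squares=frozenset(active - ts))
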