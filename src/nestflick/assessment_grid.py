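"""Bee-sized assessment grids over nest images.

The nest image is tiled with square "test squares" whose side length matches
the body size of a single surface bee (1.5 cm in the two field setups this
package models, i.e. 123 x 53 and 73 x 48 squares).  Every downstream
statistic -- flicker events, trigger-site maps, rate/intensity cohorts -- is
computed per test square, so the grid is the coordinate system of the whole
pipeline.

Conventions
-----------
* 0-based ``(row, col)`` indices, row 0 at the image top (raster order);
* half-open pixel intervals: square ``(r, c)`` owns pixels
  ``[origin_y + r*square_px, origin_y + (r+1)*square_px)`` x likewise in x,
  so a boundary pixel belongs to the square whose lower edge it sits on;
* trailing pixels that do not fill a whole square are outside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, Set, Tuple

import numpy as np
from matplotlib.path import Path as _MplPath

Square = Tuple[int, int]

MASK_LABELS = ("mouth_zone", "off_nest", "other")


@dataclass(frozen=True)
class AssessmentGrid:
    """A lattice of bee-sized test squares superimposed on the nest image.

    Parameters
    ----------
    rows, cols
        Number of test squares vertically / horizontally.
    square_px
        Pixels per square side.
    unit_len_cm
        Physical side length of one square (informational; default 1.5 cm,
        the body size of a surface bee).
    origin
        ``(y, x)`` pixel offset of square ``(0, 0)``'s top-left corner.
    """

    rows: int
    cols: int
    square_px: int
    unit_len_cm: float = 1.5
    origin: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.square_px < 1:
            raise ValueError("square_px must be >= 1")
        if self.unit_len_cm <= 0:
            raise ValueError("unit_len_cm must be positive")
        oy, ox = self.origin
        if oy < 0 or ox < 0:
            raise ValueError("origin must be non-negative")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_squares(self) -> int:
        return self.rows * self.cols

    @property
    def extent_cm(self) -> Tuple[float, float]:
        """Physical (height, width) of the gridded region in cm."""
        return (self.rows * self.unit_len_cm, self.cols * self.unit_len_cm)

    @property
    def pixel_shape(self) -> Tuple[int, int]:
        """(height, width) in pixels of the gridded region (excluding origin offset)."""
        return (self.rows * self.square_px, self.cols * self.square_px)

    def squares(self) -> Iterator[Square]:
        for r in range(self.rows):
            for c in range(self.cols):
                yield (r, c)

    def contains(self, square: Square) -> bool:
        r, c = square
        return 0 <= r < self.rows and 0 <= c < self.cols

    def square_slices(self, row: int, col: int) -> Tuple[slice, slice]:
        """Pixel slices (y, x) owned by square ``(row, col)``."""
        if not self.contains((row, col)):
            raise IndexError(f"square {(row, col)} outside {self.rows}x{self.cols} grid")
        oy, ox = self.origin
        s = self.square_px
        return (slice(oy + row * s, oy + (row + 1) * s),
                slice(ox + col * s, ox + (col + 1) * s))

    def center_px(self, row: int, col: int) -> Tuple[float, float]:
        """Pixel-space ``(x, y)`` center of a square."""
        ys, xs = self.square_slices(row, col)
        return ((xs.start + xs.stop - 1) / 2.0, (ys.start + ys.stop - 1) / 2.0)


@dataclass(frozen=True)
class RegionMask:
    """A labelled set of excluded squares (e.g. the high-traffic mouth zone)."""

    excluded: frozenset
    label: str = "other"

    def __post_init__(self) -> None:
        if self.label not in MASK_LABELS:
            raise ValueError(f"label must be one of {MASK_LABELS}")
        object.__setattr__(self, "excluded", frozenset(tuple(sq) for sq in self.excluded))


def build_grid(image_shape: Sequence[int], square_px: int,
               origin: Tuple[int, int] = (0, 0),
               unit_len_cm: float = 1.5) -> AssessmentGrid:
    """Fit the largest whole-square grid into an image.

    ``image_shape`` is ``(height, width)`` in pixels.  Rows/cols are the
    integer number of whole squares that fit below/right of ``origin``.
    """
    if square_px < 1:
        raise ValueError("square_px must be >= 1")
    height, width = int(image_shape[0]), int(image_shape[1])
    oy, ox = origin
    rows = (height - oy) // square_px
    cols = (width - ox) // square_px
    if rows < 1 or cols < 1:
        raise ValueError(
            f"square_px={square_px} with origin {origin} does not fit a single "
            f"square into a {height}x{width} image")
    return AssessmentGrid(rows=rows, cols=cols, square_px=square_px,
                          unit_len_cm=unit_len_cm, origin=(oy, ox))


def map_point_to_square(grid: AssessmentGrid, x: float, y: float) -> Square:
    """Map a pixel position (e.g. a bee thorax) to its test square.

    Half-open convention: ``x == k*square_px`` belongs to column ``k``.
    Raises ``ValueError`` for points outside the gridded region.
    """
    oy, ox = grid.origin
    col = int(np.floor((x - ox) / grid.square_px))
    row = int(np.floor((y - oy) / grid.square_px))
    if not grid.contains((row, col)):
        raise ValueError(f"point ({x}, {y}) lies outside the gridded region")
    return (row, col)


def polygon_mask(grid: AssessmentGrid, vertices: Sequence[Tuple[float, float]],
                 label: str = "mouth_zone") -> RegionMask:
    """Rasterize a pixel-space polygon to a square mask.

    A square is excluded iff its center lies inside the polygon
    (``vertices`` are ``(x, y)`` pixel coordinates).
    """
    path = _MplPath([(float(x), float(y)) for x, y in vertices])
    centers = np.array([grid.center_px(r, c) for r, c in grid.squares()])
    inside = path.contains_points(centers)
    squares = [sq for sq, hit in zip(grid.squares(), inside) if hit]
    return RegionMask(excluded=frozenset(squares), label=label)


def apply_mask(grid: AssessmentGrid, masks: Iterable[RegionMask]) -> Set[Square]:
    """Active squares = all grid squares minus the union of exclusions."""
    excluded: Set[Square] = set()
    for mask in masks:
        for sq in mask.excluded:
            if not grid.contains(sq):
                raise ValueError(f"masked square {sq} outside grid")
            excluded.add(tuple(sq))
    return {sq for sq in grid.squares() if sq not in excluded}
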