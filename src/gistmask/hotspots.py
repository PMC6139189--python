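"""Hotspot and not-hotspot window (DOI) selection on a cell map.

A DOI ("digital object of interest") is a square scoring window, by
default 1500 µm on a side so that five of them cover the ~10–11 mm² a
50-high-power-field mitotic count would.  The whole slide is scanned on
a stride lattice; every candidate window gets a Ki-67-positive ratio
(positive tumor cells / tumor cells), windows that are too sparse or
touch an exclusion region are marked invalid, and the selector picks

* ``hotspot``: the greedy top-k ratio windows, pairwise disjoint;
* ``not_hotspot``: k disjoint valid windows whose ratios are nearest the
  median of the remaining valid windows (a "typical tumor" reference;
  a ``lowest`` mode is available as an alternative definition).

All rules are deterministic: ties break on higher cell count, then lower
y, then lower x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Polygon, box

from ._errors import (
    ConfigurationError,
    GeometryError,
    InfeasibleSelectionError,
)
from .cellmap import CellMap, points_in_any_polygon

DOIKind = Literal["hotspot", "not_hotspot"]


@dataclass
class DOI:
    """One scoring window with its per-class tumor-cell counts."""

    origin_x_um: float
    origin_y_um: float
    side_um: float
    kind: DOIKind
    n_strong: int = 0
    n_weak: int = 0
    n_negative: int = 0

    @property
    def n_total(self) -> int:
        return self.n_strong + self.n_weak + self.n_negative

    @property
    def n_positive(self) -> int:
        return self.n_strong + self.n_weak

    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x_um,
            self.origin_y_um,
            self.origin_x_um + self.side_um,
            self.origin_y_um + self.side_um,
        )


@dataclass
class DensityGrid:
    """Positive-ratio field over the stride lattice of window origins.

    Matrices are indexed ``[iy, ix]``; the window at ``(iy, ix)`` has its
    lower-left corner at ``(ix * stride_um, iy * stride_um)``.
    """

    side_um: float
    stride_um: float
    ratio: np.ndarray  # positive fraction; NaN where invalid
    counts: np.ndarray  # tumor cells per window
    positives: np.ndarray
    valid: np.ndarray  # bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.ratio.shape

    def origin(self, iy: int, ix: int) -> tuple[float, float]:
        return ix * self.stride_um, iy * self.stride_um


# ---------------------------------------------------------------------- #
def apply_exclusions(cell_map: CellMap, polygons: Sequence[Polygon]) -> CellMap:
    """Flag cells inside any exclusion polygon.

    Returns a new map whose ``excluded`` column marks cells falling in
    ulceration/granulation/lymphocyte-rich regions; excluded cells (and
    lymphocyte-class cells) never contribute to window counts or scores.
    """
    for poly in polygons:
        if not poly.is_valid or poly.is_empty:
            raise GeometryError("invalid or empty exclusion polygon")
    inside = points_in_any_polygon(
        cell_map.cells["x_um"].to_numpy(),
        cell_map.cells["y_um"].to_numpy(),
        polygons,
    )
    cells = cell_map.cells.assign(excluded=inside)
    return CellMap(
        cells, cell_map.width_um, cell_map.height_um, list(polygons), cell_map.meta
    )


def count_window(
    cell_map: CellMap, x0: float, y0: float, side_um: float
) -> tuple[int, int, int]:
    """(strong, weak, negative) tumor-cell counts in ``[x0,x0+s) x [y0,y0+s)``."""
    tc = cell_map.tumor_cells
    m = (
        (tc["x_um"] >= x0)
        & (tc["x_um"] < x0 + side_um)
        & (tc["y_um"] >= y0)
        & (tc["y_um"] < y0 + side_um)
    )
    vc = tc.loc[m, "stain_class"].value_counts()
    return int(vc.get("strong", 0)), int(vc.get("weak", 0)), int(vc.get("negative", 0))


def _window_sums(binned: np.ndarray, w: int) -> np.ndarray:
    """Sliding w x w block sums on a bin grid via an integral image."""
    s = np.zeros((binned.shape[0] + 1, binned.shape[1] + 1))
    np.cumsum(np.cumsum(binned, axis=0), axis=1, out=s[1:, 1:])
    return s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w]


def compute_density_grid(
    cell_map: CellMap,
    side_um: float = 1500.0,
    stride_um: float = 250.0,
    min_cells: int = 500,
) -> DensityGrid:
    """Scan the slide and compute the positive ratio of every window.

    Windows use half-open centroid membership ``[x, x+side)``; a window
    is invalid when it holds fewer than ``min_cells`` tumor cells or
    intersects any exclusion polygon.  ``side_um`` must be an integer
    multiple of ``stride_um`` so window counts are exact bin-block sums.
    """
    if stride_um <= 0:
        raise ConfigurationError("stride_um must be positive")
    if side_um > cell_map.width_um or side_um > cell_map.height_um:
        raise ConfigurationError("window side exceeds slide extents")
    w = side_um / stride_um
    if abs(w - round(w)) > 1e-9:
        raise ConfigurationError("side_um must be a multiple of stride_um")
    w = int(round(w))

    if cell_map.exclusions:
        cell_map = apply_exclusions(cell_map, cell_map.exclusions)
    tc = cell_map.tumor_cells
    nx = int(np.floor(cell_map.width_um / stride_um))
    ny = int(np.floor(cell_map.height_um / stride_um))
    if nx < w or ny < w:
        raise ConfigurationError("slide too small for one window")

    x = tc["x_um"].to_numpy()
    y = tc["y_um"].to_numpy()
    pos = (tc["stain_class"] != "negative").to_numpy()
    edges_x = np.arange(nx + 1) * stride_um
    edges_y = np.arange(ny + 1) * stride_um
    total_bins, _, _ = np.histogram2d(y, x, bins=[edges_y, edges_x])
    pos_bins, _, _ = np.histogram2d(y[pos], x[pos], bins=[edges_y, edges_x])

    counts = _window_sums(total_bins, w)
    positives = _window_sums(pos_bins, w)
    valid = counts >= min_cells

    if cell_map.exclusions:
        for iy in range(counts.shape[0]):
            for ix in range(counts.shape[1]):
                if not valid[iy, ix]:
                    continue
                window = box(
                    ix * stride_um,
                    iy * stride_um,
                    ix * stride_um + side_um,
                    iy * stride_um + side_um,
                )
                if any(window.intersects(p) for p in cell_map.exclusions):
                    valid[iy, ix] = False

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, positives / np.maximum(counts, 1), np.nan)
    return DensityGrid(side_um, stride_um, ratio, counts, positives, valid)


# ---------------------------------------------------------------------- #
def _disjoint(ox1, oy1, ox2, oy2, side) -> bool:
    return abs(ox1 - ox2) >= side or abs(oy1 - oy2) >= side


def select_origins(
    grid: DensityGrid,
    k: int,
    kind: DOIKind,
    mode: Literal["median", "lowest"] = "median",
    avoid: Sequence[tuple[float, float]] = (),
) -> list[tuple[float, float]]:
    """Deterministic greedy window selection on the density grid.

    Returns k window origins (µm).  ``avoid`` lists origins (of the same
    side) the selection must additionally stay disjoint from — used to
    keep not-hotspot windows clear of the chosen hotspots.
    """
    iy, ix = np.nonzero(grid.valid)
    if len(iy) == 0:
        raise InfeasibleSelectionError(k, 0, kind)
    ratio = grid.ratio[iy, ix]
    count = grid.counts[iy, ix]
    ox = ix * grid.stride_um
    oy = iy * grid.stride_um

    avoid = list(avoid)
    free = [
        i
        for i in range(len(iy))
        if all(_disjoint(ox[i], oy[i], ax, ay, grid.side_um) for ax, ay in avoid)
    ]
    if kind == "hotspot":
        key = lambda i: (-ratio[i], -count[i], oy[i], ox[i])
    elif mode == "lowest":
        key = lambda i: (ratio[i], -count[i], oy[i], ox[i])
    else:
        median = float(np.median(ratio[free])) if free else np.nan
        key = lambda i: (abs(ratio[i] - median), -count[i], oy[i], ox[i])

    chosen: list[tuple[float, float]] = []
    for i in sorted(free, key=key):
        if all(
            _disjoint(ox[i], oy[i], cx, cy, grid.side_um) for cx, cy in chosen
        ):
            chosen.append((float(ox[i]), float(oy[i])))
            if len(chosen) == k:
                return chosen
    raise InfeasibleSelectionError(k, len(chosen), kind)


def select_dois(
    grid: DensityGrid,
    cell_map: CellMap,
    k: int = 5,
    kind: DOIKind = "hotspot",
    mode: Literal["median", "lowest"] = "median",
    avoid: Sequence[DOI] = (),
) -> list[DOI]:
    """Select k disjoint DOIs of the given kind and fill their counts."""
    origins = select_origins(
        grid,
        k,
        kind,
        mode,
        [(d.origin_x_um, d.origin_y_um) for d in avoid],
    )
    out = []
    for ox, oy in origins:
        s, wk, neg = count_window(cell_map, ox, oy, grid.side_um)
        out.append(DOI(ox, oy, grid.side_um, kind, s, wk, neg))
    return out
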