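"""The slide-level cell table ("digital map") and its on-disk formats.

A :class:`CellMap` is the interchange object between every stage of the
pipeline: the simulator produces one, the masking stage produces one from a
rendered tile, and hotspot selection / scoring consume one.  It wraps a
pandas DataFrame of per-nucleus records plus the slide bounds and the
exclusion polygons (ulceration, granulation tissue, lymphocyte-rich stroma).

Cell records carry micrometre coordinates, morphology (area, circularity),
the stain class (negative / weak / strong DAB reaction) and the cell class
(tumor vs lymphocyte).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape

from ._errors import FormatError, GeometryError

STAIN_CLASSES = ("negative", "weak", "strong")
CELL_CLASSES = ("tumor", "lymphocyte")

#: canonical column order of the cell-table CSV
CELL_COLUMNS = (
    "cell_id",
    "x_um",
    "y_um",
    "area_um2",
    "circularity",
    "stain_class",
    "cell_class",
)


@dataclass
class CellMap:
    """A slide's cell records, bounds and exclusion regions.

    Parameters
    ----------
    cells
        DataFrame with (at least) the columns in :data:`CELL_COLUMNS`.
        An ``excluded`` boolean column is added lazily by
        :func:`gistmask.hotspots.apply_exclusions`.
    width_um, height_um
        Slide extents; cells live in ``[0, width) x [0, height)`` µm.
    exclusions
        Shapely polygons (µm coordinates) marking regions that must not
        contribute to any window statistic.
    meta
        Free-form provenance (e.g. simulator ground truth for tests).
    """

    cells: pd.DataFrame
    width_um: float
    height_um: float
    exclusions: list[Polygon] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise FormatError(f"cell table is missing columns {missing}")
        if self.width_um <= 0 or self.height_um <= 0:
            raise GeometryError("slide extents must be positive")
        for poly in self.exclusions:
            if not poly.is_valid:
                raise GeometryError(f"invalid exclusion polygon: {poly.wkt[:80]}")
        if "excluded" not in self.cells.columns:
            self.cells = self.cells.assign(excluded=False)

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.cells)

    @property
    def tumor_cells(self) -> pd.DataFrame:
        """Non-excluded tumor-class cells — the only ones that are scored."""
        df = self.cells
        return df[(df["cell_class"] == "tumor") & (~df["excluded"])]

    def positive_fraction(self) -> float:
        """Fraction of scorable tumor cells with any positive reaction."""
        tc = self.tumor_cells
        if len(tc) == 0:
            return float("nan")
        return float((tc["stain_class"] != "negative").mean())

    def subset(self, x0: float, y0: float, x1: float, y1: float) -> pd.DataFrame:
        """Cells with centroid in the half-open box ``[x0,x1) x [y0,y1)``."""
        df = self.cells
        m = (
            (df["x_um"] >= x0)
            & (df["x_um"] < x1)
            & (df["y_um"] >= y0)
            & (df["y_um"] < y1)
        )
        return df[m]

    # ------------------------------ IO -------------------------------- #
    def to_csv(self, path: str | Path) -> None:
        cols = list(CELL_COLUMNS) + ["excluded"]
        self.cells.loc[:, cols].to_csv(path, index=False)

    def exclusions_to_geojson(self, path: str | Path) -> None:
        write_polygons_geojson(self.exclusions, path)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        width_um: float,
        height_um: float,
        exclusions_geojson: str | Path | None = None,
    ) -> "CellMap":
        df = pd.read_csv(path)
        bad = set(df["stain_class"].unique()) - set(STAIN_CLASSES)
        if bad:
            raise FormatError(f"unknown stain classes {sorted(bad)}")
        bad = set(df["cell_class"].unique()) - set(CELL_CLASSES)
        if bad:
            raise FormatError(f"unknown cell classes {sorted(bad)}")
        polys = (
            read_polygons_geojson(exclusions_geojson)
            if exclusions_geojson is not None
            else []
        )
        return cls(df, width_um, height_um, polys)


# ---------------------------------------------------------------------- #
# GeoJSON polygon round-trip (coordinates are slide micrometres)
# ---------------------------------------------------------------------- #
def write_polygons_geojson(polygons: Sequence[Polygon], path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"id": i}, "geometry": mapping(p)}
        for i, p in enumerate(polygons)
    ]
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_polygons_geojson(path: str | Path) -> list[Polygon]:
    doc = json.loads(Path(path).read_text())
    polys: list[Polygon] = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise GeometryError(f"expected Polygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise GeometryError("invalid polygon in GeoJSON")
        polys.append(geom)
    return polys


def points_in_any_polygon(
    x: np.ndarray, y: np.ndarray, polygons: Sequence[Polygon]
) -> np.ndarray:
    """Vectorised point-in-polygon test against a polygon set."""
    inside = np.zeros(len(x), dtype=bool)
    if not polygons:
        return inside
    pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
    for poly in polygons:
        inside |= shapely.contains(poly, pts)
    return inside
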