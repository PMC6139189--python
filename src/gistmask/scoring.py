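"""Per-case slide scores: HSPR%, nHSPR% and the heterogeneity delta.

HSPR% is the percentage of Ki-67-positive (weak or strong) tumor cells
among all analysed tumor cells pooled over the hotspot DOIs; nHSPR% is
the same ratio over the not-hotspot DOIs.  Pooling (sum of positives /
sum of totals) is the default; the mean of per-DOI ratios is available
as an alternative.  The heterogeneity delta HSPR% − nHSPR% quantifies
how much a hotspot-blind score would understate proliferative activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from shapely.geometry import box

from ._errors import GeometryError, UndefinedScoreError
from .cellmap import CellMap
from .hotspots import DOI, count_window


@dataclass
class SlideScore:
    """One case's digital-scoring summary."""

    hspr_pct: float
    nhspr_pct: float
    strong_hspr: int
    weak_hspr: int
    strong_nhspr: int
    weak_nhspr: int
    total_cells: int
    heterogeneity_pct: float
    density_per_mm2: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def score_doi(cell_map: CellMap, doi: DOI) -> DOI:
    """Fill a DOI's strong/weak/negative tumor-cell counts.

    Counts cover non-excluded tumor cells whose centroid lies in the
    half-open window.  Scoring a window that overlaps an exclusion
    polygon is a contract violation (such windows are invalid upstream).
    """
    window = box(*doi.bounds())
    if any(window.intersects(p) for p in cell_map.exclusions):
        raise GeometryError(
            "DOI overlaps an exclusion polygon; it should have been "
            "rejected during selection"
        )
    s, w, n = count_window(cell_map, doi.origin_x_um, doi.origin_y_um, doi.side_um)
    doi.n_strong, doi.n_weak, doi.n_negative = s, w, n
    return doi


def _pooled_pct(dois: Sequence[DOI], method: str) -> float:
    total = sum(d.n_total for d in dois)
    if method == "pooled":
        if total == 0:
            raise UndefinedScoreError("no analysable tumor cells in DOI set")
        return 100.0 * sum(d.n_positive for d in dois) / total
    # mean of per-DOI ratios
    ratios = []
    for d in dois:
        if d.n_total == 0:
            raise UndefinedScoreError("empty DOI in per-DOI averaging")
        ratios.append(d.n_positive / d.n_total)
    return 100.0 * sum(ratios) / len(ratios)


def compute_score(
    hotspot_dois: Sequence[DOI],
    nothotspot_dois: Sequence[DOI],
    method: Literal["pooled", "mean"] = "pooled",
) -> SlideScore:
    """Combine scored DOI sets into the per-case slide score.

    ``pooled`` divides total positives by total analysed cells across
    the DOI set (so larger windows weigh more); ``mean`` averages the
    per-DOI ratios.  Cell density is reported over the union of the
    hotspot DOIs, in cells/mm².
    """
    if not hotspot_dois or not nothotspot_dois:
        raise UndefinedScoreError("both DOI sets must be non-empty")
    hspr = _pooled_pct(hotspot_dois, method)
    nhspr = _pooled_pct(nothotspot_dois, method)
    hot_total = sum(d.n_total for d in hotspot_dois)
    hot_area_mm2 = sum(d.side_um**2 for d in hotspot_dois) / 1e6
    return SlideScore(
        hspr_pct=hspr,
        nhspr_pct=nhspr,
        strong_hspr=sum(d.n_strong for d in hotspot_dois),
        weak_hspr=sum(d.n_weak for d in hotspot_dois),
        strong_nhspr=sum(d.n_strong for d in nothotspot_dois),
        weak_nhspr=sum(d.n_weak for d in nothotspot_dois),
        total_cells=hot_total + sum(d.n_total for d in nothotspot_dois),
        heterogeneity_pct=hspr - nhspr,
        density_per_mm2=hot_total / hot_area_mm2,
    )
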