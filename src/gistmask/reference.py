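"""Published summary figures of the 57-patient GIST reference cohort.

The cohort this pipeline's statistics were designed around is not
public; what is available are its printed summary figures — the mean
number of analysed cells per 1500 µm hotspot window, the tercile group
sizes at the 3.5% / 10% score boundaries, and the per-tercile covariate
counts.  They are kept here as worked-example inputs: simple arithmetic
on them (implied cell density, implied cells per case, percentage
breakdowns) anchors the simulator's defaults and the acceptance checks.
"""

from __future__ import annotations

#: mean analysed cells in one 1500 µm x 1500 µm hotspot window (ROI)
CELLS_PER_ROI = 12_567
ROI_SIDE_UM = 1500.0
N_DOIS_PER_KIND = 5
#: reported slide-level cell density, cells per mm²
REPORTED_DENSITY_PER_MM2 = 5585.0

#: tercile boundaries on the hotspot score, percent
TERCILE_BOUNDS = (3.5, 10.0)
#: patients per tercile (low < 3.5%, moderate 3.5–10%, high >= 10%)
TERCILE_SIZES = (20, 17, 20)

#: per-tercile covariate counts (low, moderate, high)
TERCILE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "age_group": {"<=64": (11, 7, 11), ">64": (9, 10, 9)},
    "sex": {"female": (15, 9, 4), "male": (5, 8, 16)},
    "tumor_size": {"<=5cm": (14, 10, 7), ">5cm": (6, 7, 13)},
    "location": {"gastric": (15, 13, 12), "nongastric": (5, 4, 8)},
    "risk_group": {"gr_1-3": (19, 15, 8), "gr_4-6": (1, 2, 12)},
    "mitotic_score": {"0-5": (18, 15, 8), ">5": (2, 2, 12)},
    "total_cells": {"<25000": (5, 16, 9), ">=25000": (15, 1, 11)},
}


def implied_density_per_mm2() -> float:
    """Cell density the per-ROI mean implies, cells/mm²."""
    return CELLS_PER_ROI / (ROI_SIDE_UM / 1000.0) ** 2


def mean_cells_per_case() -> int:
    """Mean analysed cells per case over one five-window DOI set."""
    return N_DOIS_PER_KIND * CELLS_PER_ROI


def tercile_percentage(variable: str, level: str, tercile: int) -> float:
    """Recompute a printed percentage from the printed counts.

    ``tercile`` is 0 (low), 1 (moderate) or 2 (high); the denominator is
    that tercile's group size.
    """
    count = TERCILE_COUNTS[variable][level][tercile]
    return 100.0 * count / TERCILE_SIZES[tercile]
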