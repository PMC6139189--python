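"""Synthetic slides and cohorts with the statistical structure the
analysis assumes.

The slide generator lays down a homogeneous Poisson field of tumor nuclei
at a configurable density (default 5585 cells/mm², the density a 1500 µm
hotspot window of ~12.6k cells implies), superimposes Gaussian
proliferation hotspots in which the Ki-67-positive probability is raised,
splits positives into weak/strong DAB reactions, and scatters small,
round, mostly-positive lymphocytes preferentially inside simulated
ulceration/granulation zones — the confounder the masking stage must
exclude.

The cohort generator draws per-patient hotspot scores from a three-part
(tercile) mixture, links mitotic class / risk group / sex to the score
through logistic models, and attaches exponential recurrence-free
survival times with a proportional-hazards effect for the high-score
group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from skimage.color import combine_stains, rgb_from_hdx
from skimage.draw import ellipse as draw_ellipse

from ._errors import BoundsError, ConfigurationError
from .cellmap import CellMap, points_in_any_polygon

# Stain amounts used to render each class, in the normalised
# concentration units of skimage's H-DAB separation/recombination
# (1.0 spans the full dynamic range down to transmittance 1e-6).
# Negative nuclei are hematoxylin-blue, weak positives a light DAB
# brown, strong positives a dark DAB brown; the weak level sits between
# the default classification thresholds, the strong level well above
# (see masking.MaskingTemplate).
CLASS_OD = {
    "negative": (0.18, 0.005),  # (hematoxylin, DAB)
    "weak": (0.08, 0.11),
    "strong": (0.08, 0.32),
}
BACKGROUND_HEMA_OD = 0.007


def _check_frac(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SlideSimConfig:
    """Parameters of one simulated slide.

    Densities are cells per mm²; all lengths are micrometres.
    ``*_area_um2`` fields are (mean, sd) of a truncated normal.
    """

    width_um: float = 10_000.0
    height_um: float = 10_000.0
    base_density: float = 5585.0
    n_hotspots: int = 3
    hotspot_sigma_um: float = 600.0
    background_positive_frac: float = 0.02
    hotspot_positive_frac: float = 0.30
    strong_given_positive_frac: float = 0.15
    lymphocyte_frac: float = 0.05
    n_exclusion_zones: int = 2
    tumor_nucleus_area_um2: tuple[float, float] = (55.0, 12.0)
    lymphocyte_area_um2: tuple[float, float] = (22.0, 4.0)
    seed: int = 0

    def validate(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ConfigurationError("slide extents must be positive")
        if self.base_density < 0:
            raise ConfigurationError("base_density must be non-negative")
        for name in (
            "background_positive_frac",
            "hotspot_positive_frac",
            "strong_given_positive_frac",
            "lymphocyte_frac",
        ):
            _check_frac(name, getattr(self, name))
        if self.hotspot_positive_frac < self.background_positive_frac:
            raise ConfigurationError(
                "hotspot_positive_frac must be >= background_positive_frac"
            )
        if self.n_hotspots < 0 or self.n_exclusion_zones < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.hotspot_sigma_um <= 0:
            raise ConfigurationError("hotspot_sigma_um must be positive")
        if self.lymphocyte_area_um2[0] >= self.tumor_nucleus_area_um2[0]:
            raise ConfigurationError(
                "lymphocyte mean area must be below tumor mean area"
            )


@dataclass
class CohortSimConfig:
    """Parameters of one simulated patient cohort.

    ``tercile_targets`` are the low/moderate/high group fractions
    (default mirrors a 20/17/20 split of 57 patients);
    ``hspr_distribution_params`` gives (median, log-sd) of the log-normal
    hotspot score inside each tercile band; the bands themselves are
    ``hspr_tercile_bounds`` percent.  Recurrence times are exponential
    with ``baseline_hazard`` events/month, multiplied by
    ``hazard_ratio_high_vs_low`` in the top tercile.
    """

    n_patients: int = 57
    tercile_targets: tuple[float, float, float] = (20 / 57, 17 / 57, 20 / 57)
    hspr_tercile_bounds: tuple[float, float] = (3.5, 10.0)
    hspr_distribution_params: tuple[tuple[float, float], ...] = (
        (1.0, 0.7),
        (5.75, 0.5),
        (23.0, 0.6),
    )
    hazard_ratio_high_vs_low: float = 4.0
    baseline_hazard: float = 0.0015
    followup_months: float = 120.0
    censoring_rate: float = 0.3
    # logistic links from log-score to binary covariates: (intercept, slope)
    mitotic_link: tuple[float, float] = (-2.2, 0.83)
    sex_link: tuple[float, float] = (-1.1, 0.79)
    strong_share_link: tuple[float, float] = (-4.95, 1.05)
    # latent cutpoints (on score %) separating Miettinen-like groups 1..6
    miettinen_cutpoints: tuple[float, ...] = (0.5, 2.0, 5.0, 10.0, 16.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be at least 2")
        if abs(sum(self.tercile_targets) - 1.0) > 1e-6:
            raise ConfigurationError("tercile_targets must sum to 1")
        if any(t < 0 for t in self.tercile_targets):
            raise ConfigurationError("tercile_targets must be non-negative")
        if self.hazard_ratio_high_vs_low <= 0:
            raise ConfigurationError("hazard_ratio_high_vs_low must be positive")
        if self.baseline_hazard <= 0 or self.followup_months <= 0:
            raise ConfigurationError("hazard and follow-up must be positive")
        _check_frac("censoring_rate", self.censoring_rate)
        if len(self.hspr_distribution_params) != 3:
            raise ConfigurationError("need exactly three tercile distributions")


# ---------------------------------------------------------------------- #
# Slide generation
# ---------------------------------------------------------------------- #
def hotspot_positive_probability(
    x: np.ndarray,
    y: np.ndarray,
    centers: Sequence[tuple[float, float]],
    sigma_um: float,
    background: float,
    peak: float,
) -> np.ndarray:
    """Engineered positive probability at (x, y).

    Background level plus a Gaussian bump per hotspot,
    ``p = bg + (peak - bg) * exp(-d^2 / 2 sigma^2)`` using the nearest
    hotspot (max over bumps), capped at 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    kernel = np.zeros_like(x)
    for cx, cy in centers:
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        np.maximum(kernel, np.exp(-d2 / (2.0 * sigma_um**2)), out=kernel)
    return np.minimum(background + (peak - background) * kernel, 1.0)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lo: float
) -> np.ndarray:
    vals = rng.normal(mean, sd, n)
    bad = vals <= lo
    while bad.any():  # redraw the tail; converges fast for sane configs
        vals[bad] = rng.normal(mean, sd, bad.sum())
        bad = vals <= lo
    return vals


def _random_exclusion_zones(
    rng: np.random.Generator, config: SlideSimConfig
) -> list[Polygon]:
    """Irregular convex blobs emulating ulceration / granulation areas."""
    zones = []
    for _ in range(config.n_exclusion_zones):
        cx = rng.uniform(0.1, 0.9) * config.width_um
        cy = rng.uniform(0.1, 0.9) * config.height_um
        r = rng.uniform(400.0, 800.0)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 8))
        radii = r * rng.uniform(0.6, 1.0, 8)
        pts = np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
        poly = Polygon(pts).convex_hull.intersection(
            box(0, 0, config.width_um, config.height_um)
        )
        if poly.area > 0:
            zones.append(poly)
    return zones


def _sample_in_polygons(
    rng: np.random.Generator, polys: Sequence[Polygon], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points inside a polygon set, by rejection from bboxes."""
    from shapely.geometry import Point

    xs, ys = [], []
    areas = np.array([p.area for p in polys], float)
    choice = rng.choice(len(polys), size=n, p=areas / areas.sum())
    for i in range(n):
        poly = polys[choice[i]]
        minx, miny, maxx, maxy = poly.bounds
        for _ in range(1000):
            px, py = rng.uniform(minx, maxx), rng.uniform(miny, maxy)
            if poly.contains(Point(px, py)):
                xs.append(px)
                ys.append(py)
                break
        else:  # pragma: no cover - degenerate polygon
            xs.append(poly.centroid.x)
            ys.append(poly.centroid.y)
    return np.array(xs), np.array(ys)


def generate_cell_map(config: SlideSimConfig) -> CellMap:
    """Simulate one slide's digital cell map.

    Tumor nuclei form a homogeneous Poisson field at ``base_density``;
    each nucleus is Ki-67 positive with the hotspot-blended probability
    of :func:`hotspot_positive_probability` and, if positive, strong with
    ``strong_given_positive_frac``.  Lymphocytes (smaller, rounder,
    mostly positive) are placed preferentially inside the exclusion
    zones.  Fully deterministic under ``config.seed``.

    The returned map's ``meta`` carries the engineered ground truth
    (hotspot centres, sigma) and the tumor cells carry a
    ``true_p_positive`` column, so recovery tests can compare measured
    scores with the engineered probabilities.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    area_mm2 = config.width_um * config.height_um / 1e6
    expected_total = config.base_density * area_mm2

    n_tumor = rng.poisson(expected_total * (1.0 - config.lymphocyte_frac))
    n_lymph = rng.poisson(expected_total * config.lymphocyte_frac)

    # hotspot centres kept away from the border so the full bump is on-slide
    margin = min(1.5 * config.hotspot_sigma_um, 0.25 * min(config.width_um, config.height_um))
    centers = [
        (
            rng.uniform(margin, config.width_um - margin),
            rng.uniform(margin, config.height_um - margin),
        )
        for _ in range(config.n_hotspots)
    ]

    zones = _random_exclusion_zones(rng, config)

    # --- tumor cells ---------------------------------------------------
    tx = rng.uniform(0, config.width_um, n_tumor)
    ty = rng.uniform(0, config.height_um, n_tumor)
    p_pos = hotspot_positive_probability(
        tx,
        ty,
        centers,
        config.hotspot_sigma_um,
        config.background_positive_frac,
        config.hotspot_positive_frac,
    )
    positive = rng.uniform(size=n_tumor) < p_pos
    strong = positive & (rng.uniform(size=n_tumor) < config.strong_given_positive_frac)
    stain = np.where(strong, "strong", np.where(positive, "weak", "negative"))
    t_area = _truncated_normal(rng, *config.tumor_nucleus_area_um2, n_tumor, 5.0)
    t_circ = np.clip(rng.beta(8.0, 3.0, n_tumor), 1e-3, 1.0)

    # --- lymphocytes ----------------------------------------------------
    if n_lymph > 0:
        n_in_zone = int(round(0.8 * n_lymph)) if zones else 0
        if n_in_zone > 0:
            lx_in, ly_in = _sample_in_polygons(rng, zones, n_in_zone)
        else:
            lx_in = ly_in = np.empty(0)
        n_out = n_lymph - len(lx_in)
        lx = np.concatenate([lx_in, rng.uniform(0, config.width_um, n_out)])
        ly = np.concatenate([ly_in, rng.uniform(0, config.height_um, n_out)])
        l_positive = rng.uniform(size=n_lymph) < 0.9
        l_strong = l_positive & (rng.uniform(size=n_lymph) < 0.1)
        l_stain = np.where(l_strong, "strong", np.where(l_positive, "weak", "negative"))
        l_area = _truncated_normal(rng, *config.lymphocyte_area_um2, n_lymph, 5.0)
        l_circ = np.clip(rng.normal(0.93, 0.03, n_lymph), 1e-3, 1.0)
    else:
        lx = ly = l_area = l_circ = np.empty(0)
        l_stain = np.empty(0, dtype=object)

    n = n_tumor + n_lymph
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x_um": np.concatenate([tx, lx]),
            "y_um": np.concatenate([ty, ly]),
            "area_um2": np.concatenate([t_area, l_area]),
            "circularity": np.concatenate([t_circ, l_circ]),
            "stain_class": np.concatenate([stain, l_stain]),
            "cell_class": np.array(["tumor"] * n_tumor + ["lymphocyte"] * n_lymph),
            "true_p_positive": np.concatenate([p_pos, np.full(n_lymph, np.nan)]),
        }
    )
    meta = {
        "hotspot_centers": centers,
        "hotspot_sigma_um": config.hotspot_sigma_um,
        "config": config,
    }
    return CellMap(cells, config.width_um, config.height_um, zones, meta)


# ---------------------------------------------------------------------- #
# Tile rendering
# ---------------------------------------------------------------------- #
def render_tile(
    cell_map: CellMap,
    region: tuple[float, float, float, float],
    px_per_um: float = 1.0,
) -> np.ndarray:
    """Render a region of a cell map as an H-DAB brightfield RGB tile.

    Each nucleus is drawn as a filled ellipse (axes from its area and
    circularity, orientation a deterministic hash of its id) of
    class-specific hematoxylin/DAB optical density; the OD planes are
    recombined to RGB through the standard H-DAB stain matrix, so stain
    separation of the tile recovers the planes exactly.

    ``region`` is ``(x0, y0, x1, y1)`` in µm; image row 0 corresponds to
    ``y0`` (row index grows with y).  Returns a uint8 RGB array.
    """
    if px_per_um <= 0:
        raise ConfigurationError("px_per_um must be positive")
    x0, y0, x1, y1 = region
    if x1 <= x0 or y1 <= y0:
        raise BoundsError("empty region")
    if x0 < 0 or y0 < 0 or x1 > cell_map.width_um or y1 > cell_map.height_um:
        raise BoundsError(f"region {region} outside slide bounds")

    width_px = int(round((x1 - x0) * px_per_um))
    height_px = int(round((y1 - y0) * px_per_um))
    hema = np.full((height_px, width_px), BACKGROUND_HEMA_OD)
    dab = np.zeros((height_px, width_px))

    df = cell_map.cells
    pad = 2.0 * np.sqrt(df["area_um2"].max() / math.pi) if len(df) else 0.0
    sel = df[
        (df["x_um"] >= x0 - pad)
        & (df["x_um"] < x1 + pad)
        & (df["y_um"] >= y0 - pad)
        & (df["y_um"] < y1 + pad)
    ]
    for row in sel.itertuples():
        r_eq = math.sqrt(row.area_um2 / math.pi)  # equivalent radius, µm
        # elongation from circularity: a circle has circ 1; stretch the
        # ellipse (area preserved) as circularity drops
        stretch = 1.0 / max(row.circularity, 0.3) ** 0.75
        a = r_eq * stretch * px_per_um
        b = r_eq / stretch * px_per_um
        angle = (int(row.cell_id) * 2654435761 % 360) * math.pi / 180.0
        rr, cc = draw_ellipse(
            (row.y_um - y0) * px_per_um,
            (row.x_um - x0) * px_per_um,
            max(a, 1.0),
            max(b, 1.0),
            shape=(height_px, width_px),
            rotation=angle,
        )
        od_h, od_d = CLASS_OD[row.stain_class]
        hema[rr, cc] = np.maximum(hema[rr, cc], od_h)
        dab[rr, cc] = np.maximum(dab[rr, cc], od_d)

    stains = np.dstack([hema, dab, np.zeros_like(hema)])
    rgb = combine_stains(stains, rgb_from_hdx)
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------- #
# Cohort generation
# ---------------------------------------------------------------------- #
def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, float)))


def _quota_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n into len(fractions) groups."""
    raw = np.asarray(fractions, float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base.tolist()


def _truncated_lognormal(
    rng: np.random.Generator,
    median: float,
    sigma: float,
    n: int,
    lo: float,
    hi: float,
) -> np.ndarray:
    mu = math.log(median)
    out = np.empty(n)
    filled = 0
    for _ in range(200):
        draw = rng.lognormal(mu, sigma, 4 * max(n, 8))
        good = draw[(draw >= lo) & (draw < hi)]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
        if filled == n:
            break
    if filled < n:  # extremely mis-specified band: fall back to uniform
        out[filled:] = rng.uniform(lo, min(hi, lo + 4 * median), n - filled)
    return out


def generate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a patient cohort with a tercile score structure.

    Hotspot scores are drawn per tercile band by quota sampling (group
    sizes are exact), covariates (sex, mitotic class, risk group) follow
    logistic/cutpoint links to log-score, and recurrence-free survival is
    exponential with the configured hazard ratio for the top tercile,
    under independent administrative censoring.

    Returns a DataFrame with one row per patient: identifiers,
    covariates, hotspot/not-hotspot scores and per-DOI-set weak/strong
    counts, RFS time (months) and event flag, plus the generating
    ``true_tercile`` for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    b1, b2 = config.hspr_tercile_bounds
    bands = [(0.0, b1), (b1, b2), (b2, 100.0)]
    counts = _quota_counts(config.n_patients, config.tercile_targets)

    hspr_parts, tercile_parts = [], []
    for t, ((med, sig), (lo, hi), k) in enumerate(
        zip(config.hspr_distribution_params, bands, counts)
    ):
        hspr_parts.append(_truncated_lognormal(rng, med, sig, k, lo, hi))
        tercile_parts.append(np.full(k, t))
    hspr = np.concatenate(hspr_parts)
    tercile = np.concatenate(tercile_parts).astype(int)
    n = len(hspr)
    order = rng.permutation(n)  # shuffle so patient id is uninformative
    hspr, tercile = hspr[order], tercile[order]

    log_h = np.log(np.maximum(hspr, 1e-3))
    nhspr = hspr * rng.beta(2.0, 4.0, n)  # not-hotspot score below hotspot

    a, b = config.mitotic_link
    mitotic_high = rng.uniform(size=n) < _sigmoid(a + b * log_h)
    a, b = config.sex_link
    male = rng.uniform(size=n) < _sigmoid(a + b * log_h)

    latent = np.exp(log_h + rng.normal(0.0, 0.5, n))
    group = 1 + np.searchsorted(np.asarray(config.miettinen_cutpoints), latent)

    age = np.clip(rng.normal(62.2, 13.8, n), 31, 89).round(0)
    size_cm = np.round(np.exp(rng.normal(math.log(5.0), 0.45, n) + 0.05 * log_h), 1)
    gastric = rng.uniform(size=n) < 0.7

    total_cells = rng.lognormal(math.log(24_000.0), 0.25, n).round().astype(int)
    hot_cells = total_cells // 2
    pos_h = np.round(hspr / 100.0 * hot_cells).astype(int)
    pos_nh = np.round(nhspr / 100.0 * (total_cells - hot_cells)).astype(int)
    a, b = config.strong_share_link
    share = _sigmoid(a + b * log_h)
    strong_h = np.round(pos_h * share).astype(int)
    strong_nh = np.round(pos_nh * share * 0.8).astype(int)

    high = tercile == 2
    rate = config.baseline_hazard * np.where(high, config.hazard_ratio_high_vs_low, 1.0)
    t_event = rng.exponential(1.0 / rate)
    c_admin = np.where(
        rng.uniform(size=n) < config.censoring_rate,
        rng.uniform(0, config.followup_months, n),
        config.followup_months,
    )
    rfs = np.minimum(t_event, c_admin)
    event = t_event <= c_admin

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "age_years": age,
            "sex": np.where(male, "male", "female"),
            "tumor_size_cm": size_cm,
            "location": np.where(gastric, "gastric", "nongastric"),
            "miettinen_group": group,
            "mitotic_class": np.where(mitotic_high, ">5", "0-5"),
            "hspr_pct": np.round(hspr, 2),
            "nhspr_pct": np.round(nhspr, 2),
            "strong_hspr": strong_h,
            "weak_hspr": pos_h - strong_h,
            "strong_nhspr": strong_nh,
            "weak_nhspr": pos_nh - strong_nh,
            "total_cells": total_cells,
            "rfs_months": np.round(rfs, 2),
            "recurrence_event": event,
            "true_tercile": tercile,
        }
    )
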