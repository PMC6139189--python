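"""The digital masking stage: from an RGB tile to classified cell records.

Separates the H-DAB stains by colour deconvolution onto fixed standard
stain vectors, segments nuclei on the combined optical density (with a
distance-transform watershed to split touching nuclei), measures each
candidate (centroid, area, circularity, mean per-stain OD), then applies
an intensity + shape/size template: the DAB OD thresholds code each
nucleus negative / weak / strong, and small round positive nuclei are
flagged as lymphocytes so they never inflate the tumor score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import hdx_from_rgb, separate_stains
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from ._errors import ConfigurationError, FormatError

__all__ = [
    "MaskingTemplate",
    "NucleusCandidate",
    "separate_stains_od",
    "detect_nuclei",
    "classify_cells",
    "mask_tile",
]


@dataclass(frozen=True)
class NucleusCandidate:
    """One segmented nucleus, prior to classification."""

    centroid_x_um: float
    centroid_y_um: float
    area_um2: float
    circularity: float
    mean_dab_od: float
    mean_hema_od: float


@dataclass(frozen=True)
class MaskingTemplate:
    """Intensity and shape/size gates for nucleus classification.

    The DAB band between ``weak_od_threshold`` and ``strong_od_threshold``
    codes "weak"; at or above the strong threshold codes "strong".
    Candidates outside ``[min_area_um2, max_area_um2]`` are dropped as
    debris/clumps.  A positive nucleus no larger than
    ``lymphocyte_max_area_um2`` and at least ``min_circularity`` round is
    classed as a lymphocyte.  Defaults were fixed once by training on
    simulated tiles rendered with the package's own stain model.
    """

    weak_od_threshold: float = 0.05
    strong_od_threshold: float = 0.21
    min_area_um2: float = 10.0
    max_area_um2: float = 300.0
    min_circularity: float = 0.80
    lymphocyte_max_area_um2: float = 32.0

    def validate(self) -> None:
        if not (self.strong_od_threshold > self.weak_od_threshold >= 0):
            raise ConfigurationError(
                "need strong_od_threshold > weak_od_threshold >= 0"
            )
        if not (self.max_area_um2 > self.min_area_um2 > 0):
            raise ConfigurationError("need max_area > min_area > 0")
        if not (0 < self.min_circularity <= 1):
            raise ConfigurationError("min_circularity must be in (0, 1]")


def separate_stains_od(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deconvolve an RGB tile into hematoxylin and DAB OD planes.

    Uses the fixed standard H-DAB stain matrix; outputs are clipped to be
    non-negative.  Returns ``(hema_od, dab_od)`` float arrays of the
    image's spatial shape.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected an RGB image, got shape {image.shape}")
    if image.dtype == np.uint8:
        img = image.astype(float) / 255.0
    else:
        img = image.astype(float)
        if img.max() > 1.0 + 1e-9:
            raise FormatError("float images must be scaled to [0, 1]")
    stains = separate_stains(img, hdx_from_rgb)
    hema = np.clip(stains[..., 0], 0.0, None)
    dab = np.clip(stains[..., 1], 0.0, None)
    return hema, dab


def detect_nuclei(
    hema_od: np.ndarray,
    dab_od: np.ndarray,
    px_per_um: float,
    *,
    od_foreground_threshold: float = 0.05,
    min_peak_distance_um: float = 2.0,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> list[NucleusCandidate]:
    """Segment and measure nuclei on the combined OD foreground.

    Foreground is ``hema + dab OD > od_foreground_threshold``; touching
    nuclei are split by a watershed on the negated distance transform
    seeded at distance-transform peaks at least ``min_peak_distance_um``
    apart.  Candidates are measured in µm (centroids offset by
    ``origin_um``, the tile's slide position) and kept when their
    centroid lies inside the tile, so half-open tiling never counts a
    border nucleus twice.
    """
    if px_per_um <= 0:
        raise ConfigurationError("px_per_um must be positive")
    hema_od = np.asarray(hema_od, float)
    dab_od = np.asarray(dab_od, float)
    if hema_od.shape != dab_od.shape:
        raise FormatError("stain channels must have the same shape")

    combined = hema_od + dab_od
    foreground = combined > od_foreground_threshold
    if not foreground.any():
        return []

    distance = ndimage.distance_transform_edt(foreground)
    min_dist_px = max(int(round(min_peak_distance_um * px_per_um)), 1)
    peaks = peak_local_max(
        distance,
        min_distance=min_dist_px,
        labels=cc_label(foreground),
        exclude_border=False,
    )
    markers = np.zeros_like(distance, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers = cc_label(foreground)
    labels = watershed(-distance, markers, mask=foreground)

    x0, y0 = origin_um
    h, w = foreground.shape
    out: list[NucleusCandidate] = []
    for prop in regionprops(labels, intensity_image=None):
        if prop.area < 3:  # sub-resolution specks
            continue
        cy, cx = prop.centroid
        if not (0 <= cy < h and 0 <= cx < w):
            continue
        area_um2 = prop.area / px_per_um**2
        perim = prop.perimeter_crofton
        circ = min(4 * np.pi * prop.area / perim**2, 1.0) if perim > 0 else 1.0
        region = labels == prop.label
        out.append(
            NucleusCandidate(
                centroid_x_um=cx / px_per_um + x0,
                centroid_y_um=cy / px_per_um + y0,
                area_um2=area_um2,
                circularity=circ,
                mean_dab_od=float(dab_od[region].mean()),
                mean_hema_od=float(hema_od[region].mean()),
            )
        )
    return out


def classify_cells(
    candidates: list[NucleusCandidate], template: MaskingTemplate
) -> pd.DataFrame:
    """Apply the masking template to segmented candidates.

    Returns a cell-record DataFrame (schema of
    :data:`gistmask.cellmap.CELL_COLUMNS`): stain class from the mean DAB
    OD against the weak/strong thresholds, lymphocyte class for small
    round positives, and candidates outside the area gates dropped.  The
    number of dropped candidates is recorded in ``df.attrs["n_dropped"]``.
    """
    template.validate()
    rows = []
    n_dropped = 0
    for i, c in enumerate(candidates):
        if not (template.min_area_um2 <= c.area_um2 <= template.max_area_um2):
            n_dropped += 1
            continue
        if c.mean_dab_od >= template.strong_od_threshold:
            stain = "strong"
        elif c.mean_dab_od >= template.weak_od_threshold:
            stain = "weak"
        else:
            stain = "negative"
        is_lymph = (
            stain != "negative"
            and c.area_um2 <= template.lymphocyte_max_area_um2
            and c.circularity >= template.min_circularity
        )
        rows.append(
            {
                "cell_id": i,
                "x_um": c.centroid_x_um,
                "y_um": c.centroid_y_um,
                "area_um2": c.area_um2,
                "circularity": c.circularity,
                "stain_class": stain,
                "cell_class": "lymphocyte" if is_lymph else "tumor",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "x_um",
            "y_um",
            "area_um2",
            "circularity",
            "stain_class",
            "cell_class",
        ],
    )
    df.attrs["n_dropped"] = n_dropped
    return df


def match_to_reference(
    detected: pd.DataFrame,
    reference: pd.DataFrame,
    max_distance_um: float = 5.0,
) -> pd.DataFrame:
    """Greedy one-to-one nearest-neighbour match of detected cells to a
    reference cell table (e.g. simulator ground truth).

    Returns a DataFrame with one row per matched pair: the match
    distance and both records' stain/cell classes, for confusion-matrix
    style evaluation of the masking stage.
    """
    from scipy.spatial import cKDTree

    if len(detected) == 0 or len(reference) == 0:
        return pd.DataFrame(
            columns=["distance_um", "ref_stain", "det_stain", "ref_class", "det_class"]
        )
    tree = cKDTree(detected[["x_um", "y_um"]].to_numpy())
    dist, idx = tree.query(
        reference[["x_um", "y_um"]].to_numpy(), distance_upper_bound=max_distance_um
    )
    ok = np.isfinite(dist) & (dist < max_distance_um)
    rows = []
    used: set[int] = set()
    for ref_i in np.nonzero(ok)[0][np.argsort(dist[ok])]:
        det_i = int(idx[ref_i])
        if det_i in used:
            continue
        used.add(det_i)
        rows.append(
            {
                "distance_um": float(dist[ref_i]),
                "ref_stain": reference["stain_class"].iloc[ref_i],
                "det_stain": detected["stain_class"].iloc[det_i],
                "ref_class": reference["cell_class"].iloc[ref_i],
                "det_class": detected["cell_class"].iloc[det_i],
            }
        )
    return pd.DataFrame(rows)


def mask_tile(
    image: np.ndarray,
    px_per_um: float,
    template: MaskingTemplate | None = None,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Full masking of one tile: separate stains, detect, classify."""
    template = template or MaskingTemplate()
    hema, dab = separate_stains_od(image)
    candidates = detect_nuclei(hema, dab, px_per_um, origin_um=origin_um)
    return classify_cells(candidates, template)
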