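import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gistmask as gm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_map(
    points,
    width_um=1000.0,
    height_um=1000.0,
    exclusions=(),
):
    """Build a CellMap from (x, y, stain_class[, cell_class]) tuples."""
    rows = []
    for i, p in enumerate(points):
        x, y, stain = p[0], p[1], p[2]
        cls = p[3] if len(p) > 3 else "tumor"
        area = 22.0 if cls == "lymphocyte" else 55.0
        circ = 0.95 if cls == "lymphocyte" else 0.75
        rows.append(
            {
                "cell_id": i,
                "x_um": float(x),
                "y_um": float(y),
                "area_um2": area,
                "circularity": circ,
                "stain_class": stain,
                "cell_class": cls,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "x_um", "y_um", "area_um2", "circularity",
            "stain_class", "cell_class",
        ],
    )
    return gm.CellMap(df, width_um, height_um, list(exclusions))


@pytest.fixture(scope="session")
def hotspot_slide():
    """One mid-size slide with a single strong engineered hotspot."""
    cfg = gm.SlideSimConfig(
        width_um=5000.0,
        height_um=5000.0,
        n_hotspots=1,
        hotspot_sigma_um=700.0,
        background_positive_frac=0.02,
        hotspot_positive_frac=0.35,
        n_exclusion_zones=0,
        lymphocyte_frac=0.0,
        seed=42,
    )
    return gm.generate_cell_map(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    return gm.generate_cohort(gm.CohortSimConfig(seed=7))
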