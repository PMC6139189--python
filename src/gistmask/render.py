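"""Dot-map rendering of a digital cell map.

The map uses the conventional overview colour code for nuclear Ki-67
scoring: yellow dots for strong expression, red for weak, blue for
negative nuclei, with selected DOI rectangles and exclusion polygons
overlaid.  Rendering is plain numpy rasterisation so tests can count
blobs and check overlay coordinates exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import disk, polygon_perimeter

from .cellmap import CellMap
from .hotspots import DOI

DOT_COLORS = {
    "strong": (255, 220, 0),  # yellow
    "weak": (255, 0, 0),  # red
    "negative": (0, 70, 255),  # blue
}
LYMPHOCYTE_COLOR = (160, 160, 160)
DOI_COLORS = {"hotspot": (0, 0, 0), "not_hotspot": (0, 150, 0)}
EXCLUSION_COLOR = (130, 80, 150)
BACKGROUND = (255, 255, 255)


def render_map(
    cell_map: CellMap,
    dois: Sequence[DOI] = (),
    px_per_um: float = 0.05,
    dot_radius_px: int = 1,
    show_lymphocytes: bool = True,
    path: str | Path | None = None,
) -> np.ndarray:
    """Render the slide overview dot map; optionally write a PNG.

    Row 0 of the image corresponds to y = 0 µm (y grows downward in the
    raster); a µm position maps to pixel ``(round(y*s), round(x*s))``.
    """
    h = max(int(round(cell_map.height_um * px_per_um)), 1)
    w = max(int(round(cell_map.width_um * px_per_um)), 1)
    img = np.full((h, w, 3), BACKGROUND, dtype=np.uint8)

    def _draw_poly_outline(xs_um, ys_um, color):
        rr, cc = polygon_perimeter(
            np.clip(np.round(np.asarray(ys_um) * px_per_um).astype(int), 0, h - 1),
            np.clip(np.round(np.asarray(xs_um) * px_per_um).astype(int), 0, w - 1),
            shape=(h, w),
        )
        img[rr, cc] = color

    for poly in cell_map.exclusions:
        xs, ys = poly.exterior.coords.xy
        _draw_poly_outline(xs, ys, EXCLUSION_COLOR)

    # stamp dots via a small disk stencil; negatives first so the
    # sparser positive dots stay on top
    dy, dx = disk((0, 0), dot_radius_px + 0.5)
    df = cell_map.cells
    for stain in ("negative", "weak", "strong"):
        sub = df[df["stain_class"] == stain]
        if not show_lymphocytes:
            sub = sub[sub["cell_class"] == "tumor"]
        for cls, color in (
            ("lymphocyte", LYMPHOCYTE_COLOR),
            ("tumor", DOT_COLORS[stain]),
        ):
            pts = sub[sub["cell_class"] == cls]
            rows = np.round(pts["y_um"].to_numpy() * px_per_um).astype(int)
            cols = np.round(pts["x_um"].to_numpy() * px_per_um).astype(int)
            for oy, ox in zip(dy, dx):
                rr = np.clip(rows + oy, 0, h - 1)
                cc = np.clip(cols + ox, 0, w - 1)
                img[rr, cc] = color

    for doi in dois:
        x0, y0, x1, y1 = doi.bounds()
        _draw_poly_outline([x0, x1, x1, x0], [y0, y0, y1, y1], DOI_COLORS[doi.kind])

    if path is not None:
        Image.fromarray(img).save(path)
    return img
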