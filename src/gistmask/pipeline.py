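"""One-call pipeline: simulate -> (render + mask) -> select -> score ->
cohort statistics, with every artifact written to a run directory.

Reruns with the same configuration produce byte-identical CSV outputs;
the run manifest records the configuration (and its hash), the seed and
the library versions used, so a run directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._errors import GistMaskError
from .cellmap import CellMap, write_polygons_geojson
from .hotspots import DOI, apply_exclusions, compute_density_grid, select_dois
from .masking import MaskingTemplate, mask_tile
from .render import render_map
from .report import analyse_cohort
from .scoring import compute_score
from .simulate import CohortSimConfig, SlideSimConfig, generate_cell_map, render_tile

logger = logging.getLogger("gistmask")


@dataclass
class PipelineConfig:
    """Everything one run needs; validated before any stage executes."""

    slide: SlideSimConfig = field(default_factory=SlideSimConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    template: MaskingTemplate = field(default_factory=MaskingTemplate)
    side_um: float = 1500.0
    stride_um: float = 250.0
    k: int = 5
    min_cells: int = 500
    nothotspot_mode: str = "median"
    score_method: str = "pooled"
    tercile_boundaries: tuple[float, float] | None = (3.5, 10.0)
    positive_class: str = "groups56"
    or_cutoff_pct: float = 16.0
    km_split_pct: float = 10.0
    mask_demo: bool = True  # render + re-mask one tile as a stage check
    mask_demo_tile_um: float = 400.0
    render_overview: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed drives every stage deterministically
        self.slide = dataclasses.replace(self.slide, seed=self.seed)
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed + 1)
        self.slide.validate()
        self.cohort.validate()
        self.template.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class StageError(GistMaskError):
    """A pipeline stage failed; earlier artifacts remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except GistMaskError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise StageError(name, exc) from exc
            logger.info("stage %-8s %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapper

    return deco


@dataclass
class PipelineResult:
    out_dir: Path
    cell_map: CellMap
    hotspot_dois: list[DOI]
    nothotspot_dois: list[DOI]
    slide_score: "pd.DataFrame"
    cohort: pd.DataFrame
    analysis: object


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute every stage and write the artifact directory.

    Artifacts: ``cells.csv`` + ``exclusions.geojson`` (simulated map),
    ``tile.png`` + ``masked_cells.csv`` (mask-stage demo), ``dois.csv``
    + ``dois.geojson`` (selected windows), ``slide_score.csv``,
    ``cohort.csv``, ``report.md`` + per-test CSVs, ``map.png`` and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("simulate")
    def s_simulate():
        cm = generate_cell_map(config.slide)
        cm.to_csv(out / "cells.csv")
        write_polygons_geojson(cm.exclusions, out / "exclusions.geojson")
        return cm

    @_stage("mask")
    def s_mask(cm: CellMap):
        # render one tile at the first hotspot and push it back through
        # the masking stage: a built-in consistency check of the run
        cx, cy = cm.meta.get("hotspot_centers", [(cm.width_um / 2, cm.height_um / 2)])[0]
        half = config.mask_demo_tile_um / 2
        x0 = float(np.clip(cx - half, 0, cm.width_um - 2 * half))
        y0 = float(np.clip(cy - half, 0, cm.height_um - 2 * half))
        region = (x0, y0, x0 + 2 * half, y0 + 2 * half)
        tile = render_tile(cm, region, px_per_um=2.0)
        Image.fromarray(tile).save(out / "tile.png")
        recs = mask_tile(tile, 2.0, config.template, origin_um=(x0, y0))
        recs.to_csv(out / "masked_cells.csv", index=False)
        return recs

    @_stage("select")
    def s_select(cm: CellMap):
        cm = apply_exclusions(cm, cm.exclusions)
        grid = compute_density_grid(
            cm, config.side_um, config.stride_um, config.min_cells
        )
        hot = select_dois(grid, cm, config.k, "hotspot")
        not_hot = select_dois(
            grid, cm, config.k, "not_hotspot", config.nothotspot_mode, avoid=hot
        )
        rows = [
            {
                "kind": d.kind,
                "origin_x_um": d.origin_x_um,
                "origin_y_um": d.origin_y_um,
                "side_um": d.side_um,
                "n_strong": d.n_strong,
                "n_weak": d.n_weak,
                "n_negative": d.n_negative,
                "n_total": d.n_total,
            }
            for d in hot + not_hot
        ]
        pd.DataFrame(rows).to_csv(out / "dois.csv", index=False)
        from shapely.geometry import box

        write_polygons_geojson(
            [box(*d.bounds()) for d in hot + not_hot], out / "dois.geojson"
        )
        return cm, grid, hot, not_hot

    @_stage("score")
    def s_score(hot, not_hot):
        score = compute_score(hot, not_hot, config.score_method)
        df = pd.DataFrame([score.as_dict()])
        df.to_csv(out / "slide_score.csv", index=False)
        return df

    @_stage("cohort")
    def s_cohort():
        from .simulate import generate_cohort

        cohort = generate_cohort(config.cohort)
        cohort.to_csv(out / "cohort.csv", index=False)
        return cohort

    @_stage("stats")
    def s_stats(cohort):
        analysis = analyse_cohort(
            cohort,
            config.tercile_boundaries,
            config.positive_class,
            config.or_cutoff_pct,
            config.km_split_pct,
            seed=config.seed,
        )
        (out / "report.md").write_text(analysis.markdown)
        analysis.tercile_table.to_csv(out / "tercile_table.csv", index=False)
        pd.DataFrame([dataclasses.asdict(analysis.roc)]).drop(
            columns=["fpr", "tpr", "thresholds"]
        ).to_csv(out / "roc.csv", index=False)
        orr = analysis.or_result
        pd.DataFrame(
            [
                {
                    "or_value": orr.or_value,
                    "ci_low": orr.ci_low,
                    "ci_high": orr.ci_high,
                    "p_value": orr.p_value,
                    "haldane_corrected": orr.haldane_corrected,
                }
            ]
        ).to_csv(out / "odds_ratio.csv", index=False)
        km = []
        for name, curve in analysis.logrank.curves.items():
            km.append(curve.assign(group=name))
        pd.concat(km, ignore_index=True).to_csv(out / "km_curves.csv", index=False)
        return analysis

    @_stage("render")
    def s_render(cm, dois):
        render_map(cm, dois, path=out / "map.png")

    cell_map = s_simulate()
    if config.mask_demo:
        s_mask(cell_map)
    cm_excl, grid, hot, not_hot = s_select(cell_map)
    score_df = s_score(hot, not_hot)
    cohort = s_cohort()
    analysis = s_stats(cohort)
    if config.render_overview:
        s_render(cm_excl, hot + not_hot)

    import gistmask

    manifest = {
        "package": "gistmask",
        "version": gistmask.__version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return PipelineResult(out, cm_excl, hot, not_hot, score_df, cohort, analysis)
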