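"""Cohort analysis: the full statistical battery plus a Markdown report.

Given a scored cohort table, this runs the tercile breakdown of every
covariate (median/IQR or count/percent per score tercile with the
appropriate group test), the ROC analysis of the hotspot score against
the very-high-risk group, the odds ratio at a fixed score cut-off, and
the two-group Kaplan–Meier / log-rank recurrence-free survival
comparison at a score split — and lays the results out as a
three-column tercile table the way such cohorts are conventionally
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DegenerateInputError
from .stats import (
    GroupTestResult,
    LogrankResult,
    OrResult,
    RocResult,
    compare_groups,
    km_logrank,
    odds_ratio,
    roc_analysis,
    spearman_corr,
    tercile_split,
)

TERCILE_NAMES = ("low", "moderate", "high")


@dataclass
class CohortAnalysis:
    """All computed cohort results plus the rendered Markdown report."""

    tercile_boundaries: tuple[float, float]
    tercile_sizes: tuple[int, int, int]
    tercile_table: pd.DataFrame
    roc: RocResult
    or_result: OrResult
    logrank: LogrankResult
    spearman: dict[str, tuple[float, float]]
    markdown: str = field(repr=False, default="")


def _median_iqr(x: pd.Series) -> str:
    q1, med, q3 = np.percentile(x.astype(float), [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _continuous_rows(
    label: str, values: pd.Series, terciles: np.ndarray
) -> tuple[dict, GroupTestResult]:
    test = compare_groups(values, terciles, kind="continuous")
    row = {"characteristic": label}
    for t in range(3):
        row[TERCILE_NAMES[t]] = _median_iqr(values[terciles == t])
    row["test"] = test.test
    row["p_value"] = test.p_value
    return row, test

def _categorical_rows(
    label: str, values: pd.Series, terciles: np.ndarray, seed: int
) -> tuple[list[dict], GroupTestResult]:
    test = compare_groups(values, terciles, kind="categorical", seed=seed)
    rows = [{"characteristic": label, "test": test.test, "p_value": test.p_value}]
    sizes = np.bincount(terciles, minlength=3)
    for level in sorted(values.unique(), key=str):
        row = {"characteristic": f"  {level}"}
        for t in range(3):
            n = int(((values == level) & (terciles == t)).sum())
            pct = 100.0 * n / sizes[t] if sizes[t] else float("nan")
            row[TERCILE_NAMES[t]] = f"{n} ({pct:.1f}%)"
        rows.append(row)
    return rows, test


def analyse_cohort(
    cohort: pd.DataFrame,
    tercile_boundaries: tuple[float, float] | None = (3.5, 10.0),
    positive_class: str = "groups56",
    or_cutoff_pct: float = 16.0,
    km_split_pct: float = 10.0,
    seed: int = 0,
) -> CohortAnalysis:
    """Run the full cohort battery on a scored cohort table.

    Parameters
    ----------
    cohort
        One row per patient with the CohortRecord schema (covariates,
        ``hspr_pct``/``nhspr_pct`` scores, ``rfs_months`` and
        ``recurrence_event``), plus optional per-DOI-set count columns.
    tercile_boundaries
        Fixed score boundaries for the tercile table (percent); ``None``
        uses the empirical 1/3 and 2/3 quantiles.
    positive_class
        ``"groups56"`` treats risk groups 5–6 as the positive class of
        the ROC / odds-ratio analyses; ``"esmo_gt3"`` uses groups > 3.
    or_cutoff_pct
        Score cut-off for the 2x2 odds-ratio table.
    km_split_pct
        Score split for the recurrence-free-survival log-rank test.
    """
    terciles, bounds = tercile_split(
        cohort["hspr_pct"].to_numpy(), tercile_boundaries
    )
    sizes = tuple(int(s) for s in np.bincount(terciles, minlength=3))

    rows: list[dict] = []
    tests: dict[str, GroupTestResult] = {}

    def add_continuous(label, col):
        if col not in cohort:
            return
        row, test = _continuous_rows(label, cohort[col], terciles)
        rows.append(row)
        tests[label] = test

    def add_categorical(label, values):
        rs, test = _categorical_rows(label, values, terciles, seed)
        rows.extend(rs)
        tests[label] = test

    add_continuous("Age (years)", "age_years")
    add_categorical(
        "Age group", pd.Series(np.where(cohort["age_years"] <= 64, "<=64", ">64"))
    )
    add_categorical("Sex", cohort["sex"])
    add_continuous("Tumor size (cm)", "tumor_size_cm")
    add_categorical(
        "Tumor size group",
        pd.Series(np.where(cohort["tumor_size_cm"] <= 5, "<=5cm", ">5cm")),
    )
    add_categorical("Tumor location", cohort["location"])
    add_categorical(
        "GIST group",
        pd.Series(np.where(cohort["miettinen_group"] <= 3, "gr_1-3", "gr_4-6")),
    )
    add_categorical("Mitotic score", cohort["mitotic_class"])
    add_continuous("Strong HSPR (items per DOI set)", "strong_hspr")
    add_continuous("Strong nHSPR (items per DOI set)", "strong_nhspr")
    add_continuous("Weak HSPR (items per DOI set)", "weak_hspr")
    add_continuous("Weak nHSPR (items per DOI set)", "weak_nhspr")
    add_continuous("nHSPR%", "nhspr_pct")
    rows_het, t_het = _continuous_rows(
        "HSPR% minus nHSPR%",
        cohort["hspr_pct"] - cohort["nhspr_pct"],
        terciles,
    )
    rows.append(rows_het)
    tests["HSPR% minus nHSPR%"] = t_het
    add_continuous("Total number of cells", "total_cells")

    tercile_table = pd.DataFrame(
        rows, columns=["characteristic", *TERCILE_NAMES, "test", "p_value"]
    )

    # --- cut-off statistics -------------------------------------------
    if positive_class == "groups56":
        labels = (cohort["miettinen_group"] >= 5).astype(int)
    elif positive_class == "esmo_gt3":
        labels = (cohort["miettinen_group"] > 3).astype(int)
    else:
        raise DegenerateInputError(f"unknown positive_class {positive_class!r}")
    roc = roc_analysis(cohort["hspr_pct"].to_numpy(), labels.to_numpy())

    above = cohort["hspr_pct"] > or_cutoff_pct
    table = [
        [int((above & (labels == 1)).sum()), int((above & (labels == 0)).sum())],
        [int((~above & (labels == 1)).sum()), int((~above & (labels == 0)).sum())],
    ]
    orr = odds_ratio(table)

    km_groups = np.where(cohort["hspr_pct"] >= km_split_pct, "high", "low")
    logrank = km_logrank(
        cohort["rfs_months"].to_numpy(),
        cohort["recurrence_event"].to_numpy(),
        km_groups,
    )

    spearman = {}
    for col in ("weak_hspr", "strong_hspr", "nhspr_pct"):
        if col in cohort and cohort[col].nunique() > 1:
            spearman[col] = spearman_corr(cohort["hspr_pct"], cohort[col])

    md = _markdown(
        bounds, sizes, tercile_table, roc, orr, logrank, spearman,
        positive_class, or_cutoff_pct, km_split_pct, len(cohort),
    )
    return CohortAnalysis(
        tercile_boundaries=bounds,
        tercile_sizes=sizes,
        tercile_table=tercile_table,
        roc=roc,
        or_result=orr,
        logrank=logrank,
        spearman=spearman,
        markdown=md,
    )


def _markdown(
    bounds, sizes, table, roc, orr, logrank, spearman,
    positive_class, or_cutoff, km_split, n,
) -> str:
    lines = [
        "# Cohort analysis report",
        "",
        f"Patients: {n}. Score terciles at {bounds[0]:g}% and {bounds[1]:g}% "
        f"(group sizes {sizes[0]}/{sizes[1]}/{sizes[2]}).",
        "",
        "## Characteristics by HSPR% tercile",
        "",
        "| Characteristic | Low | Moderate | High | Test | p |",
        "|---|---|---|---|---|---|",
    ]
    def fmt(v):
        return "" if (v is None or (isinstance(v, float) and pd.isna(v))) else v

    for r in table.itertuples(index=False):
        p = "" if pd.isna(r.p_value) else f"{r.p_value:.4g}"
        lines.append(
            f"| {r.characteristic} | {fmt(r.low)} | {fmt(r.moderate)} | "
            f"{fmt(r.high)} | {fmt(r.test)} | {p} |"
        )
    lines += [
        "",
        "## ROC analysis of HSPR% vs risk group",
        "",
        f"Positive class: {positive_class}. "
        f"AUC = {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f}, "
        f"p = {roc.p_value:.3g}); Youden-optimal cut-off = "
        f"{roc.optimal_cutoff:.2f}% (sensitivity {roc.sensitivity:.2f}, "
        f"specificity {roc.specificity:.2f}).",
        "",
        f"## Odds ratio at HSPR% > {or_cutoff:g}%",
        "",
        f"OR = {orr.or_value:.1f} (95% CI {orr.ci_low:.1f}-{orr.ci_high:.1f}, "
        f"p = {orr.p_value:.3g})"
        + (" [Haldane-corrected]" if orr.haldane_corrected else "")
        + ".",
        "",
        f"## Recurrence-free survival at HSPR% >= {km_split:g}%",
        "",
        f"Log-rank chi-square = {logrank.statistic:.2f}, "
        f"p = {logrank.p_value:.3g} "
        f"(observed events {logrank.observed[0]:.0f}/{logrank.observed[1]:.0f}, "
        f"expected {logrank.expected[0]:.1f}/{logrank.expected[1]:.1f}).",
        "",
        "## Spearman correlations with HSPR%",
        "",
    ]
    for col, (rho, p) in spearman.items():
        lines.append(f"- {col}: rho = {rho:.2f} (p = {p:.3g})")
    lines.append("")
    return "\n".join(lines)
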