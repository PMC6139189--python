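# gistmask

Digital masking and hotspot Ki-67 scoring for tumor whole-slide cell
maps, with synthetic tissue and cohort simulation.

## The problem

Gastrointestinal stromal tumors (GISTs) are risk-stratified by mitotic
count, tumor size and site (the Miettinen/ESMO scheme), but a mitotic
count taken in a randomly chosen field misses the most proliferative
clone. Whole-slide digital analysis of the Ki-67 labelling index fixes
the field-choice problem: scan the slide, find the *hotspots* (the
fields with the highest fraction of Ki-67-positive nuclei), score those
fields explicitly, and compare against typical ("not-hotspot") tumor.
Two practical obstacles make this non-trivial: Ki-67-positive stromal
lymphocytes near ulceration inflate the score unless they are masked
out, and weak vs strong nuclear DAB reactions must be separated because
both count as positive but carry different biology.

`gistmask` implements that pipeline end to end:

1. **Synthetic slides and cohorts** (`simulate`) — spatial point-process
   tissue with engineered Gaussian hotspots, lymphocyte confounders and
   exclusion zones; patient cohorts with a tercile score structure and a
   proportional-hazards recurrence link. Every downstream stage is
   testable against known ground truth.
2. **Digital masking** (`masking`) — H-DAB colour deconvolution onto
   standard stain vectors, distance-transform watershed nucleus
   segmentation, and an intensity + shape/size template that codes each
   nucleus negative/weak/strong and flags small round positives as
   lymphocytes.
3. **Hotspot selection** (`hotspots`) — a stride-lattice scan of
   candidate 1500 µm × 1500 µm scoring windows (DOIs: five of them cover
   the ~10–11 mm² of a conventional 50-high-power-field count), greedy
   top-k disjoint hotspot selection, median-ratio not-hotspot selection,
   and rigorous exclusion-region handling.
4. **Slide scoring** (`scoring`) — the per-case statistics:

   ```
   HSPR%  = 100 · Σ_hotspot DOIs (n_strong + n_weak) / Σ_hotspot DOIs n_total
   nHSPR% = the same over the not-hotspot DOIs
   heterogeneity = HSPR% − nHSPR%
   ```

   pooled across windows (positives over analysed tumor cells), not the
   mean of per-window ratios.
5. **Cohort statistics** (`stats`, `report`) — chi-square/Fisher,
   Mann–Whitney/Kruskal–Wallis, Spearman, ROC with AUC (Mann–Whitney
   rank form), DeLong 95% CI and Youden-optimal cut-off, odds ratios
   with Woolf CIs (Haldane-corrected when needed), tercile splits, and
   two-group Kaplan–Meier with the log-rank test.

## Worked example

```python
import gistmask as gm

cell_map = gm.generate_cell_map(gm.SlideSimConfig(seed=0))   # 10x10 mm slide
cell_map = gm.apply_exclusions(cell_map, cell_map.exclusions)
grid = gm.compute_density_grid(cell_map, side_um=1500, stride_um=250, min_cells=500)
hot = gm.select_dois(grid, cell_map, k=5, kind="hotspot")
not_hot = gm.select_dois(grid, cell_map, k=5, kind="not_hotspot", avoid=hot)
score = gm.compute_score(hot, not_hot)
print(score.hspr_pct, score.nhspr_pct, score.density_per_mm2)
```

prints (seed 0):

```
HSPR%  = 12.29
nHSPR% = 2.03
heterogeneity = 10.25 percentage points
density = 5330 analysed cells/mm^2
```

The five selected hotspot windows each hold ~12,000 analysed tumor
cells; pooling their positives gives HSPR% = 12.29, while five
median-ratio windows give nHSPR% = 2.03 — the 10-point heterogeneity
delta is exactly what a hotspot-blind score would miss. On the cohort
side (`examples/04_cohort_statistics.py`, seed 4):

```
tercile sizes: (20, 17, 20) at boundaries (3.5, 10.0)
AUC vs groups 5-6: 0.962 (95% CI 0.919-1.000)
Youden cut-off: 12.13% (sens 0.86, spec 0.94)
OR at >16%: 112.0 (95% CI 12.1-1038.5)
log-rank at 10% split: chi2 = 5.78, p = 0.0162
```

i.e. the hotspot score sharply separates very-high-risk (group 5–6)
tumors and a 10% split stratifies recurrence-free survival.

The `examples/` directory has one short script per capability;
`gistmask --help` exposes the same stages as a CLI
(`simulate`, `render`, `mask`, `select`, `score`, `cohort`, `report`,
`all`).

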