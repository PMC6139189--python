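# Methods

This note documents the models, conventions and design choices behind
`gistmask`, in the order the pipeline runs.

## Slide simulation

Tumor nuclei form a homogeneous Poisson point process on the slide
rectangle with intensity `base_density` (default 5585 cells/mm², the
density implied by ~12.6k analysed cells in a 1500 µm square window;
the default 10 × 10 mm slide guarantees at least 6 × 6 = 36 disjoint
windows so that 5 + 5 DOI selection is always feasible). Each nucleus
is Ki-67 positive with probability

```
p(x) = p_bg + (p_hot − p_bg) · max_j exp(−‖x − c_j‖² / 2σ²),   capped at 1,
```

a smooth Gaussian-bump blend between background labelling
(`background_positive_frac`, default 0.02) and the hotspot peak
(`hotspot_positive_frac`, default 0.30) over `n_hotspots` centres
(default 3, σ = 600 µm). The smooth kernel avoids artificial hotspot
edges that a disc model would hand to the selector for free. Positives
are strong with `strong_given_positive_frac` (default 0.15 — weak
reactions dominate strong ones by roughly this margin in scored GIST
material). Nuclear areas are truncated normals (tumor 55 ± 12 µm²,
lymphocyte 22 ± 4 µm²), circularity Beta-distributed for tumor
(spindle/epithelioid spread) and near 0.93 for lymphocytes.

Exclusion zones are irregular convex blobs (400–800 µm radius)
emulating ulceration/granulation areas; 80% of lymphocytes are placed
inside them (rejection sampling), the rest scattered, and lymphocytes
are 90% Ki-67 positive — the confounder that digital masking must keep
out of the score. The generated map records its ground truth (hotspot
centres, per-cell engineered positive probability) for recovery tests.

What the simulator does *not* model: staining chemistry, tissue folds,
scanner optics, 3-D tissue, spatially correlated nucleus morphology, or
realistic stromal texture. Tests passing on these maps show that the
pipeline recovers engineered spatial and statistical structure; they do
not certify segmentation performance on real scanned tissue.

## Tile rendering and stain model

Tiles are rendered through the same physical model the masking stage
inverts: each nucleus is a filled ellipse (axes from area and
circularity, orientation a deterministic hash of the cell id) assigned
hematoxylin/DAB stain amounts per class, and the two stain planes are
recombined to RGB through the standard H-DAB stain matrix
(`skimage.color.rgb_from_hdx`). Stain amounts are expressed in
scikit-image's normalised concentration units (1.0 spans the full
dynamic range down to transmittance 10⁻⁶): negative (0.18 H, 0.005 D),
weak (0.08, 0.11), strong (0.08, 0.32), background 0.007 H. Overlaps
take the per-pixel maximum of each plane, which keeps rendering
order-independent.

Because rendering and deconvolution share one fixed stain matrix, the
separation round-trip is exact to quantisation (±1/255); on real
material, stain-vector mismatch would add a calibration step that is
out of scope here.

## Digital masking

* **Separation** — colour deconvolution onto the fixed H-DAB vectors,
  clipped non-negative.
* **Detection** — foreground at combined OD > 0.05 (background renders
  at 0.007, nuclei at ≥ 0.18), Euclidean distance transform, peaks at
  least 2 µm apart as watershed seeds, watershed on the negated
  distance. Candidates keep their centroid-inside-tile rule so
  half-open tiling never double-counts border nuclei. Circularity is
  4πA/P² with the Crofton perimeter, capped at 1.
* **Classification** — mean DAB OD against two thresholds: < 0.05
  negative, 0.05–0.21 weak, ≥ 0.21 strong. The defaults sit midway
  between the rendered class levels and were fixed once by training on
  simulated tiles; they are template parameters, not constants, because
  real material would need its own training cycle. A positive nucleus
  with area ≤ 32 µm² and circularity ≥ 0.80 is classed as a lymphocyte
  (two-parameter, auditable rule); candidates outside 10–300 µm² are
  dropped as debris/clumps and counted.

At the default density the matched stain-class accuracy against ground
truth is ≥ 95%; under-segmentation of touching nuclei (~15% of
detections at 5585 cells/mm²) is the dominant error mode and mostly
merges same-class neighbours.

## Window selection

Candidate windows sit on a stride lattice (default stride 250 µm =
side/6, balancing hotspot localisation against grid size). Window
counts are exact block sums of a stride-resolution 2-D histogram
(half-open membership by centroid). A window is invalid below
`min_cells` = 500 tumor cells (ratio stability at tissue edges) or when
it intersects an exclusion polygon.

Hotspot selection is greedy top-k by positive ratio with pairwise
disjointness; ties break on higher count, then lower y, then lower x,
making selection fully deterministic. On a non-overlapping lattice
greedy top-k is provably optimal; with overlapping candidates a greedy
gap is possible and the infeasibility error reports the achievable k.
Not-hotspot windows are the k disjoint valid windows (also disjoint
from the chosen hotspots) whose ratios are nearest the median of the
remaining valid windows — a "typical tumor" reference that keeps the
HSPR−nHSPR contrast interpretable; a `lowest`-ratio mode is available
as the alternative definition. Greedy packing can fail before k on
small slides even when a feasible packing exists; the error names the
achieved k so the caller can shrink k or the window side.

## Scoring

HSPR% and nHSPR% pool counts across their DOI set (Σ positives /
Σ analysed tumor cells); the per-window-mean alternative is available
but pooling is the default because the ratio is defined over *all
analysed tumor cells* of the window set. Cell density is reported over
the union of the hotspot windows. Excluded cells and lymphocyte-class
cells never enter any count. Scoring a window that touches an exclusion
polygon is a contract violation and raises.

## Cohort simulation

Per-patient hotspot scores are drawn from a three-band mixture: quota
sampling fixes the group sizes exactly (default 20/17/20 of 57, the
tercile split at 3.5% and 10%), and within each band the score is a
truncated log-normal (medians 1.0 / 5.75 / 23%, the scale the published
per-tercile score summaries suggest). Covariates link to log-score
through logistic models (mitotic class, sex, strong-reaction share) or
a noisy cut-point model (Miettinen-like groups 1–6 at 0.5/2/5/10/16%);
all coefficients are config, not constants. Not-hotspot scores are the
hotspot score times a Beta(2,4) factor, so nHSPR% ≤ HSPR% always.
Recurrence-free survival is exponential at `baseline_hazard` (default
0.0015/month ⇒ ~16% 10-year recurrence in the low group) multiplied by
`hazard_ratio_high_vs_low` (default 4) in the top tercile, with
independent uniform administrative censoring at rate 0.3. At n = 57
this yields ~10–18 events and realistic (i.e. not-always-significant)
log-rank power, matching the scale of a single-institution cohort.

## Statistics: conventions

* **ROC/AUC** — rank (Mann–Whitney) formulation with midrank ties; the
  identity AUC = U/(n₁n₀) is asserted in tests. 95% CI and the p-value
  against AUC = 0.5 by DeLong's placement-variance method (deterministic;
  verified to 10⁻⁸ against an independent DeLong implementation).
  Optimal cut-off maximises Youden's J over midpoints between
  consecutive distinct scores (calls ≥ cut-off positive), ties towards
  higher sensitivity then lower cut-off.
* **Odds ratio** — cross-product with Woolf log-normal CI; the
  Haldane–Anscombe +0.5 correction applies to all cells when any cell
  is zero and is flagged in the result.
* **Terciles** — boundaries at the empirical 1/3 and 2/3 quantiles
  (type-7 linear interpolation — membership near a boundary depends on
  this choice, hence it is pinned) or fixed external boundaries;
  half-open bins [min,b1), [b1,b2), [b2,max]; degenerate splits warn
  with the achieved sizes.
* **Group comparisons** — chi-square without continuity correction;
  Fisher's exact replaces it when any expected count is below 5 (exact
  2×2; seeded Monte-Carlo chi-square under fixed margins for larger
  tables, since r×c enumeration is intractable). Continuous variables:
  Mann–Whitney (2 groups) or Kruskal–Wallis.
* **Survival** — Kaplan–Meier product-limit per group; two-group
  log-rank as (O₁−E₁)²/V with hypergeometric E and V summed over pooled
  event times, χ²₁ reference. The full observed/expected life table is
  returned, and tests check it against `scipy.stats.hypergeom` and the
  statistic against lifelines.
* The positive class of the ROC/OR analyses defaults to risk groups
  5–6 ("very high grade"); `esmo_gt3` (groups > 3) is the config
  alternative. No multivariable Cox model is fitted and no
  multiple-testing correction is applied — deliberately, to keep the
  battery a like-for-like single-marker analysis.

## Determinism and problem sizes

Every stochastic step flows from a single integer seed
(`numpy.random.default_rng`); fixed seed ⇒ bit-identical cell maps,
cohorts and CSV artifacts, and the run manifest records the config
hash. The test-suite simulations are sized for single-CPU runs (slides
of 4–10 mm, cohorts of 40–500, 50 replicates for cut-off recovery,
1000 for the log-rank null calibration); these sizes are stated in the
tests themselves and chosen so each check's sampling error is well
below its assertion tolerance.

## Known limitations

* The stain model and the masking defaults are mutually calibrated;
  applying the template to real scanner output requires re-training the
  thresholds (the template is config for exactly this reason).
* Greedy selection is not a packing solver: it may report infeasibility
  on crowded small slides where an exhaustive packing would succeed.
* The simulator's lymphocyte rule and the classifier's lymphocyte gate
  share the area/circularity parameterisation, so the confounder test
  demonstrates internal consistency, not clinical lymphocyte detection.
* Whole-slide file formats (SVS/NDPI) and pyramid processing are out of
  scope; cell tables (CSV) and tiles (PNG/TIFF) are the interchange
  level.
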