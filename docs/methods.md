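# Methods

`senescape` quantifies the burden of cellular senescence in brain tissue
from two complementary modalities: single-nucleus RNA-seq gene-set
scoring and imaging-mass-cytometry (IMC) single-cell tables.  This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Gene-set scoring

**AUC (rank-based) score.** For each nucleus, genes are ranked by
descending expression; ties — ubiquitous in zero-inflated count data —
are broken by a seeded uniform shuffle within tie groups (an
`average`-midrank mode is available for deterministic testing).  With
`max_rank_frac` = 0.05 (so maxRank = ceil(0.05 · n_genes), at least 1),
the recovery curve y(i) counts gene-set genes at rank ≤ i for
i = 1..maxRank, and the score is

    AUC = Σᵢ y(i) / Σᵢ min(i, k)

where k is the number of set genes matched in the matrix.  The
denominator is the top-packed maximum, so AUC ∈ [0, 1]: 1 when the set
occupies the best ranks, 0 when no set gene enters the window.  Scores
are insensitive to library-size normalisation (ranks are within-cell)
but are computed on log-normalised data by default for consistency with
the module score; this is configurable.  A set entirely absent from the
matrix scores 0 with a warning rather than an error, because curated
senescence sets (e.g. the canonical senescence pathway, CSP) routinely
contain symbols missing from a given matrix; symbols are matched
case-sensitively after whitespace trimming.

**Module score.** The bin-matched control score: genes are placed into
`n_bins` = 24 near-equal bins by rank of dataset-wide mean expression,
and for each matched set gene `n_ctrl` = 100 control genes are drawn
from its bin (seeded; with replacement when the pool is smaller, so
small matrices never fail).  Score(cell) = mean expression of set genes
− mean expression of pooled controls.  Control pools exclude set genes;
a consequence worth knowing is that adding a constant to the set genes
alone moves scores by exactly that constant whenever bin memberships are
unaffected (exactly so with one bin), while adding a constant to *all*
genes never changes the score because binning is rank-based.  Requires
log-normalised input (warned otherwise).

**Gene-set curation.** GMT sets are de-duplicated and sets with fewer
than `min_genes` = 10 symbols are dropped, with the drop count logged.

## Senescent-nucleus calling

A nucleus is senescent when its score strictly exceeds

    median(scores) + k · MAD,  MAD = 1.4826 · median |x − median(x)|

computed within its stratum; defaults k = 3 and the normal-consistency
factor 1.4826 (a raw-MAD mode is available, since conventions differ).
The stratum defaults to cell type pooled across samples and diagnoses so
that AD and control calls share one yardstick; per-region stratification
is a flag.  When MAD = 0 the threshold degenerates to the median and
only strictly greater scores are called, so constant strata produce no
calls.  Strata with fewer than two cells are all-false with a warning.

Calibration: on N(0, 1) scores the rule calls 1 − Φ(3) ≈ 0.135% of
cells.  A known limitation: with heavy contamination (≈ 30% planted
outliers) the mixture inflates both the median and the MAD, costing a
few percent of sensitivity (expected recovery ≈ 0.291 for a true 0.300
at an 8σ shift).  This is a property of the estimator, not of the
implementation, and is covered by an operating-characteristic test
against the closed-form expected call rate.

Per-sample proportions are exact ratios n_senescent/n_cells per
(sample, stratum); strata with fewer than `min_cells` = 3 cells in a
sample are excluded (the IMC rule, applied uniformly).

## Group statistics

Two-group contrasts use the Wilcoxon rank-sum test with midrank tie
handling.  The p-value is exact (full null distribution) when both arms
have ≤ 10 observations without ties, otherwise a normal approximation
with continuity and tie correction.  The effect size is the
rank-biserial correlation r = 2U₁/(n₁n₂) − 1 = P(x>y) − P(x<y); its CI
is a seeded percentile bootstrap (2,000 resamples within arms) by
default, with a normal approximation for speed.  Contrasts run per
stratum on per-sample proportions; strata with fewer than two samples
per arm are reported as skipped, and BH-FDR adjusted p-values are
appended across tested strata.  Pearson regression (e.g. senescent
fraction vs amyloid load) reports r, the t-based two-sided p on n − 2
df, and the OLS line, and refuses zero-variance inputs by name.

## Linear-plateau age model

Mean senescence score vs donor age is modelled as y = a + b·min(x, c):
a linear rise to breakpoint c (years) then a plateau, the shape expected
as cells approach a replicative limit late in life.  Because the
objective is piecewise-quadratic in c, the breakpoint is profiled on a
dense grid (200 points by default) over the observed age range with OLS
for (a, b) at each c; this is robust and exactly reproducible, unlike
derivative-based search across the kink.  Significance is an F-test
with (2, n − 3) df against the intercept-only null — i.e. a test for
*any* age trend, chosen because the scientific question is whether the
age association persists, not whether the plateau improves on a line.
Constant scores return slope 0 and p = 1; fewer than 5 distinct ages is
an error.

## Meta-analysis

The unit of analysis is the donor: scores are averaged over nuclei per
sample before any effect size is computed.  Each dataset contributes
Hedges' g (Cohen's d with the J = 1 − 3/(4(n₁+n₂) − 9) correction) with
variance J²(1/n₁ + 1/n₂ + d²/(2(n₁+n₂−2))).  Pooling is
DerSimonian–Laird: tau² = max(0, (Q − (k−1))/C), weights 1/(se² + tau²),
with I² = max(0, (Q−(k−1))/Q)·100 and the count of positive-direction
datasets reported alongside the pooled z and p.  A single dataset pools
to itself with tau² = 0.  Replicating any specific published
multi-cohort result would require the underlying accessions and is out
of scope; the implementation is validated against direct evaluation of
the closed forms and by parameter recovery (14 simulated datasets,
true g = 0.6, tau = 0.15).

## IMC spatial quantification

**QC trim.** ROIs in the lowest `trim_frac` = 1% of mean
senescence-marker (GLB1, p16, p21, γ-H2AX) intensity are removed
(cutoff computed across all ROIs; a within-sample mode is configurable),
then within each remaining ROI the lowest 1% of cells by defining
cell-type-marker intensity (maximum over Iba1/GFAP/OLIG2/MAP2/GLUT1).
The cutoff is the `lower`-interpolated quantile with inclusive (≤)
removal, so 100 distinct ROIs at 1% lose exactly one and ties at the
cutoff are all removed — a deterministic rule.  `trim_frac` = 0 is the
identity.  Re-applying a pass's frozen cutoffs removes nothing new
(idempotence); recomputing cutoffs on trimmed data would, by
construction, keep trimming.

**Marker positivity.** Per-channel rules: fixed threshold, per-ROI
quantile, or Otsu's threshold on log1p intensities; positivity is
strictly-greater and the applied rule is stored with the calls.  The
original pixel-classifier workflow is not reproducible from published
information, so thresholding is the package's deliberate
reinterpretation.

**Peri-plaque classification.** A cell is peri-plaque when its centroid
lies within `radius_um` = 10 µm of a plaque boundary, inclusive at
exactly 10.0 µm (0 inside a plaque).  Coordinates are µm with origin at
the ROI top-left, y downward.  `centroid` mode computes continuous
distances (disks analytically, label masks via Euclidean distance
transform); `mask` mode reproduces the raster procedure — dilate the
plaque mask by radius/scale pixels with a disk structuring element and
test the centroid pixel — and agrees with centroid mode on disk plaques
to within one pixel at 1 µm/px.  ROIs without plaques yield +∞
distances and all-false calls.  Cluster-level proportions count cells
positive for the cluster's defining marker (denominator) and those also
positive for ≥ 1 senescence marker (numerator), summed over ROIs to
sample level; (sample, cluster) pairs under 3 denominator cells are
excluded.  The peri vs non-plaque contrast compares per-sample
positivity in the two compartments with a paired Wilcoxon signed-rank
test.

## Synthetic data

The expression generator emulates a two-arm (AD/NDC) cohort: 8 donors
per arm across three regions (EC/MTG/SSC round-robin), 150 nuclei per
donor over a five-type mixture (20% microglia), 1,000 genes with
lognormal(0, 1) base means (≈ 10³ counts per nucleus) and
negative-binomial noise (dispersion 0.5, the standard gamma–Poisson
snRNA-seq model).  A 40-gene senescence set is planted: senescent cells
have those genes' means multiplied by fold-change 4.  Planted senescent
fractions are 0.25 (AD microglia) vs 0.05 (NDC microglia), 0.02
baseline elsewhere, with per-donor Beta(π·30, (1−π)·30) variability;
per-donor amyloid load is 2 + 60·(true senescent microglial fraction) +
N(0, 1.5²) % area, truncated at 0, so amyloid tracks the planted signal
as it does pathology.  Ages are uniform 50–100 (NDC) and 60–95 (AD).
The geometry was chosen so the 5% AUC rank window (50) exceeds the set
size, matching the real relationship in genome-wide matrices where 5%
of the gene universe is far larger than any curated set.  The imaging
generator places ~100 cells uniformly per 500 × 500 µm ROI (4 ROIs per
sample), non-overlapping disk plaques (4 per ROI, radii 8–20 µm,
bounded-retry placement), and log-normal channel intensities; GLB1
positivity is 0.30 within 10 µm of a plaque vs 0.03 elsewhere.

What the generators do *not* emulate: ambient RNA, doublets, batch
effects, segmentation errors, channel spillover, or spatial clustering
of cells.  Passing benchmarks therefore demonstrate correctness of the
statistical machinery under a clean generative model, not robustness to
the artefacts real pipelines remove upstream.

## Problem sizes and determinism

The benchmark sizes are chosen to give stable statistics at desk scale:
500 random instances for the scoring oracle, 10⁵ scores for tail
calibration (2,000 per planted mixture, where Monte-Carlo error
dominates the contamination bias discussed above), 2,000 null
replicates for the type-I-error check, 100 seeds per arm for end-to-end
recovery, and 200 replicates for breakpoint recovery.  Every stochastic
component — tie-breaking, control-gene draws, bootstrap, simulation —
flows through an explicit seed, and pipeline reruns with an identical
config are byte-identical.

## Known limitations

- MAD-threshold sensitivity degrades with contamination (above); calls
  are a lower bound on the planted fraction at high burden.
- The AUC tie policy is this package's own (seeded shuffle); other
  rank-based scorers may order ties differently, so absolute scores are
  comparable only within one tool and seed.
- Bootstrap CIs for the rank-biserial correlation are percentile
  intervals; they can undercover below ~5 samples per arm.
- `mask`-mode peri-plaque classification quantises distances to the
  pixel grid; at coarse scales (> 2 µm/px) prefer centroid mode.
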