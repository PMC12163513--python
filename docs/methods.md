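# Methods

## Morphotype vocabulary and raster conventions

The analysis vocabulary is the six colorectal-adenocarcinoma morphotypes
in a fixed canonical order: CT (complex tubular), TB (solid/trabecular),
MU (mucinous), PP (papillary; the alias "PA" is accepted on input), DE
(desmoplastic), SE (serrated). The order is total and is used everywhere
a deterministic order is needed: raster label values (CT=1 … SE=6),
proportion-vector columns, and tie-breaking of dominance rankings.
Rasters are 0-based, row-major, with 0 = background/non-tumor. "Tumor
area" of a section is defined operationally as the count of pixels
carrying any morphotype label (1–6); this makes proportions sum to one
over classified tissue and is documented as this package's definition,
not asserted as universal.

## Region filtering and section profiles

Connected components are computed per morphotype with 8-connectivity by
default (4-connectivity available); blob-like histological regions join
across corners, so 8 is the natural choice. The small-region filter
removes every fragment whose area is below `min_frac` (default 0.05) of
the section tumor area; the threshold is inclusive ("at least 5%"), is
applied per fragment rather than per morphotype aggregate, and uses the
pre-filter classified area as its denominator. Proportions are then
renormalized over the retained area so they sum to one. A section whose
fragments are all filtered away is flagged empty and excluded from tumor
aggregation with a logged warning.

## Heterogeneity

Shannon entropy uses the natural logarithm, fixed by the normalization
constant `ln 6 ≈ 1.7918` (conventionally printed 1.79); the normalized
Shannon index NSI = H/ln 6 maps any six-way profile to [0, 1]. Inputs
must sum to 1 within 1e-6; zero entries contribute 0 (0·ln 0 := 0).
NSI classes are low (< 0.3), medium ([0.3, 0.7] — both boundaries are
assigned to medium, a deliberate closure of the open boundary cases) and
high (> 0.7).

Dominance ranks the morphotypes with positive proportion by descending
share; exact ties are broken by canonical order and flagged rather than
resolved arbitrarily. A tumor's DMC is the multiset of its four section
dominants; its pattern class is the multiplicity partition. Tumors with
fewer than four valid sections keep their proportion/NSI summaries but
are excluded from DMC tabulations, which presuppose four dominants.

Tumor profiles are clustered agglomeratively (Ward linkage on Euclidean
distance, k = 9 by default; both configurable since no canonical choice
exists for compositional vectors at this scale). A per-DMC-group median
mode (`group_median_profiles`) is exposed as an alternative substrate.

## Agreement

The modified intersection-over-union is |P∩A|/|A| — the recall of the
annotated region, asymmetric by construction (overprediction is not
penalized); the training gate requires strictly > 0.9 for every
morphotype present in the annotation set, pooled per category (a
per-image evaluation can be composed from per-pair calls). Cohen's kappa
is computed from the 2×2 presence/absence table with marginal-product
expected agreement; the degenerate case p_e = 1 (both raters constant)
is flagged undefined instead of coerced to a number. Kappa is computed
on presence/absence only; ranked (dominant/secondary/tertiary) calls are
compared by a separate concordance rate reported with its numerator and
denominator.

## Associations

Continuous outcomes (morphotype proportions, tumor NSI) are compared
across covariate groups by Mann–Whitney U (two groups) or Kruskal–Wallis
(more), with pairwise Mann–Whitney follow-ups emitted only when the
omnibus p < 0.05. Categorical tables use Pearson's chi-square without
continuity correction; cells with expected count < 5 are counted and
reported as a reliability flag rather than triggering an automatic
switch to exact tests. The wall-location analysis collapses mucosa and
submucosa to "superficial" and muscularis and fat to "deep" before the
chi-square; absent layers drop out of the collapse without error.
Benjamini–Hochberg adjustment is applied over one family: all omnibus
outcome × covariate tests of a pipeline run (gated pairwise tests are
reported unadjusted and marked as children of their omnibus test).
Significance means adjusted p < 0.10. Rank tests are mildly conservative
when some covariate levels are small, so the realized type-I rate of the
battery sits slightly below the nominal 5% in null simulations.

## Survival

Kaplan–Meier estimation and the k-sample log-rank test are delegated to
lifelines; a vectorized observed-minus-expected two-group log-rank
statistic is implemented internally for the cutoff search, where it runs
once per candidate split, and the test suite asserts exact agreement
between the two routes. The "most informative split" of a morphotype
proportion is found by exhaustive search over midpoints of consecutive
distinct values, maximizing the log-rank statistic subject to both arms
holding at least `min_leaf_frac` (default 0.1) of subjects — the first
split a single-split survival tree would make, implemented transparently
instead of through a tree library. Ties prefer the smallest cutoff; the
search is deterministic. Because the cutoff maximizes separation, the
reported p-value is selection-biased; it is flagged `exploratory=True`
and no permutation correction is applied by default. Stratifications are
produced for DE, PP and CT proportions × {OS, RFS} × {all, stage I–III},
the stage subset dropping AJCC stage IV rows before analysis.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
it is a first-class, tested module, not a fixture.

* **Profiles.** Tumor mean profiles ~ Dirichlet(α) with default
  α = (5, 1, 1, 1, 1.2, 0.8) (total 10), giving mean shares of roughly
  50% CT, 12% DE, 10% each TB/MU/PP and 8% SE — CT-dominant cohorts of
  the kind reported for CRC. Section profiles ~ Dirichlet(c·mean) with
  concentration c = 50, which yields realistic section-to-section
  dispersion (sections resemble, but do not duplicate, the tumor mean).
* **Spatial realization.** Each section raster is an elliptical tumor
  mask partitioned into Voronoi cells around 24 random seeds; cells are
  swept by angle and pixels allocated to morphotypes at exact cumulative
  counts (largest-remainder apportionment), so patches are contiguous
  and realized proportions are pixel-exact. An optional layer-preference
  mode sweeps by depth instead and allocates PP/SE near the luminal edge
  and TB/DE near the deep edge, to exercise the wall-location test.
  Real tumors have richer spatial statistics (fragment-size
  distributions, infiltration fronts) that are not emulated; passing
  tests therefore validate the measurement pipeline, not spatial realism.
* **Clinical effects.** MSI ~ logistic(−3 + 10·p_MU + 5·p_TB) (~15%
  marginal MSI, typical of CRC); right-sided location odds rise with MU;
  AJCC stage follows a cumulative-logit model shifted by 4·p_DE with
  thresholds giving roughly 25/30/30/15% stage I–IV at the null; grade 3
  odds rise with TB. T/N/M are drawn consistently with stage.
* **Survival.** Exponential event times with hazard
  0.012·exp(5·p_DE − 4·p_PP) per month, administrative censoring at 120
  months plus independent uniform-on-(0, T) censoring of a configurable
  fraction (default 0.3). The hazard coefficients were set from the
  magnitude of the survival separation such a cohort must display for a
  log-rank test at n = 161 to reach the very small p-values typical of a
  strong desmoplastic effect (between-arm log-HR near 0.8 after
  dichotomization, given the ~0.1 SD of the DE proportion).
* **Determinism.** All randomness derives from one master seed through
  named `SeedSequence` child streams (profiles, clinical, render);
  identical configs produce byte-identical bundles.

`SimConfig.null()` zeroes every planted coefficient for calibration
studies.

## Problem sizes and numerical choices

Calibration and power studies use 200 replicate cohorts of 161 tumors,
drawn as profile + clinical frames without raster rendering (the spatial
step is validated separately by a 100-profile render→quantify round trip
at 128×128 with max-norm tolerance 0.02, and by flood-fill equivalence on
50×50 rasters). Proportion sums are validated to 1e-6 on input and
produced to 1e-9 internally; CSV output uses a fixed `%.10g` float format
and LF endings so reruns are bytewise comparable.

## Known limitations

* No whole-slide reading or segmentation: the upstream AI model that
  produces label maps is out of scope, as are stain handling and WHO
  subtype diagnosis.
* Survival analysis is univariate (KM/log-rank); no Cox or multivariable
  adjustment.
* Only pairwise (two-rater) kappa; no multi-rater generalization.
* Post-selection inference for the optimal cutoff is flagged but not
  corrected; a permutation wrapper can be layered on by resampling
  cohorts through the generator.
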