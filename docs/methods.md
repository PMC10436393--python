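# Methods

This note documents the statistical model behind each pipeline stage, the
conventions chosen where several are defensible, the synthetic-data
generator's assumptions, and known limitations.

## Tissue predominance

For each gene, per-tissue mean log2 expression is computed at two
granularities: the detailed tissue list and coarse tissue groups (group
means pool raw samples, i.e. they are sample-count-weighted). Foetal
tissues are excluded from the Z computation and can never be called
predominant. The Z-score of tissue *t* is `(x_t − mean) / std` over the
N non-foetal tissue means, and a gene is predominant in its maximal-Z
tissue when that Z exceeds `0.6 (N − 1) / √N`.

**Standard-deviation convention.** The *population* standard deviation
(divide by N) is used. Under this convention a profile entirely
concentrated in one tissue attains Z exactly `(N − 1)/√N`, which is the
"maximum Z-score" the 0.6 factor scales; the sample-SD convention would
break that identity. A corollary used as a test invariant: per-gene
Z-scores sum to zero over the non-foetal tissues.

**Candidate selection.** A gene is a screening candidate when it passes
at *either* granularity with its predominant tissue in the target set
(testis, placenta, ESC) *and* its breast expression is low: the
linear-scale breast mean (2^mean-log2) must be strictly below 1/10 of the
linear-scale mean of the predominant tissue, evaluated at the granularity
of the passing call. Boundary equality fails. Genes with zero
cross-tissue variance are non-scorable and dropped with a logged count.

## Ectopic activation

The per-gene activation threshold is `mean + 2·SD` of the non-tumour log2
signal, with the *sample* (n−1) standard deviation — the conventional
estimator of population spread from a reference cohort. A sample is ON
iff its value is *strictly* above the threshold; ties are OFF. Missing
values are OFF and excluded from frequency denominators, with counts
logged. Genes are retained when their activation frequency over the
pooled tumour set is strictly greater than 0.10. Each threshold records
its percentile rank among the defining cohort's tumour values for later
propagation.

Note the estimator's small positive bias: for a silent Gaussian gene,
~2.3% of tumour samples exceed mean + 2·SD by chance, so estimated
frequencies sit slightly above planted ones. This is far below the 10%
gate and is accounted for in the tests by comparing against realized
(truth-manifest) activation fractions.

## Survival screen

* **Grid.** Thresholds are the linear-interpolation quantiles of tumour
  expression from the 15th to the 85th percentile in half-percentile
  steps (141 points); duplicate values collapse keeping the lowest
  percentile; constant genes yield an empty grid. The same quantile
  convention is used for propagation, making round-trip propagation into
  the defining cohort an exact identity.
* **Tests.** Each threshold's ON/OFF split is scored by the standard
  two-group logrank chi-square (1 df) on the full training cohort and on
  cross-validation subsets: 3-fold partitions repeated 5 times, with the
  15 held-in 2/3 portions evaluated by default (they preserve event
  counts and hence power; a `subset_mode="held_out"` switch evaluates the
  folds instead). The stability of a threshold is the fraction of
  subsets with subset logrank p < 0.05.
* **Multiplicity.** BH adjustment is applied across the *entire*
  gene × threshold family of full-set p-values of the screen — the most
  conservative family choice, and invariant to per-gene grid collapsing.
* **Gates.** Significant: p < 0.05, FDR < 0.2, ON-vs-OFF hazard ratio
  > 1. The reference threshold per gene is the significant one with
  maximal stability; ties break by lower full-set p, then lower
  percentile. Thresholds leaving either arm below 15% of tumour samples
  are skipped (the grid bounds imply this floor before tie collapsing).
* **Validation.** Reference thresholds propagate as percentile ranks;
  a gene is validated when significant (p < 0.05 with HR > 1) in at
  least ⌈2m/3⌉ of m validation cohorts and p < 0.1 in every remaining
  cohort. Cohorts with zero events are excluded with a warning;
  degenerate splits (empty arm) yield NaN and always fail.

**Fast statistics.** The scan evaluates on the order of 10^5–10^6
(gene × threshold × subset) splits, so the logrank statistic and the
ON-indicator Cox model are computed by vectorized count-based formulas:
all thresholds of a gene share one time-sorted pass, and because the
covariate is binary the Efron-tie partial likelihood reduces to the same
risk-set counts, solved by Newton iteration simultaneously across
thresholds (log HR clipped at ±15 under separation; splits with an empty
arm give NaN). `lifelines` is the engine for general Cox fits and
Kaplan–Meier curves elsewhere in the package, and the test-suite checks
the fast paths against `lifelines`, an exhaustive permutation oracle and
a hand O−E/V computation.

## GEC

Sample score = number of panel genes ON at cohort-propagated thresholds.
With a K-gene panel: group *low* is count ≤ 1, *high* is ≥ 2; extremes
GEC− (0) and GEC+ (≥ K−1). Evaluation: low-vs-high logrank; univariate
Cox with the count as a numeric covariate; multivariate Cox adding age
(years), molecular subtype and stage. Subtype enters as one ordered
numeric covariate by default (order luminal-A < luminal-B < HER2 <
basal), with dummy encoding available; stage is ordinal. Missing
covariates are dropped per cohort; constant covariates are dropped with a
warning. Subtype-stratified evaluation pools cohorts *after* per-cohort
threshold propagation and scoring, so counts stay cohort-calibrated.

The extreme-group differential-expression filter compares GEC+ against
GEC− (intermediates excluded; ≥ 3 samples per side required): two-sided
Mann–Whitney per gene, BH-adjusted across all tested genes, plus a fold
gate on the ratio of *linear-scale* group means (back-transformed from
log2): selected iff adjusted p < 0.05 and ratio > 1.5 or < 1/1.5.

## Synthetic studies

The generator emulates the study structure, not the biology:

* Expression is Gaussian on the log2 scale (baseline mean 1.0, SD 0.5
  log2 units by default). Planted predominant genes gain a
   +6 log2-unit shift in exactly one designated target tissue; the panel
  always contains breast and ≥ 1 foetal tissue. Default panel: 20 adult
  tissues + 2 foetal, 3 samples per tissue.
* Cohorts: non-tumour samples keep every gene at baseline; each tumour
  sample independently activates each activatable gene (+4 log2 units)
  with its planted probability. A single per-cohort offset drawn with SD
  0.5 log2 units models platform shifts. Default study: 125 genes — 30
  planted predominant (10 per target class), 25 activatable, 5
  prognostic — and 4 cohorts (training n = 600 tumours + 100 non-tumours,
  three others n = 250 + 50).
* Survival: event times are exponential with hazard
  `h0 · exp(Σ β_g · ON_g)` over prognostic genes — the simplest
  proportional-hazards-compatible family, giving closed-form oracles
  (e.g. the zero-activation Kaplan–Meier curve equals `exp(−h0 t)`).
  Defaults: `h0 = 0.08`/year, per-gene hazard ratios spanning 2.5–3,
  activation frequencies spanning 0.25–0.35 for prognostic genes and
  0.30 otherwise. Censoring is an independent exponential time
  (0.04/year) capped at 10 years of follow-up.
* Covariates age (Uniform 30–80), molecular subtype (luminal-A 53.4%,
  luminal-B 19.8%, HER2 8.0%, basal 18.8% — a luminal-A-dominated mix
  typical of large breast-cancer cohorts) and stage (I/II/III at
  0.3/0.5/0.2) are survival-independent noise unless a test plants
  structure through them.
* Determinism: all draws flow from `numpy.random.default_rng` seeded by
  `(seed, stream-index)`; identical config + seed reproduce every output
  byte for byte, and a planted-truth manifest always accompanies the
  data.

What the generator does **not** model — and what passing tests therefore
do not establish for real data: mixed epithelial/stromal cell
composition (bulk deconvolution), count-based mean–variance noise,
gene–gene correlation beyond shared activation structure,
subtype-specific expression programs, non-proportional hazards, and
informative censoring.

## Problem sizes used in the test-suite

Simulation-backed checks run at sizes chosen to keep sampling noise well
below the asserted margins: the screen calibration/recovery suites use
the default study (above) over 50 seeds with a 2-percentile grid step
(36 thresholds; the half-percentile grid is the analysis default), and
the GEC hazard-scale suite uses four cohorts of n = 2000 tumours, sized
so the per-cohort logrank significance of the planted log-hazard 0.2 has
above 99% joint power — at n ≈ 1000 the realized per-cohort effect is
noisy enough (SE of the log HR ≈ 0.04) to leave an appreciable chance of
one marginal cohort, which would make the check flaky without changing
what it demonstrates.

## Known limitations

* No correction for tumour purity / epithelial fraction between tumour
  and non-tumour bulk samples; activation frequencies of genes expressed
  in rare normal-breast cell types can be biased.
* The validation rule reports per-cohort p-values without a combined
  ranking across cohorts.
* The screen's FDR family (all gene × threshold tests pooled) is one of
  several defensible choices; per-gene families would be less
  conservative.
* Enrichment analysis, microarray normalization and read-level
  quantification are out of scope; inputs are assumed already normalized
  on a log2 scale.
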