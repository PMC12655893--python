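# Methods

## OJIP transients and the JIP-test

### Curve model (generator)

A synthetic induction curve is a renormalized mixture of saturating
exponentials plus Gaussian noise:

    V(t)  = wJ(1−e^(−t/τJ)) + wI(1−e^(−t/τI)) + wP(1−e^(−t/τP)) + κ(1−e^(−t/τK))
    F(t)  = F0 + (Fm − F0) · V(t−t1)/V(tmax−t1) + N(0, σ²)

with phase weights wJ+wI+wP = 1 and time constants τJ < τI < τP. The rise
is referenced to the first sampling instant t1, mirroring the instrument
convention that the earliest recorded point (~20 µs) defines F0; with σ = 0
the curve is deterministic, F(t1) = F0 and max F = Fm exactly. This is a
phenomenological model chosen for controllable cardinal-point values
(VJ, Wk, φPo can be set and recovered), not a mechanistic PSII energy-flux
model; the κ term (τK = 0.3 ms) injects a K-band like the one produced by
donor-side (oxygen-evolving-complex) impairment.

Defaults describe a healthy leaf: F0 = 400, Fm = 2000 (φPo = 0.80),
wJ/wI/wP = 0.50/0.25/0.25, τJ/τI/τP = 0.6/8/120 ms (VJ ≈ 0.54), κ = 0.
The measurement grid is 120 log-spaced points over 20 µs–1 s, matching a
1-s saturating pulse. The four-group generator applies additive parameter
shifts per group (raise κ, lower Fm for stressed groups) and multiplicative
lognormal jitter (cv = 5%) on F0, Fm−F0 and κ per sample.

### Extraction and derivation

F0 is read at 20 µs (interpolated when bracketed, else the earliest point,
which must lie ≤ 50 µs); F300/FJ/FI are interpolated linearly in
fluorescence against log-time, the conventional axis for OJIP data, so
exact grid points are returned unchanged. Fm is the curve maximum with the
first attaining index as tie-break. The complementary area integrates
(Fm − F) from t(F0) to t(Fm) by the trapezoid rule (a.u.·ms); Sm divides by
Fm − F0, making it dimensionless and grid-invariant.

The parameter chain follows the standard JIP-test closure
RC/ABS = φPo·VJ/Mo, which is what makes PI_ABS computable from the measured
quantities; per-RC energy fluxes use TRo/RC = Mo/VJ, ABS/RC = TRo/RC / φPo,
ETo/RC = TRo/RC·ψo, DIo/RC = ABS/RC − TRo/RC. For RC/CSm two conventions
circulate: the default RC/ABS·Fm, and the literal φPo·Fm variant kept
behind the `phipo_rccs` flag rather than silently corrected.
Degenerate inputs are defined, not fatal: FJ = F0 yields Wk = NaN with a
diagnostic; φPo or ψo at 1 yields PI_ABS = +inf; a flat curve or a grid
starting after 50 µs is rejected with a named error. Noisy interpolation
can overshoot [F0, Fm] marginally; cardinal values are clipped to that
interval.

## Physiology statistics

T vs S comparisons within a soil stratum use a two-sided t-test; Welch
(unequal variances) is the default because group variances under stress are
routinely unequal, with the pooled Student variant behind a flag. Star
coding: \*\*\*\* p<1e−4, \*\*\* p<1e−3, \*\* p<0.01, \* p<0.05, "ns"
otherwise. Identical constant groups return t = 0, p = 1 rather than NaN.
Fold ratios are reported raw and rounded to one decimal; detection-limit
censored soil entries ("<0.02") are stored as bounds and refused in
ratios with a warning. The soil-chemistry table shipped under
`rhizojip/data/` is the example input for the fold-ratio stage.

## Community stage

* **Normalization.** Distances, correlation and the biomarker stage operate
  on total-sum-scaled data (relative, or per-million for LDA); the raw
  table's integer counts are preserved for ACE.
* **ACE** (Chao–Lee) uses the conventional rare/abundant cutoff of 10.
  When no rare taxa exist, or coverage C = 1 − F1/N_rare is zero, the
  estimate falls back to S_obs with a flag — defined behavior beats an
  exception mid-pipeline. Cross-checked against scikit-bio and against a
  direct formula evaluation in the tests.
* **PCoA** eigendecomposes the Gower-centred −D²/2 matrix. No
  Lingoes/Cailliez correction: negative eigenvalues are excluded from the
  variance-explained denominator and reported separately. On
  Euclidean-embeddable inputs the embedding reproduces the distances to
  1e−9 (tested).
* **ANOSIM** uses R = (r̄_between − r̄_within)/(M/2), M = n(n−1)/2. The p
  value enumerates all distinct label permutations when there are at most
  10,000 (p = fraction with R ≥ observed), otherwise seeded Monte-Carlo
  with the add-one rule p = (1 + #{R_perm ≥ R_obs})/(1 + B). Type-I error
  at α = 0.05 is calibrated within binomial tolerance (tested on 400 null
  data sets).
* **Correlation screen.** Spearman by default (robust to the compositional
  scale; Pearson by flag) with the t-approximation p value, adjusted by
  Benjamini–Hochberg jointly across the whole taxon × indicator grid; raw-p
  stars are also emitted for heatmap-style annotation. Constant vectors
  yield missing correlations excluded from the adjustment. The
  t-approximation is anti-conservative in the far tail for very small
  sample counts; at the default design size (24 samples) the global-null
  familywise behavior is within binomial tolerance of the nominal 5%
  (tested over 200 replicates).
* **Kruskal–Wallis screen** is vectorised over taxa (tie-corrected H,
  chi-square p) and matches scipy.stats.kruskal to 1e−10 (tested);
  all-tied taxa get p = 1.
* **Biomarker discovery** is a two-group LEfSe-style procedure: stage 1
  gates taxa at Kruskal–Wallis p < α (0.05); stage 2 scales survivors to
  per-million and, over 30 bootstrap rounds subsampling 2/3 of each class
  without replacement, fits a one-dimensional linear discriminant
  (covariance shrinkage 1e−3 guards degenerate within-class variance) and
  scores each survivor as the average of its raw class-mean difference and
  its share of the discriminant-projected class-mean difference; the
  effect size is log10 of the bootstrap mean, floored at 1, passing at
  score > 2. There is no subclass stage (the design has none). Numeric
  parity with the original LEfSe implementation is not promised — only
  threshold-behavior parity on strong effects, which is what the power
  tests pin down.

## Synthetic community and linkage generators

Abundance tables are Dirichlet-multinomial: per sample, proportions are
drawn from Dirichlet(p/θ) where p is the softmax of a base log-abundance
profile plus planted group effects (log2 units), and counts are multinomial
at the stated depth, so rows sum to the depth exactly. Defaults — chosen
once as the study conditions for all calibration and power runs — are 150
taxa, 6 samples/group, depth 1e5, and overdispersion θ = 0.005 (Dirichlet
concentration mass 200), a moderate replicate-to-replicate dispersion
consistent with homogenized pot-soil replicates. The base profile is a
deterministic lognormal rank-abundance curve (σ = 1.5 natural-log units),
so ground truth does not shift with the seed. The default planted-marker
taxon sits at the upper-quartile abundance rank: differential genera of
interest in this kind of study are drawn from the most abundant genera, and
a design-time power evaluation showed Kruskal–Wallis detection of a log2
effect of 3 at these settings is ≈ 1.0 for an upper-quartile marker
(≈ 0.96 at the median rank) — driving the ≥ 95% detection requirement the
acceptance suite checks.

Physiology linkage: indicator = α + β·log10(relative abundance + 1/depth)
+ N(0, σ²); the 1/depth pseudocount avoids −∞ while preserving rank order
among nonzero counts, so σ = 0 linkages give Spearman ρ = ±1 exactly.

What the generators do **not** emulate: taxonomic misassignment, variable
sequencing depth, compositional correlation structure between taxa beyond
the Dirichlet's, spatial/temporal autocorrelation, or realistic phylogenetic
structure in the lineage strings. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under a known model, not
that real rhizosphere data meet that model's assumptions.

## Problem sizes and determinism

The test and acceptance runs use the study design (4 groups × 6 samples,
150 taxa, depth 1e5), 500 transients for recovery, 400 null data sets for
ANOSIM calibration, 100 replicates for biomarker power and 200 for the
correlation null. Every stochastic operation takes an explicit seed and is
reproducible bit-for-bit; the acceptance script derives all its seeds from
one `--seed` argument.

## Known limitations

* The JIP engine assumes log-spaced sampling reaching ~20 µs; curves from
  instruments that start later than 50 µs are rejected rather than
  extrapolated.
* ACE is computed on raw counts without rarefaction; samples at very
  different depths are not made comparable first.
* The biomarker stage is restricted to two groups; one-against-all
  multi-group designs are out of scope.
* PI_ABS is reported as +inf (flagged), not censored, when φPo or ψo
  saturate; downstream group means propagate the inf deliberately.
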