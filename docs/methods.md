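# Methods

`tsmr` implements two-sample Mendelian randomization (MR) on GWAS summary
statistics. This note records the statistical model, the conventions chosen
where several are defensible, and what the packaged tests do and do not
establish.

## Model and assumptions

For variant *j*, let β̂_xj (SE σ_xj) be its estimated per-allele effect on
the exposure and β̂_yj (SE σ_yj) its effect on the outcome, estimated in
non-overlapping samples. Under the instrumental-variable assumptions
(relevance, no confounding of the variant–outcome relation, and exclusion —
the variant affects the outcome only through the exposure), each variant
yields a Wald ratio estimate of the causal effect θ:

    θ̂_j = β̂_yj / β̂_xj,   se(θ̂_j) ≈ σ_yj / |β̂_xj|   (first-order delta method)

The first-order SE ignores exposure-side noise; a second-order option adds
the β̂_yj²σ_xj²/β̂_xj⁴ term but is off by default because the first-order
weights are what standard IVW, Cochran's Q and the published analyses use.

### Estimators

* **IVW** — weighted least squares of β̂_y on β̂_x through the origin with
  weights 1/σ_yj², algebraically identical to the inverse-variance-weighted
  mean of Wald ratios (the test suite asserts agreement to 1e−12). The point
  estimate is the same under the fixed-effect model (SE = (Σβ̂_xj²/σ_yj²)^−½)
  and the multiplicative random-effects model, which inflates the SE by
  max(1, √(Q/(k−1))) and is the default, matching common practice in MR
  software. The SE is never deflated below the fixed-effect value.
* **Weighted median** — the interpolated weighted median of Wald ratios
  with weights β̂_xj²/σ_yj² (inverse first-order ratio variances):
  ratios are sorted, standardized cumulative mid-weights p_j = (Σ_{i≤j}w_i −
  w_j/2)/Σw are formed, and the estimate interpolates linearly at p = 0.5.
  Consistent when valid instruments carry more than half the weight. The SE
  is a parametric bootstrap: β̂_x and β̂_y are resampled from
  N(β̂, σ) per variant, the median re-estimated (default 1,000 replicates),
  and the replicate SD taken. The seed is a mandatory argument.
* **MR-Egger** — weighted regression of β̂_y on β̂_x *with* intercept,
  weights 1/σ_yj². The intercept estimates the mean directional pleiotropic
  effect; the slope is consistent for θ under the InSIDE assumption.
  SEs are scaled by max(1, residual SE) (multiplicative random effects);
  inference uses normal quantiles by default with a t(k−2) option. Because
  the estimator is orientation-sensitive, exposure effects must be oriented
  to the exposure-raising allele — instrument construction enforces β̂_x > 0.
* **MR-PRESSO** — the residual-sum-of-squares pleiotropy test. The observed
  statistic is Σ_j w_j (β̂_yj − θ̂_(−j) β̂_xj)² with leave-one-out slopes
  θ̂_(−j); its null distribution comes from parametric simulation
  (β̂_x* ~ N(β̂_x, σ_x), β̂_y* ~ N(θ̂_(−j)β̂_xj, σ_y), default 1,000 draws)
  with the leave-one-out statistic recomputed per draw. The global p is the
  exceedance fraction (resolution 1/n_sim; an exact zero is reported as
  the floor 1/n_sim with a flag). Per-variant outlier p-values compare each
  observed leave-one-out residual with its simulated distribution,
  Bonferroni-corrected across k (threshold 0.05). When outliers are removed,
  the estimate is recomputed and a distortion test resamples outlier-free
  subsets (with replacement) to reference the percentage shift of the
  estimate. MR-PRESSO's own causal estimates use the weighted
  origin-regression with lm-style empirical residual scaling (no flooring at
  1), a normal-theory 95% CI, and a t reference with k−1 (raw) or
  k−1−#outliers (corrected) degrees of freedom — the convention of the
  reference implementation of this test, which the packaged study's printed
  intervals follow.

### Heterogeneity and sensitivity

Cochran's Q uses the same first-order weights as IVW: Q = Σ w_j(θ̂_j −
θ̂_IVW)², referenced to χ²(k−1). I² = max(0, (Q−(k−1))/Q)·100% (the
clipping reproduces printed "0.0%" entries when Q < df). The I² confidence
interval uses the test-based method of Higgins & Thompson on H = √(Q/df);
the source study does not name its CI method, so these bounds are a
documented convention, not a reproduction target. Leave-one-out analysis
re-runs a chosen estimator with each variant excluded in turn, preserving
input order, and appends the all-variant estimate; it is exported as a
table (one row per excluded variant), the tabular equivalent of a
leave-one-out forest plot.

### Instrument strength and power

Three variance-explained formulas are implemented (see the module
docstring): the F-statistic identity r² = β²/(β² + Nσ²) is the default
because it reproduces the packaged study's per-variant column; the variant
with an extra factor 2 in the denominator is retained verbatim as
`printed_formula_1` because some sources print it that way — it roughly
halves every value and its discrepancy is documented rather than silently
corrected. The allele-frequency form 2·MAF·(1−MAF)·β² requires EAF and
raises a targeted error without it. Table-style totals sum per-variant
percentages after rounding to 2 decimals, matching how a printed column
totals; the unrounded total is also exposed.

Power for a binary outcome uses the non-centrality approximation of the
mRnd calculator: power = Φ(√(N·R²·K(1−K))·|ln OR| − z_{1−α/2}), K the case
fraction; continuous outcomes drop K(1−K) and use |β|. The minimal
detectable OR inverts this in closed form, |ln OR| = (z_{1−α/2} +
z_{power})/√(N·R²·K(1−K)); the round trip power(detectable_or(p)) = p holds
to 1e−9. This form was adopted because it exactly reproduces the study's
published detectable OR of 0.84 for the IGAP dataset (N = 63,926, K =
21,982/63,926, R² = 0.0179, α = 0.05); it is an approximation that ignores
case-control ascertainment corrections beyond K(1−K).

## Harmonization conventions

Outcome records are aligned to the exposure-raising allele: matching allele
labels copy the outcome effect, swapped labels negate it, irreconcilable
allele sets drop the variant with a recorded reason. Nothing is silently
lost — every instrument ends with exactly one status (direct / flipped /
proxied / dropped) and an audit log row.

Palindromic variants (A/T, C/G) cannot be aligned by labels. The default
policy, `proxy_required`, substitutes *every* palindromic instrument by a
high-LD proxy measured in the outcome GWAS (exposure effect retained from
the original instrument, outcome effect taken at the proxy through the
proxy map's allele correspondence), because the packaged study proxied its
C/G instrument even though its frequency (EAF 0.32) was not ambiguous. A
substitution is refused when the proxy's r² falls below 0.8 (configurable).
The `infer_by_frequency` policy aligns palindromic variants whose EAF is at
least 0.08 from 0.5 in both datasets and proxies/drops the rest; the 0.08
window is our convention — the source study names no frequency criterion.
`drop` discards all palindromic instruments.

## Instrument selection

Variants must pass a p-value threshold (default 5e−8, genome-wide
significance). Independence uses a pairwise LD table with an r² < 0.01
cutoff when one is supplied; without LD information a conservative
same-chromosome 10 Mb distance window is the fallback. Among dependent
pairs the smaller-p variant is kept (greedy pruning). Note the fallback is
stricter than LD pruning: two of the packaged study's instruments sit
5.8 Mb apart on chromosome 12 yet are independent by r², so reproducing
that selection requires the LD-table rule.

## Synthetic data generator

`simulate_two_sample` draws per-variant MAFs and true exposure effects,
then emits the summary statistics two independent GWAS would report, with
SEs from the standard 1/√(2p(1−p)N) form (binary outcomes add the K(1−K)
Bernoulli variance factor; effects are generated directly on the log-odds
scale, sidestepping liability-scale conversion). True instrument effects
are shared between the samples — no winner's-curse modelling — and the two
noise draws are independent, the defining feature of the two-sample design.
Pleiotropy modes: none, balanced (zero-mean direct effects; InSIDE holds),
directional (non-zero mean, optionally carried by only a fraction of
variants), and outlier (a few variants with inflated direct effects of
random sign). All randomness flows from one seed through spawned
sub-streams, so identical configs are bit-identical and component streams
are reproducible.

Defaults mirror the packaged study's conditions: 11 instruments with
per-allele effects 0.03–0.11 exposure-SD estimated in 52,018 samples, and
a binary outcome GWAS of 63,926 samples at case fraction 0.344.

What the generator does *not* emulate: LD between instruments, sample
overlap, winner's curse, liability-scale binary effects, and non-normal
summary noise. Passing calibration tests therefore demonstrate correctness
of the estimators under the idealized two-sample model, not robustness to
those real-data complications.

## Numerical choices and degenerate inputs

* Weighted-median interpolation clamps to the extreme ratio when 0.5 falls
  outside the mid-weight range, so a single dominant weight returns that
  variant's ratio.
* IVW with k = 1 degenerates exactly to the Wald ratio; Q-based inflation
  is skipped.
* MR-Egger refuses zero spread in β̂_x (singular design) with a
  collinearity error; estimators refuse k below their minimum (1 for IVW,
  3 for weighted median and Egger, 4 for MR-PRESSO, 2 for Q).
* A zero exposure effect cannot form a Wald ratio and raises a degenerate-
  instrument error; instrument containers enforce β̂_x > 0 up front.
* Significance conventions in the study report: suggestive at P < 0.05,
  significant at the Bonferroni level P < 0.05/4 = 0.0125 across the four
  estimation methods; the per-variant outcome screen uses P < 0.05/k.
* Coordinates are 1-based GRCh37 throughout; no liftover, no multi-allelic
  variants, no GWAS-VCF parsing.

## Problem sizes used by the test suite

The statistical property tests run at sizes chosen to give informative
Monte-Carlo error on a single CPU: 1,000 replicates for IVW CI coverage
(k = 20), 300 for MR-Egger pleiotropy recovery (k = 30), 150 for
weighted-median robustness (k = 20, 40% invalid), 150×400 simulations for
MR-PRESSO null calibration and 30×400 for outlier detection. The packaged
study itself (11 variants, 5 outcomes) runs in seconds at full fidelity.

## Known limitations

Only the published two-sample form of each method is implemented — no
multivariable MR, mode-based estimators, penalized weights, or
simulation-based power. The distortion-test resampling scheme follows the
published description; per-draw details unspecified there (subset size,
replacement) are our convention. I² CI bounds and the weighted-median
bootstrap SE are convention-dependent and should not be compared across
software at more than ~1 significant figure.
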