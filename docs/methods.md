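# Methods

This note records the model, the numerical methods and the design
choices behind `ebf`, in the order the modules build on one another.

## The bias-corrected posterior Bayes factor

The posterior marginal likelihood M_H(x) re-uses the data's own
posterior as the prior, so it systematically overstates the support for
H relative to a Bayes factor whose prior carries the same amount of
information but comes from *independent replicate data* (same sampling
model, same size). The expected overstatement in log scale,
E_Y b_H(Y), is averaged over the joint prior predictive of the data and
one replicate; subtracting it puts the EBF back on the ordinary
Bayes-factor scale. Both hypotheses are corrected, so shared bias
cancels (e.g. the two half-lines in a directional test).

Assumptions worth keeping in mind:

- the summary statistic's sampling distribution is taken as exact
  (normal/t/binomial/F), as in any test-based analysis;
- priors are the improper flat/scale-invariant references, which is the
  point of the construction: they cannot be used in an ordinary Bayes
  factor, but the bias correction makes their posterior re-use honest;
- for composite hypotheses the bias depends on the predictive
  distribution of the data. In the normal family the half-line value
  1/4 is the diffuse-location limit; for the binomial the uniform
  (α = 1) prior is the default precisely because its prior predictive is
  uniform over outcomes.

## Per-family computations

**Normal (z, χ²).** Everything is normal cdf/pdf arithmetic done on the
log scale (`log_ndtr`, log-sf differences), so regions tens of standard
errors from the estimate retain valid log masses. Beyond |z| ≈ 40 the
EBF itself over/underflows and only the log value is meaningful; the
result object keeps the log exactly and reports 0/∞ for the ratio.

**t.** The likelihood-times-posterior product collapses to a t density
with 2ν+1 degrees of freedom, so region marginal likelihoods are
cumulative-t differences times the constant C(ν). For the unrestricted
expected bias, the defining double integral reduces analytically: the
cross term is the self-convolution k = t_ν ⋆ t_ν at x − y, and X − Y has
density k, hence

    E_Y b_H(Y) = log C(ν) + differential entropy of k.

This is evaluated as nested one-dimensional adaptive quadratures
(`scipy.integrate.quad`): k(d) by splitting at the two density peaks
with a 1/(1+u) change of variable for the power-law middle, the entropy
with the heavy tail mapped through d → 1/d. Domains are truncated at
the 10⁻⁹ t quantiles. For ν = 1 the convolution is Cauchy with scale 2
and the bias is exactly log 4 = 1.386, which the quadrature reproduces
to ~10⁻⁶; the tabulated values for ν = 1..10 agree with the Monte Carlo
oracle to within its standard error. Non-integer ν is accepted (Wald
tests with fractional df); it is validated against the normal limit.

**Binomial.** All Beta quantities are log-space; incomplete-Beta masses
that underflow (e.g. Beta(9, 2000) above 0.5) switch to the exact
binomial-tail identity for integer shapes, or a 200-node Gauss–Legendre
log-sum-exp otherwise. The expected bias is the exact (n+1)²-term sum
over the joint prior predictive — no quadrature error at all. The
per-term deviation is implemented from its definition (log M_H(x) minus
the log replicate-prior marginal of x given y); the symmetric predictive
makes the posterior-normaliser terms cancel in expectation. The
negative-binomial variant (x fixed, n random) mirrors the construction
with the replicate trial-count pair summed to a truncation point
n ≤ 2000, where the neglected predictive mass is ~x/2000; model
averaging takes the arithmetic mean of the bias-corrected marginal
likelihoods with equal weights by default.

**F.** Region marginal likelihoods use the doubled-degrees-of-freedom
reduction; the one-sided (ANOVA) region (0, 1] has the closed
cumulative form. The expected bias again reduces to nested 1-D
quadratures: with h(ρ) = ∫ u f(u) f(uρ) du, the E log x terms cancel and
bias = log K − E log h(Y/X), where the density of log(Y/X) is the
self-convolution of the log-F density. Integration is done on the log
scale throughout, which tames the heavy right tail at small ν₂. The
scale hypothesis r > 1 being implausible by construction in ANOVA, the
one-sided region carries the full unrestricted bias.

**P-values.** The Beta(1, β) alternative gives closed forms in
L = log(1−p). Rewritten in M = −L all bracket terms are positive, so
the implementation is exact (no cancellation) from p = 10⁻³⁰⁰ to
1 − 10⁻¹⁶; no series switch is needed. The production bias is the
exact constant log(5/2) = 0.916; `pvalue_expected_bias` exists to
validate it and, over β ∈ {1.5, 2, 5, 10, 50}, yields values in
0.86–0.92 — "fairly constant", approaching log(5/2) for β ≳ 5. The
CLI applies an optional floor (default 10⁻³⁰⁰) instead of clamping;
p = 0 and p = 1 are rejected in the API.

**Multiple testing.** Only the normal-likelihood ensemble is
implemented (the multiplicity experiments are all normal); every term is
a closed-form normal convolution times a normal-cdf region factor,
accumulated with log-sum-exp in row blocks of 2048 so the m×m matrices
stay bounded in memory up to m ~ 10⁴. Only the own-data term is
bias-adjusted; the denominator weights never carry the adjustment.
Ranks use average tie-handling. The mixture weight defaults to
p_Θ = 1, which the screening experiment shows is near-indistinguishable
from the true weight over a wide range.

## Synthetic-data generators

`ebf.simulate` fixes the study conditions of the experiments:

- **Bias oracle**: by pivotality the normal/t/F biases do not depend on
  the true parameter, so simulation fixes μ = 0 (r = 1); the binomial
  draws p from its Beta(α, α) prior so the predictive matches the exact
  sums. Half-line normal biases depend on the location predictive and
  reach 1/4 only in the diffuse limit, approximated by an optional wide
  normal prior on μ. Defaults: 10⁵ replicates, reporting the Monte
  Carlo standard error.
- **Limited multiplicity**: m = 1..10 tests, sample size n = 100
  (sampling s.e. 1/√n), 10,000 repetitions, one independent replicate
  per mean; three mean configurations — all zero, N(0,1) random per
  repetition, and a fixed uniform grid on [−5, 5] (midpoint 0 when
  m = 1, a choice the experiments leave open). The replicate-prior
  comparator is the mixture over replicate posteriors with the same
  p_Θ; p_Θ = 1 throughout (the screening experiment shows
  insensitivity).
- **Large-scale screening**: 1000 tests, 900 null and 100 with means
  drawn N(0,1), sampling s.e. 1; single- and mixture-EBFs at
  p_Θ ∈ {1, 0.1, 0.01}, true-positive proportions over a threshold
  grid, and mean ranks of the non-null tests.

What these generators deliberately idealise: independent tests with
known, homoscedastic standard errors and exactly normal summaries.
Passing tests therefore demonstrate the internal consistency and
calibration of the method under its stated model, not robustness to
correlated tests, estimated variances or model misspecification.

## Numerical choices

- Quadrature tolerances: 10⁻⁸–10⁻¹⁰ relative on inner integrals,
  ~5×10⁻⁷ absolute on outer bias integrals — comfortably inside the
  3-significant-figure targets of the tabulated biases; infinite
  domains truncated at 10⁻⁹ tail quantiles.
- Bias values are cached per (family, parameters, region); tables
  regenerate rather than interpolate at unseen degrees of freedom.
- EBF = 1 maps to "neutral" only under exact equality; no tolerance
  band, since the two-sided knife edge z² = 1 + log 2 is a genuine
  boundary.
- Region masses that underflow switch representation (log-sf
  differences, binomial-tail identities, log-sum-exp quadrature) rather
  than clamping; a region raises an error only when its mass is a true
  float zero.
- The evidence-unit base is derived at import by bisection on the third
  derivative of the logistic function (root σ(x*) = (3+√3)/6, base
  e^{x*} = 2+√3), with the closed form as a guard; it is cached.
- Monte Carlo experiments take one `numpy` Generator per run, seeded
  explicitly; identical seeds reproduce tables bit-for-bit.

## Known limitations

- Correlated multivariate region hypotheses (d > 1) are out of scope;
  vectors are supported through the χ² form and through independent
  scalar components with additive biases.
- The one-sided ANOVA bias equals the unrestricted value by the
  implausibility argument; no separate one-sided F bias table exists.
- The negative-binomial replicate construction (what "same size" means
  when n is random) fixes x, one of several defensible readings.
- The P-value EBF assumes the Beta(1, β) alternative; for genuinely
  non-parametric tests it is a rough measure, and the 10p rule is
  intended for p ≲ 0.1 (the API warns beyond that).
- The t and F Monte Carlo oracles cover the unrestricted hypothesis
  (the tabulated case) only.
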