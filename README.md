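# ebf — empirical Bayes factors for common hypothesis tests

`ebf` computes **empirical Bayes factors (EBFs)**: Bayes factors in which
the posterior distribution from the data at hand stands in for the prior,
corrected for the optimism incurred by using the data twice. The package
is aimed at applied statisticians and epidemiologists who want a Bayes
factor at the same stage of an analysis as a P-value — from a summary
statistic alone, with no informative prior to elicit.

## The idea

For a hypothesis H: θ ∈ Θ_H, the *posterior marginal likelihood* of data
x is

    M_H(x) = ∫_Θ f(x|θ) π(θ|x) dθ / ∫_Θ π(θ|x) dθ,

the posterior predictive density of x itself. Compared with a Bayes
factor whose prior comes from independent replicate data of the same
size, log M_H is biased upward by an expected amount E_Y b_H(Y), and the
EBF is the ratio of bias-corrected posterior marginal likelihoods:

    EBF01 = M_H0(x) e^{−E b_H0} / [ M_H1(x) e^{−E b_H1} ].

For a regular normal model the expected bias is d/2 for a d-dimensional
unrestricted hypothesis, 1/4 for a half-line (1/2 when the excluded sign
is impossible a priori), and 0 for points and finite intervals. This
yields closed forms such as the two-sided z-test EBF
√2·exp(−(z²−1)/2), which favours H0 exactly when z² < 1 + log 2.
The bias for t, binomial and F families is computed by quadrature or
exact finite sums; when only a P-value is available a Beta(1, β)
alternative gives the rule of thumb **EBF01 ≈ 10p**. For ensembles of
tests, each test's alternative borrows the posteriors of the other tests
(weight p_Θ), an empirical-Bayes mixture that shrinks extreme results.

Evidence is reported in logarithmic **units of base 2+√3 ≈ 3.73**, the
Bayes factor that moves any "weaker" belief to a "stronger" one under
the curvature structure of Bayes' theorem on the logistic scale.

## Worked example

The first blinded randomised trial of stenting for angina reported an
exercise-time gain of 16.6 s over control, standard error 12.96 s
(z = 1.28, two-sided P = 0.2):

```sh
$ ebf single --type z --estimate 16.6 --se 12.96 --h0 point:0 --h1 two-sided
test_id  ebf01    log10_ebf01  units   posterior_prob_h0  favoured
inline   1.02662  0.01141      0.01995 0.50657            H0
```

The EBF of 1.03 favours "no effect" but only barely — the study carries
almost no evidence either way, rather than evidence of no benefit. The
trial's own clinically meaningful effect was 30 s; comparing
H0: effect < 30 s against H1: effect ≥ 30 s,

```sh
$ ebf single --type z --estimate 16.6 --se 12.96 --h0 less:30 --h1 greater:30
test_id  ebf01    log10_ebf01  units   posterior_prob_h0  favoured
inline   2.29036  0.35990      0.62926 0.69608            H0
```

an EBF of 2.29 for "no clinically meaningful benefit": supportive, but
below one full unit of evidence (3.73). In the same way a bare P-value
can be converted (`--type p --p 0.05` gives EBF01 = 1/2.05), and a
5σ one-sided discovery statistic gives 1.48×10⁵ in favour of a real
effect.

Python API equivalents live in `ebf.normal`, `ebf.student_t`,
`ebf.binomial`, `ebf.fdist`, `ebf.pvalue` and `ebf.multitest`;
`ebf single --help` documents the hypothesis grammar.

## Layout

- `ebf.core` — hypotheses, bias specs, the EBF assembly rule, evidence units
- `ebf.normal` — z and χ² tests, interval/directional hypotheses, comparator Bayes factors
- `ebf.student_t`, `ebf.binomial`, `ebf.fdist`, `ebf.pvalue` — per-family EBFs and expected biases
- `ebf.multitest` — mixture-posterior EBFs for test ensembles
- `ebf.simulate` — Monte Carlo bias oracle and the multiplicity experiments
- `ebf.tables`, `ebf.cli` — table regeneration and the `ebf` command line

See `docs/methods.md` for the numerical methods and design choices.
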