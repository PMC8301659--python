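# Methods

## The testing problem

Each comparison is a two-arm contrast (treatment vs control, or regimen A vs
regimen B) evaluated as a Bayesian hypothesis test. `BF01` is reported
throughout: the marginal likelihood of the data under H0 (no effect) divided
by that under H1. Values above 1 favor the null; the verbal ladder is
1/3 < BF01 < 3 "ambiguous", [3, 10) / (1/10, 1/3] "moderate", and ≥10 / ≤1/10
"strong". Exact boundary values — which never arise from floating-point
output — are assigned to the stronger category on the null side and the
weaker on the alternative side, so the categories partition (0, ∞).

Trials are never pooled: the six remdesivir trials measured different
outcomes on different scales, so each trial/outcome/subgroup is analyzed
separately and the output is a table, not a meta-analytic estimate.

## Continuous and ratio outcomes: the JZS t-test

For a two-sample t statistic with `df = n1 + n2 − 2` and effective sample
size `n_eff = n1·n2/(n1+n2)`:

* H0: standardized effect δ = 0, so t is central Student-t;
* H1: δ ~ Cauchy(0, r), and t | δ is noncentral-t with noncentrality
  δ·√n_eff.

`BF01 = f_ν(t; 0) / ∫ f_ν(t; δ√n_eff) Cauchy(δ; 0, r) dδ`.

The default scale `r = √2/2` puts half the prior mass on |δ| < 0.707 — a
deliberately diffuse "no prior indication of efficacy" choice. The prior is
two-sided and zero-centered; directional (one-sided) Bayes factors and
informed priors are out of scope. A one-sample variant
(`n_eff = n`, `df = n − 1`) is provided for completeness.

**Sign convention.** Positive t always means benefit for the first
(treatment) arm. Because "benefit" depends on the outcome (shorter time to
improvement is good; a higher recovery-rate ratio is good; a lower death
hazard is good), the benefit direction is an explicit per-comparison config
flag, never inferred from the data.

**Reconstruction paths.**

* *mean/SD per arm*: classical pooled-variance t. Pooled rather than Welch,
  because the JZS factor is defined for the classical statistic with
  `df = n1 + n2 − 2`.
* *median/Q1/Q3 per arm*: the Wan-style estimator
  `mean = (q1 + median + q3)/3`, `sd = (q3 − q1)/η(n)`,
  `η(n) = 2·Φ⁻¹((0.75n − 0.125)/(n + 0.25))` — the standard meta-analytic
  recovery of moments from quartiles, with the asymptotic IQR/1.35 rule
  available as a cross-check option. Note the finite-sample denominator is
  calibrated for *empirical* quartiles; feeding it exact population
  quartiles inflates sd by the factor `2Φ⁻¹(0.75)/η(n)` (36% at n = 5,
  0.15% at n = 1000).
* *ratio with CI*: the CI is assumed symmetric on the log scale, so
  `SE = (ln U − ln L)/(2·z_(1+level)/2)` and `z = ln(ratio)/SE`, treated as a
  t with `df = n1 + n2 − 2`. This is deliberately conservative (a z treated
  as t is slightly penalized) and is the only route available when the
  original analysis was a Cox or proportional-odds model. Every conversion
  is recorded in the results row's notes and in the log.

## Binary outcomes: 2×2 contingency Bayes factors

Arms are independent binomials: `y_i ~ Bin(n_i, θ_i)`.

* **Independent-binomial model (default).** H0: a single shared rate
  θ ~ Beta(1,1); H1: independent θ1, θ2 ~ Beta(1,1). Binomial coefficients
  cancel, giving the exact closed form
  `ln BF01 = lnB(y+1, n−y+1) − lnB(y1+1, n1−y1+1) − lnB(y2+1, n2−y2+1)`
  (y, n pooled). Evaluated through log-Gamma, finite for every valid table
  including all-zero and all-event tables — no continuity corrections.
* **Gunel–Dickey independent-multinomial variant.** The fixed-row-margin
  Bayes factor computed by standard contingency-table BF software. The H1
  marginal is identical; under H0 the shared rate carries the
  column-collapsed prior Beta(2,2) (for unit per-cell concentration), i.e.
  `ln BF01` gains `lnB(y+2, n−y+2) − lnB(2,2)` in place of the uniform-null
  term. The two variants differ materially for small or very unbalanced
  tables and converge as counts grow.

The independent-binomial model is the pipeline default because it is the
model the reference reanalysis of these trials describes (uniform priors on
the joint rate under H0 and on each arm's rate under H1) and because it is
the variant that reproduces that reanalysis's published numbers (below).
The fixed-margin sampling plan (arm sizes fixed by design) is the
design-faithful choice for randomized trials; Poisson and hypergeometric
plans are not implemented.

## Prior-scale sensitivity

Every t-based Bayes factor can be recomputed over a grid of Cauchy scales;
the default grid {√2/4, √2/2, 1, √2} spans the conventional narrow-to-
ultrawide range. A comparison is flagged *stable* when a single evidence
category is attained across the whole grid. An analogous (optional) check
varies the Beta concentration {0.5, 1, 2} for contingency tables. Curves
export as tidy long-format tables (analysis_id, scale, bf01, category).

## Numerical scheme

* The noncentral-t density is evaluated through its chi scale-mixture
  representation `f(x; ν, μ) = ∫ u·φ(xu − μ)·h_ν(u) du` (h_ν the density of
  √(χ²_ν/ν)) with a 96-node Gauss–Legendre rule over ±12 Laplace widths
  around the analytically located peak, accumulated in log space. This stays
  finite to ν ~ 10⁴ and |μ| ~ 10³, far beyond where boost-style closed-form
  densities overflow, and matches reference values to ~10⁻⁵ where both exist.
* The H1 marginal over δ is integrated in prior-CDF coordinates
  (v = F_Cauchy(δ), so the heavy tails are exact) with breakpoints at 0 and
  at the likelihood bump δ̂ ± {6, 30}/√n_eff, using nested 24/48-node
  Gauss–Legendre panels bisected adaptively to a relative tolerance of 10⁻⁶.
  Non-convergence raises an explicit error; there is no silent fallback.
  The integrand is exponentiated relative to its peak, and the null density
  enters through `logpdf`, so |t| up to ~40 and n up to ~10⁴ are stable.
* The two-sided factor is an even function of t and is evaluated at |t|,
  making BF01(t) = BF01(−t) bitwise exact.
* Cross-checks in the test suite: (i) a dense-trapezoid integration over δ
  built on an unrelated density implementation; (ii) the Zellner g-prior
  mixture form of the same quantity (integrating g ~ InvGamma(1/2, r²/2)
  analytically in δ), an algebraically independent derivation. Both agree
  with the implementation to better than 10⁻⁴ relative error across
  t ∈ [−6, 6], n/arm ∈ {5, 30, 500}, r ∈ {0.354, 0.707, 1.414}.
* Results tables carry 4 significant figures; the display column uses
  2 significant figures with a minimum of one decimal (45.37 → "45.4",
  0.1329 → "0.13") — a documented convention of this package, chosen to
  match how such tables are conventionally printed. The stored evidence
  category is computed from the serialized 4-figure value so each row is
  self-consistent.

## The packaged six-trial config

`src/trialbf/data/remdesivir_trials.json` encodes fifteen comparisons from
the six remdesivir trial publications (ACTT-1 preliminary and final reports,
Wang et al., GS-US-540-5773, GS-US-540-5774, WHO Solidarity interim
results), using the summary statistics those publications print: per-arm
death and clinical-improvement counts, recovery rate ratios, improvement
hazard ratios, and proportional-odds ratios with their 95% CIs. The
Solidarity no-ventilation subgroup counts are derived from the publication's
totals minus its ventilated-at-entry deaths.

A published Bayesian reanalysis of these six trials reports BF01 values for
exactly these fifteen comparisons. All ten count-based comparisons reproduce
that reanalysis at its printed precision with the independent-binomial
default (0.75, 2.8, 8.3, 5.4, 0.97, 9.1, 0.27, 3.3, 45.4, 15.8) — and do
*not* reproduce it under the Gunel–Dickey variant (e.g. 26.9 instead of 45.4
for Solidarity), which is why independent-binomial is the default. The five
ratio-CI comparisons do not match the published values under any documented
conversion of the trials' printed intervals:

| comparison | published | this package | required \|t\| | converted \|t\| |
|---|---|---|---|---|
| ACTT-1 prelim, recovery RR 1.32 (1.12–1.55) | 0.13 | 0.059 | 3.10 | 3.35 |
| ACTT-1 final, recovery RR 1.29 (1.12–1.49) | 0.13 | 0.036 | 3.10 | 3.50 |
| Wang early, improvement HR 1.52 (0.95–2.43) | 0.38 | 1.3 | 2.41 | 1.75 |
| GS-5774, 5-day OR 1.65 (1.09–2.48) | 0.91 | 0.58 | 2.18 | 2.39 |
| GS-5774, 10-day OR 1.31 (0.88–1.95) | 5.1 | 3.8 | 1.09 | 1.33 |

The "required |t|" column inverts the JZS factor at the published arm sizes;
none of these statistics can be obtained from the printed ratios under any
CI level, direction, or log/linear reading, so the reanalysis evidently used
reconstruction inputs that were never published (its analysis files are in
an external repository, not in the article). The package reports its own
documented conversions rather than tuning toward the published numbers, and
the table above is the authoritative list of the discrepancies.

## The synthetic-trial generator

The generator emulates the three statistical structures the reanalysis
assumes:

* **continuous**: arm 1 ~ N(δ, 1), arm 2 ~ N(0, 1); both mean/SD and
  quartile summaries are emitted, so the two reconstruction paths can be
  compared on identical data;
* **binary**: per-arm binomial event counts with set rates;
* **recovery**: log-normal times (median settable directly; log-scale SD
  defaults in examples to 0.6, a typical skew for time-to-recovery data),
  right-censored at a follow-up day. Censored values contribute the censor
  day to the quartile summaries and are flagged; if at least half an arm is
  censored the observed median is degenerate and the generator refuses.

Reproducibility: each `simulate_*` output is a pure function of its
arguments; calibration runs spawn per-replicate child streams from a root
seed by counter, so any replicate can be regenerated alone.

What the generator does **not** model: ordinal 7-point clinical-status
scales (real trials' ordinal outcomes enter this package only through their
published odds/rate ratios), adaptive designs, dropout, non-proportional
hazards, or dependence between censoring and outcome. Passing calibration
tests therefore demonstrate the *statistical* behavior of the
reconstruct→BF→categorize chain under clean sampling models, not robustness
to every feature of real trial data.

**Calibration problem sizes.** The shipped calibration runs use 500
replicates per scenario — Solidarity-scale nulls at n = 1000/arm, a large
(δ = 1) effect at n = 100/arm, and a medium (δ = 0.5) effect at n = 100/arm
for the reconstruction-fidelity comparison — sizes chosen so Monte-Carlo
error on a reported frequency is ~2 points while a full run stays in the
tens of seconds.

## Known limitations

* Survival outcomes are approximated through the ratio-CI→t route; this
  mirrors what can be done from published summaries, but skewness and
  censoring mean the t model is an approximation, and the package flags
  every such conversion in its output rather than hiding it.
* Quartile-based and mean/SD-based reconstructions of the *same* trial agree
  in evidence category only when the Bayes factor lands away from category
  thresholds. At δ = 0.5 with n = 100/arm — where the sampling distribution
  of t sits near the strong/moderate boundary — the measured agreement is
  ~81% (recomputed by `scripts/acceptance.py`); with large effects (δ ≥ 1)
  agreement is essentially 100%. Quartile summaries carry ~1.65× the
  sampling noise of moment summaries, and near a threshold that noise flips
  labels; users comparing the two paths should expect disagreement exactly
  where the evidence is borderline.
* The five ratio-CI discrepancies listed above are irreducible without the
  unpublished reconstruction inputs.
* Bayesian meta-analytic pooling, posterior estimation of δ, and Bayes
  factors for tables larger than 2×2 are out of scope.
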