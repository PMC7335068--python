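# Methods

## Model

Per-SNP standardized log-odds-ratios follow a spike-and-slab normal
mixture over the M reference-panel SNPs:

- two-component: `beta ~ (1 - pi_c) delta_0 + pi_c N(0, sigma^2)`
- three-component: `beta ~ (1 - pi_c) delta_0 + pi_c [p1 N(0, s1^2) + p2 N(0, s2^2)]`, `s2^2 > s1^2`, `p2 = 1 - p1`.

Polygenicity is `M pi_c`; GWAS heritability is `h2 = M pi_c E(beta^2)`
with `E(beta^2) = sigma^2` or `p1 s1^2 + p2 s2^2` — equal to the
population variance of the true PRS `sum_m beta_m G_m` with standardized
genotypes. Under the three-component model,
`upsilon = p2 s2^2 / (p1 s1^2 + p2 s2^2)` is the heritability share of the
larger-variance component.

The sampling layer is a composite (independence) likelihood: after QC the
observed z-statistic marginalises to
`z ~ (1 - pi_c) N(0,1) + pi_c sum_h p_h N(0, 1 + n_eff s_h^2)`. An
optional LD-score mode replaces `n_eff s_h^2` by `ell_m n_eff s_h^2`.
Parameter recovery is guaranteed only when simulator and fitter use
matched modes; a full LD-convolution likelihood is out of scope.

**Effective sample size.** `n_eff = 4/(1/n_cases + 1/n_controls)`
everywhere a formula says "n". Any fixed convention works as long as the
simulator and the fitter share it; this one makes `n_eff = 2 n_cases` at a
1:1 case-control ratio.

## Quality control

Applied in order, as a single pass:

1. panel restriction, keeping SNPs present in the reference panel with
   panel MAF > 0.05; A1/A2 swapped against the panel flips the sign of the
   effect, any other allele combination drops the record;
2. per-SNP sample size `N < 0.67 x Q90(N)` removed. Q90 uses the
   nearest-rank convention (`ceil(0.9 k)`-th order statistic); the
   inequality is strict, so a record exactly at the cutoff survives.
   The cutoff is computed once from the full input; `cutoff=` can be
   passed explicitly. Naive re-application recomputes the percentile on
   the filtered subset and is not a mathematical fixed point for
   adversarial N distributions (it is for realistic ones, where most SNPs
   sit at the full study size);
3. MHC exclusion: chromosome 6, 26,000,000-34,000,000 bp, both ends
   inclusive ("between ... and" read conservatively);
4. large-effect extraction: greedy clumping of z^2 > 80, each retained top
   removing everything within 1 Mb or with squared LD > 0.1; ties in z^2
   break toward the smaller coordinate for determinism. The retained tops
   are added back to totals as `sum_i (beta_i^2 - tau_i^2)` (negative
   terms clamped at 0 with a warning) and their count to the
   susceptibility-SNP total; the "average heritability per susceptibility
   SNP" excludes them.

## Fitting

Maximum likelihood on transformed scales: logit for `pi_c` and `p2`, log
for `s1^2` and for the increment `s2^2 - s1^2` (which enforces the
component ordering). Nelder-Mead from an initialization grid with
`pi_c in {1e-4, 1e-3, 1e-2}` and variances set by method of moments from
`mean(z^2) = 1 + pi_c n_eff E(beta^2)`; the best restart wins and
optimization is deterministic. For the three-component model the grid also
contains the fitted two-component solution embedded at the
equal-variance boundary, which guarantees the nesting property
`loglik(3) >= loglik(2)` because the starting point is a Nelder-Mead
simplex vertex and the best vertex never deteriorates.

Standard errors: inverse observed information (numerical Hessian) on the
transformed scale; delta method for `pi_c`, `M pi_c`, `h2`, `upsilon`.
The large-effect add-back is treated as a constant in the SEs. Model
selection between the two fits uses BIC with the SNP count as sample size
(deterministic and mildly conservative; AIC available via `rule="aic"`).
Calibration of the reported SEs is checked by simulation: at
M = 2e5, pi_c = 0.01, sigma^2 = 1e-4, n_eff = 1e5, both h2 and pi_c fall
within 3 reported SEs of truth in >= 90% of 50 replicates.

## Projections

Two-sided power at threshold alpha:
`pow(beta) = 1 - Phi(c - sqrt(n) beta) + Phi(-c - sqrt(n) beta)`,
`c = Phi^-1(1 - alpha/2)`. Expected discoveries and variance explained are
mixture expectations of `pow` and `beta^2 pow`, plus the large-effect
terms `sum_i pow(beta_i)` and `sum_i (beta_i^2 - tau_i^2) pow(beta_i)`.
Expectations are computed by adaptive quadrature after component-wise
standardization (`beta = s_h x`), relative tolerance 1e-10, split at
x = 0; they agree with 1e6-draw Monte-Carlo oracles within Monte-Carlo
error.

The buildable-PRS variance uses `h2_PRS = A^2 / (A + S/n_eff)` with A the
absolute expected variance of selected SNPs and S their expected count
including `M (1 - pi_c) alpha` null pass-throughs. The form follows from
the signal-to-total variance ratio of a score built with estimated
coefficients (`beta_hat = beta + e/sqrt(n)` on the selected set):
`cov(PRS_hat, PRS_true)^2 / var(PRS_hat)`. It is validated against a
genotype-level Monte-Carlo oracle (individual-level cohort, empirical
covariance), agreeing to well under the 20% acceptance band (~0.4% in the
shipped configuration). The optimized threshold maximises `h2_PRS` over a
log-uniform grid on [1e-12, 0.5] (61 points plus 5e-8, so the optimum is
never worse than genome-wide significance).

Sample-size requirements invert EV(n)/h2 >= target by doubling-then-
bisection (cap n_eff = 1e8, relative tolerance 1e-3). The "fraction of
heritability explained" criterion defaults to the optimized-threshold EV
scale, configurable to the fixed genome-wide threshold.

## Absolute risk

Risk stratification uses the log-linear hazard model
`lambda(t | r) = lambda_pop(t) exp(r - h2_PRS/2)`, `r = sqrt(h2_PRS) z`.
The `exp(-h2_PRS/2)` baseline calibration makes the population-average
multiplier exactly 1 (`E[exp(r - h2/2)] = 1` for `r ~ N(0, h2)`), so the
marginal incidence is preserved in the rare-disease limit; a fully
iterative calibration against the marginal constraint is deliberately not
implemented. Residual lifetime risk to age 80 is a discrete one-year
recursion with competing all-cause mortality:
`risk = sum_t lambda(t|r) S(t)`, `S(t+1) = S(t)(1 - lambda(t|r))(1 - mu(t))`,
with annual hazards treated as per-interval probabilities (clamped at 1
with a warning if a multiplier pushes them past it). Percentile curves
evaluate z at the 1st-99th percentiles and average over baseline-age
categories with census-style weights; the representative age of each
5-year category is its lower bound. Sex-specific weight tables are
supported by supplying the appropriate weights file.

## Synthetic data generator

The generator defines the study conditions for all tests:

- **Panel**: SNPs spread over 22 chromosomes, strictly increasing
  positions, MAF ~ U(0.05, 0.5]; chromosome 6 always receives SNPs inside
  the 26-34 Mb MHC-like window (about 5% of its SNPs) so the exclusion
  filter is exercised. LD is block-diagonal AR(1)
  (`corr(i,j) = rho^|i-j|`, blocks of consecutive SNPs) — enough to
  exercise clumping and LD-aware corrections without a real LD map.
- **Effects**: i.i.d. draws from the mixture; `E(sum beta^2) = h2` by
  construction.
- **Summary statistics**: generated at the z level,
  `z ~ N(sqrt(n_eff_m) beta, 1)` (LD blocks: mean `R sqrt(n_eff) beta`,
  noise covariance R), then converted to `beta_hat = z sqrt(1/n_eff_m)`,
  `tau = 1/sqrt(n_eff_m)`. Per-SNP sample-size variation: a fraction
  `n_jitter` (default 0.05) of SNPs has its sample size multiplied by
  U(0.25, 0.9), with mean and SE scaled consistently — this puts a
  realistic minority of SNPs below the 0.67 x Q90 cutoff.
- **Life tables**: ages 30-80, flat or quadratically increasing incidence
  to a peak (default 0.005/yr), flat mortality (default 0.01/yr), and
  mildly age-decreasing baseline weights over 5-year bins 30-74
  normalized to 1.
- **Cohort mode** (M <= 5000): independent standardized normal genotypes
  and a logistic outcome; used only to validate PRS formulas.

What the generator does not emulate: realistic human LD maps, allele-
frequency-dependent architecture, imputation error, population structure,
or sample overlap between studies. Passing tests therefore demonstrate
correctness of the estimators under their own sampling assumptions, not
robustness to those real-data complications.

## Problem sizes in the shipped tests

Simulation-based tests use M between 2e4 and 2e5 SNPs, effective sample
sizes around 1e5, 5-50 replicates per property, and Monte-Carlo oracles of
1e5-1e6 draws; these sizes give Monte-Carlo standard errors comfortably
inside the asserted bands while keeping the suite fast.

## Known limitations

- The composite likelihood ignores LD in the default fitting mode; with
  LD-generated data, fits are unbiased only in matched LD-score mode.
- SEs at boundary truths (e.g. pure-null data) come from a nearly singular
  information matrix and are flagged, not repaired.
- The tail relative-risk formula is evaluated exactly as stated at the
  99th percentile; published rounded values for the weakest-heritability
  traits can differ from it at the second decimal (e.g. h2 = 0.24 gives
  2.77), which is documented rather than reconciled.
- The order-of-magnitude sample-size checks use single-slab proxies built
  from printed polygenicity and heritability; the underlying published
  curves come from unpublished multi-component fits and are not exactly
  reproducible by construction.
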