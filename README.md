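# polyarch

Polygenic architecture of complex disease from GWAS summary statistics:
how many common susceptibility variants are there, how much risk variation
do they explain, and what will larger studies and polygenic risk scores
(PRS) actually deliver?

`polyarch` is aimed at statistical geneticists and epidemiologists working
with case-control GWAS summary statistics (for example, cancer consortium
meta-analyses). From a single set of summary statistics it

1. applies the standard quality-control filters (reference-panel
   restriction, per-SNP sample-size cut, MHC exclusion, clumping of
   extreme-effect loci),
2. fits spike-and-slab normal-mixture models for the effect-size
   distribution by maximum likelihood,
3. reports polygenicity and GWAS heritability with standard errors, and
4. projects the yield of future GWAS — expected discoveries, variance
   explained, PRS variance, discrimination (AUC), tail relative risk, and
   absolute residual-lifetime-risk stratification under competing
   mortality.

Because real consortium summary statistics are access-controlled, the
package ships a first-class synthetic-GWAS generator with the same
statistical structure (mixture effects, LD blocks, per-SNP sample-size
variation, an MHC-like region, SEER-like life tables), so the whole
pipeline is testable end to end.

## The model

Standardized log-odds-ratios of the M panel SNPs follow a mixture

    beta_m ~ (1 - pi_c) delta_0 + pi_c N(0, sigma^2)                     (two-component)
    beta_m ~ (1 - pi_c) delta_0 + pi_c [p1 N(0, s1^2) + p2 N(0, s2^2)]   (three-component)

so `M pi_c` is the polygenicity and `h2 = M pi_c E(beta^2)` the GWAS
heritability — the variance of the true PRS on the log-OR scale. The
observed z-statistic of SNP m in a study of effective sample size
`n_eff = 4/(1/n_cases + 1/n_controls)` marginalises (treating SNPs as
independent after QC) to

    z_m ~ (1 - pi_c) N(0, 1) + pi_c sum_h p_h N(0, 1 + n_eff sigma_h^2),

which is maximised directly; standard errors come from the observed
information and the delta method. Loci clumped out for chi-square > 80 are
added back as `sum_i (beta_i^2 - tau_i^2)`.

Projections at threshold alpha use the two-sided power
`pow(beta) = 1 - Phi(c - sqrt(n) beta) + Phi(-c - sqrt(n) beta)`,
`c = Phi^-1(1 - alpha/2)`: expected discoveries
`ED = M pi_c E[pow(beta)]`, expected variance explained
`EV = M pi_c E[beta^2 pow(beta)]`, and the variance of the buildable PRS
`h2_PRS = A^2/(A + S/n_eff)` with A = EV and S the expected selected-SNP
count. Discrimination and tail risk follow as `AUC = Phi(sqrt(h2_PRS/2))`
and `RR(99%) = exp(-h2_PRS/2 + Phi^-1(0.99) sqrt(h2_PRS))`; absolute
residual lifetime risk to age 80 combines the PRS hazard multiplier
`exp(r - h2_PRS/2)` with age-specific incidence and competing mortality in
a one-year life table, averaged over a census-style baseline-age
distribution.

## Worked example

```python
from polyarch import *
from polyarch.projection import project_point

truth = MixtureModel(M=50_000, pi_c=0.01, components=[(1.0, 2e-4)])  # h2 = 0.1
panel = make_reference_panel(50_000, seed=7)
arch = simulate_effect_sizes(panel, truth, seed=8)
records = simulate_summary_stats(arch, 50_000, 50_000, seed=9, n_jitter=0.05)

qc = apply_qc(records, panel)
res = fit_mixture(qc.records, n_eff=100_000, M=50_000, n_components=2)
print(res.summary(qc.large_effects))
pt = project_point(res.mixture, qc.large_effects, 200_000, threshold_mode="optimized")
print(f"2x sample size: alpha*={pt.alpha:.2e} ED={pt.ed:.0f} "
      f"EV/h2={pt.ev_frac:.2f} AUC={pt.auc:.3f} RR99={pt.rr99:.2f}")
```

prints

```
Effect-size mixture model (maximum likelihood)
==========================================================
components (incl. null spike): 2
SNPs in likelihood:            47318
panel size M:                  50000
effective sample size:         100000
log-likelihood:                -68930.948
BIC:                           137883.426
converged:                     True (3/3 restarts)
----------------------------------------------------------
pi_c:                 1.0870e-02 (SE 1.03e-03)
component 1:          weight 1.000, variance 1.3415e-04
susceptibility SNPs:  569 (SE 51)
h2 (log-OR scale):    0.1012 (SE 0.0060)
  mixture part:       0.0729
  large-effect add-back: 0.0283 (26 SNPs)
upsilon:              NA (two-component model)
==========================================================
2x sample size: alpha*=3.58e-03 ED=342 EV/h2=0.96 AUC=0.586 RR99=1.95
```

The generating truth had `pi_c = 0.01` and `h2 = 0.1`: the fit recovers
the heritability (0.1012, SE 0.006) once the 26 clumped extreme loci are
added back, and projects that doubling the study would capture 96% of it
at an optimized inclusion threshold of about 4e-3, giving a PRS with AUC
0.586 and a 2-fold relative risk in the top percentile.

The same pipeline runs from the shell:

```sh
polyarch simulate --n-snps 50000 --pi-c 0.01 --sigma2 2e-4 --out-dir run/
polyarch qc  --sumstats run/sumstats.tsv --out-dir run/
polyarch fit --sumstats run/sumstats_clean.tsv --n-eff 100000 --m-panel 50000 --out-dir run/
polyarch project --fit-json run/fit.json --out-dir run/
polyarch risk    --fit-json run/fit.json --out-dir run/
# or everything from a YAML config:
polyarch all --config config.yaml
```

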