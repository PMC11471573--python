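# mrscreen

Two-sample Mendelian randomization (MR) screening and two-step MR mediation
analysis for GWAS summary statistics, with a synthetic summary-statistics
generator whose causal truth is exactly known.

The package is aimed at genetic-epidemiology analyses of the form "which of
these many molecular exposures (e.g. plasma lipid species) causally affect a
disease outcome (e.g. an ischemic-stroke subtype), and how much of each
effect runs through a candidate mediator (e.g. a circulating immune-cell
phenotype)?" — using only per-SNP association summary statistics from
non-overlapping GWAS.

## Model and estimators

For each exposure, instruments are SNPs with association p < 5×10⁻⁸,
LD-clumped greedily (discard SNPs with r² > 0.001 to a more significant
index SNP within ±10,000 kb) and required to have per-SNP strength
F = (β/se)² ≥ 10. After allele harmonization (orientation flips; palindromic
A/T and C/G SNPs resolved by effect-allele frequency or dropped when the
frequency is within 0.08 of 0.5), the harmonized pairs (β_Xj, β_Yj) feed:

- **IVW** — weighted regression of β_Y on β_X through the origin with
  weights 1/se²_Yj:
  β̂ = Σ wⱼ β_Xj β_Yj / Σ wⱼ β²_Xj; the multiplicative random-effects SE
  (default) inflates the fixed-effect SE by √max(1, Q/(k−1)).
- **Weighted median** — the 50% crossing point of the inverse-variance-
  weighted ordered per-SNP ratios β_Yj/β_Xj, SE by seeded parametric
  bootstrap; consistent when ≥50% of weight comes from valid instruments.
- **MR-Egger** — weighted regression with an unconstrained intercept after
  orienting β_X ≥ 0; the intercept estimates average directional pleiotropy.
- **Cochran's Q** over the per-SNP ratios (weights β²_Xj/se²_Yj) for
  heterogeneity; a result is "robust" when both the Q p-value and the Egger
  intercept p-value (evaluated for k > 3) exceed 0.05.

With k ≥ 3 instruments both IVW and the weighted median are reported,
otherwise IVW alone (k = 1 is the Wald ratio). Estimates are exported as
log-odds with odds ratios and 95% CIs, exp(β ∓ 1.959964·se).

Two-step mediation composes three univariable IVW estimates per
exposure→mediator→outcome triplet: total β₀ (exposure→outcome), β₂
(exposure→mediator, exposure instruments) and β₁ (mediator→outcome, the
mediator's own instruments). The indirect effect is the coefficient product
β₁β₂, the direct effect β₀ − β₁β₂, and the proportion mediated
100·β₁β₂/β₀ — reported only when total and indirect effects share sign
(otherwise NA).

## Worked example

```python
from mrscreen import (CausalScenario, IndependentLdProvider, analysis_ready,
                      build_instrument_set, harmonize_pair, run_mr,
                      sensitivity_report, simulate_triplet)

exposure, mediator, outcome, truth = simulate_triplet(CausalScenario(seed=42))
iv = build_instrument_set(exposure, IndependentLdProvider())
pairs = analysis_ready(harmonize_pair(iv.as_sumstats(), outcome))
for est in run_mr(pairs):
    print(est.method, round(est.beta, 3), round(est.or_point, 3))
```

prints (the simulated truth is a total effect of 0.30):

```
ivw_mre 0.339 1.404
weighted_median 0.324 1.383
```

and `sensitivity_report(pairs)` gives `Q = 26.56 (p = 0.228)`, Egger
intercept `+0.0081 (p = 0.100)` — no detectable heterogeneity or pleiotropy,
as planted. The scripts in `examples/` walk through a single analysis, a
mediation decomposition and a planted multi-trait screen; each prints the
numbers it computes and what they mean.

A thin CLI mirrors the library: `mrscreen simulate`, `mrscreen instruments`,
`mrscreen mr`, `mrscreen screen --config cfg.yaml`, `mrscreen mediate`
(tab-separated inputs/outputs; see `mrscreen --help`).

## Scope

No reference-panel LD computation (LD is supplied through a pluggable
provider: synthetic block-AR(1) or a square r² matrix from TSV), no proxy-SNP
lookup, no multivariable MR, MR-PRESSO or Steiger filtering, and no figure
rendering — forest-plot data are exported as tidy tables.
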