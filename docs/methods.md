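# Methods

## The analysis problem

Two-sample MR treats SNPs as instrumental variables for a heritable
exposure: if a SNP affects the outcome only through the exposure, the ratio
of its outcome and exposure associations estimates the causal effect.
`mrscreen` implements the screening form of this design — many exposures
(plasma lipid species), candidate mediators (immune-cell phenotypes) and a
small set of disease outcomes (ischemic-stroke subtypes), all observed as
per-SNP summary statistics from non-overlapping GWAS — plus the two-step
mediation decomposition that splits a total effect into a mediated and a
direct component.

MR rests on three assumptions per instrument: (1) strong association with
the exposure, (2) no effect on the outcome except through the exposure
(exclusion restriction), and (3) no confounding of the instrument–outcome
relationship. The pipeline enforces (1) directly (p < 5×10⁻⁸, F ≥ 10) and
probes violations of (2) with the Egger intercept and Cochran's Q.

## Estimation details and numerical choices

- **IVW.** Closed-form weighted origin regression. Fixed-effect SE
  (Σ wⱼβ²_Xj)^(−1/2); the default multiplicative random-effects variant
  multiplies it by √max(1, Q/(k−1)). Because of the max(1,·) floor the
  variant is deliberately never anti-conservative; under a true null its
  type-I error sits slightly below the nominal 5% (measured ≈ 4–4.5%).
  k = 2 uses the fixed-effect SE (Q has a single degree of freedom there and
  the overdispersion estimate is unstable); k = 1 collapses to the Wald
  ratio with first-order SE se_Y/|β_X|. IVW p-values are normal.
- **Weighted median.** Ratios sorted ascending with normalized weights
  β²_Xj/se²_Yj; cumulative midpoints sⱼ = Σ_{i≤j}w_i − wⱼ/2; the estimate
  interpolates the sorted ratios linearly at s = 1/2 (clamped to the extreme
  ratio when 1/2 falls outside [s₁, s_k]). The SE is the SD of the estimate
  under a parametric bootstrap (default 1,000 resamples) drawing both β_X
  and β_Y from Normal(observed, se²). The bootstrap is seeded and the pairs
  are sorted by SNP id first, so the estimate is independent of input order.
- **MR-Egger.** Pairs oriented so every β_X ≥ 0 before fitting (the
  intercept is only interpretable in that orientation). Normal-equation
  solve of the weighted regression with intercept; coefficient SEs are the
  fixed-effect SEs times max(1, σ̂), where σ̂² is the weighted residual mean
  square on k−2 df — overdispersion inflates the SEs but underdispersion
  never shrinks them below the fixed-effect values. p-values from t(k−2).
  A design with all β_X identical is singular and rejected.
- **Cochran's Q.** Computed on the Wald-ratio scale with first-order weights
  β²_Xj/se²_Yj — algebraically the weighted residual sum of squares of the
  IVW origin regression, so the heterogeneity test and the random-effects
  inflation use the *same* Q by construction. Second-order weights are not
  used.
- **CIs.** 95% bounds use z = 1.959964 (full precision) so that exported
  tables round-trip bit-exactly; rounding is cosmetic and happens only at
  display time.
- **Dispatch.** k ≥ 3 → IVW + weighted median; k < 3 → IVW only. The Egger
  intercept test requires k > 3; at k = 3 it is reported "not evaluated"
  and the robustness gate then rests on Q alone.
- **Robustness gate.** Passes iff Q p > 0.05 and (where evaluated) Egger
  intercept p > 0.05; both thresholds configurable.

## Instrument selection

Significance filtering is strict (p < threshold). Clumping is the standard
greedy algorithm: promote the most significant remaining SNP, delete
in-window (±10,000 kb, same chromosome) neighbours with r² > 0.001, repeat;
p-value ties are broken by (chromosome, position, SNP id) so the output is
order-independent. "r² > 0.001 excludes" is the conventional reading of the
clumping criterion; the alternative (retain only correlated SNPs) is
degenerate. A pair the LD provider cannot score, inside the window, is
treated as r² = 1 with a warning — the fail-safe direction, since silently
keeping a correlated instrument would understate estimator variance.
Per-SNP F = (β/se)² is the standard summary-data approximation; note that
at p = 5×10⁻⁸ it already exceeds ~29.7, so the F ≥ 10 gate only bites for
laxer p thresholds. Trait-level strength is summarized as min/mean/max F.

## Harmonization

Non-palindromic SNPs are aligned or orientation-flipped deterministically.
Palindromic SNPs are resolved by requiring both effect-allele frequencies on
the same side of 0.5 after any orientation flip; a frequency within 0.08 of
0.5 (or missing) is ambiguous and the SNP is dropped. The 0.08 half-width is
the de-facto community default. Complementary-strand rescue of
non-palindromic mismatches (A/G vs T/C) is off by default
(`allow_strand_flip`): modern summary files are forward-strand and silent
rescue risks sign errors.

## The synthetic generator

Summary statistics are simulated directly as true effect + Gaussian noise at
the analytic SE, 1/√(2p(1−p)n) — not via individual-level genotypes. This is
what two-sample MR actually consumes, it is fast, and the truth (per-SNP
effects and the implied total effect β₀ = θ + β_em·β_mo) is exactly known.
Per-SNP model: exposure instruments carry γⱼ ~ N(0, γ_sd²); mediator
instruments (a disjoint SNP set) carry their own δⱼ ~ N(0, δ_sd²); mediator
effect = β_em·γⱼ + δⱼ; outcome effect = θ·γⱼ + β_mo·(mediator effect) + αⱼ
with pleiotropy αⱼ ~ N(pleiotropy_mean, pleiotropy_sd²) drawn independently
of γ (so the InSIDE condition holds by construction). The three traits'
noise draws are mutually independent (non-overlapping samples). Giving the
mediator its own instruments mirrors real two-step MR, where exposure and
mediator GWAS hits map to essentially disjoint loci; without them the
mediator→outcome leg would be estimable only from exposure instruments and
would converge to β_mo + θ/β_em rather than β_mo.

Default scenario (chosen once as a realistic, well-powered study):

| parameter | default | rationale |
|---|---|---|
| m_snps / m_instruments / m_mediator_instruments | 70 / 30 / 30 | tens of instruments per trait, plus null SNPs |
| θ, β_em, β_mo | 0.1, 0.5, 0.4 | mediated chain over a direct effect; β₀ = 0.3, true proportion mediated 66.7% |
| γ_sd, δ_sd | 0.1, 0.15 | per-SNP F mostly 30–1000 at the sample sizes below |
| n_exposure | 50,000 | continuous-trait (lipidomic) GWAS scale |
| n_mediator | 5,000 | cytometry-cohort scale; also keeps exposure loci below genome-wide significance in the mediator GWAS, as in the disjoint-loci setting |
| n_outcome | 36,000 | *effective* sample size of a ~9,000-case / 1.5M-control binary GWAS, 4/(1/n_case + 1/n_control); outcome log-odds SEs then dominate the ratio-scale noise as in real data |
| maf_range | (0.05, 0.45) | common variants |
| palindromic_fraction | 0.2 | A/T + C/G SNPs at roughly their genomic share; frequencies drawn from U(0.05, 0.35) (or mirrored) so harmonization can succeed; an `ambiguous_palindromes` switch forces frequencies near 0.5 to exercise the drop path |

Outcome effects are simulated on the linear scale but interpreted as
log-odds; MR algebra is scale-agnostic, and this keeps the truth exactly
recoverable. LD enters only through the pluggable r² provider used by
clumping (block-diagonal AR(1): r²(i,j) = ρ^(2|i−j|) within a block, 0
across blocks); observed betas are drawn independently across SNPs.

What the generator does **not** emulate: liability-scale case-control
genetics, winner's-curse-inducing discovery/replication structure, sample
overlap between the two samples, realistic human LD maps, allele-frequency–
dependent effect-size architecture, population stratification. Passing
calibration tests on these simulations therefore demonstrates correctness of
the estimators and plumbing under the stated model, not robustness to those
real-data complications.

## Mediation

β₁ is a *univariable* mediator→outcome IVW estimate, not multivariable MR
adjusting for the exposure; with shared or correlated instruments this can
absorb part of the direct path. The direct effect is defined as β₀ − β₁β₂,
so additivity holds exactly by construction. The proportion mediated is
suppressed (NA) under inconsistent mediation (total and indirect effects of
opposite sign), where the ratio has no interpretation as a proportion. An
optional first-order delta-method SE for the indirect effect,
√(β₁²se₂² + β₂²se₁²), is provided as a labelled extension; reference
pathway tables typically print point estimates only.

## Screening conventions

Significance at IVW p < 0.05 with no multiple-testing correction — the
exploratory screening convention; a Benjamini–Hochberg option exists but is
off by default. Traits with no eligible instruments, or none surviving
harmonization against a given outcome, land in an exclusions table rather
than disappearing. Candidate mediation triplets require all three IVW links
significant; the weighted-median concordance of the exposure→mediator link
is carried as an annotation. Runs are deterministic given the config seed
(weighted-median bootstrap seeds derive from it per analysis in a fixed
order), and the manifest echoes the config, seed and package version.

## Calibration experiments (problem sizes)

`mrscreen.calibration` measures operating characteristics at desk scale:
CI coverage and null rejection use 1,000 replicates of a 30-instrument,
n = 50,000 scenario with no selection step (pure estimator calibration —
instrument selection adds winner's-curse bias, which is a separate
phenomenon); mediation recovery runs 500 full-pipeline replicates of the
default chain; screen recovery runs 20 replicate six-exposure screens.
Expected values: coverage ≈ 95%, null rejection ≈ 4–4.5% (see the max(1,·)
note above), median proportion mediated within a few points of 66.7%
(slightly attenuated by winner's curse on the mediator-instrument
selection), planted-trait recovery 100%, null false-positive rate ≈ the
5% screening alpha.

## Known limitations

Univariable β₁ (above); no proxy-SNP lookup for instruments missing in the
outcome GWAS; no reference-panel LD (bring your own r² matrix); no
MR-PRESSO/mode-based/Steiger sensitivity estimators; binary outcomes are
treated on the log-odds scale throughout, with no liability-scale
conversion.
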