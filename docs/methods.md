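# Methods

`mrpath` implements the summary-statistic Mendelian-randomization (MR)
inference chain used to ask whether a common disease exposure (diabetes
mellitus, with its subtypes) causally raises the risk of a rare outcome
(aplastic anemia), and whether an immune-cell trait mediates that effect.
This note records the statistical model, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Model

Two-sample MR treats genetic variants as instrumental variables. For variant
*j*, the exposure GWAS reports an effect `bx_j` with standard error `sx_j`
and the outcome GWAS (a different cohort) reports `by_j`, `sy_j`, both on the
log-odds scale and signed to a shared effect allele after harmonization.
Under the instrumental-variable assumptions each ratio `by_j / bx_j`
estimates the same causal slope θ.

Estimators:

- **IVW** — weighted regression of `by` on `bx` through the origin with
  weights `w_j = 1/sy_j²`: `θ̂ = Σ w·bx·by / Σ w·bx²`. The default
  *multiplicative random-effects* model inflates the fixed-effect SE by
  `√(Q/(k−1))` whenever the Cochran heterogeneity ratio exceeds 1; the point
  estimate never changes. Fixed-effects is an option.
- **MR-Egger** — the same regression with a free intercept after orienting
  every row so `bx_j ≥ 0`. The intercept estimates the mean directional
  pleiotropic effect (relative to the exposure-raising allele); the slope is
  a pleiotropy-adjusted θ. Inference is t-based with `k−2` df and the same
  multiplicative SE inflation.
- **Weighted median** — the interpolated weighted 50th percentile of the
  per-variant ratios with weights `(bx_j/sy_j)²` (first-order inverse
  variance of the ratio), consistent when ≥ 50% of weight comes from valid
  instruments. Its SE comes from a seeded parametric bootstrap (resample
  `bx`, `by` from normals at the observed values).
- **Triangulation rule** — a result is declared significant only when the
  IVW p-value is below α (default 0.05) *and* the weighted-median and Egger
  slopes share the IVW sign.

Instrument selection: genome-wide significance `P < 5×10⁻⁸` (strict), greedy
LD clumping (keep the smallest p-value, drop candidates on the same
chromosome within 10,000 kb with `r² ≥ 0.001`; ties broken by variant ID so
the output is order-independent), LD-proxy substitution (`r² > 0.8`, strict)
for instruments absent from the outcome, and strength screening via
`R² = β²/(β² + N·SE²)` per variant and `F = R²(N−k−1)/(k(1−R²))` overall,
with `F < 10` flagged as weak.

Harmonization: outcome rows are aligned to the exposure's effect allele
directly, by effect/other swap (negating `by`), or — for non-palindromic
variants — by strand complement. A/T and C/G (palindromic) variants are
excluded when the exposure minor-allele frequency exceeds 0.42 (or the
frequency is missing, since orientation is then unknowable); retained
palindromic variants are additionally frequency-aligned against the outcome
EAF. Matching is by variant ID only. Exclusions are data, not errors: every
instrument lands in exactly one of retained/excluded with a recorded reason.

Multivariable MR regresses `by` on the k×m matrix of exposure effects
(weights `1/sy²`), without intercept (MVMR-IVW, normal inference,
overdispersion-inflated SEs) or with one (MVMR-Egger, t with `k−m−1` df).
Instruments are the union of each exposure's significant variants, jointly
clumped by the minimum p-value across exposures, harmonized to the first
exposure's alleles. Egger's orientation axis is a declared option; the
pipeline pins it to the lexicographically first exposure ID so results are
invariant to input ordering. Conditional instrument strength is reported as
a diagnostic but never gated on.

Sensitivity battery: Cochran's `Q = Σ w(by − θ̂_fixed·bx)²` with `k−1` df;
the Egger intercept test (directional pleiotropy iff p < α); MR-PRESSO —
observed weighted residual sum of squares against leave-one-out IVW
predictions, a parametric null simulation (`bx* ~ N(bx, sx)`,
`by* ~ N(θ̂₋ⱼbx, sy)`) for the global test, per-variant outlier p-values
Bonferroni-adjusted across the k variants, and a global re-test plus
corrected IVW estimate after outlier removal; leave-one-out IVW with the
all-variant row labelled "All".

Two-step mediation: step 1 estimates the exposure→mediator effect β_XY with
the exposure's instruments for every candidate trait, retaining traits by
the triangulation rule with **no multiplicity correction** (an exploratory
screen, deliberately anti-conservative; a Benjamini–Hochberg switch exists
but is off by default, and an IVW-only rule is available). Step 2 estimates
the conditional mediator→outcome effect β_YZ by MVMR over (mediator,
exposure). The indirect effect is `β_XY·β_YZ` with the delta-method SE
`√(β_YZ²SE_XY² + β_XY²SE_YZ²)`; the mediated proportion is
`100·β_XY·β_YZ/β_XZ` with a delta-method CI treating the total as
independent of the product. The proportion CI method is labelled in the
output metadata; ratio CIs are known to be approximate near small totals.

## Synthetic-data generator

No real FinnGen/IEU download is required anywhere: the generator produces
summary statistics with the exact structure the estimators assume, and the
tests measure recovery of known truth. Defaults are the study conditions:

| parameter | default | why |
| --- | --- | --- |
| θ (causal slope, log-OR) | 0.11 | log of the headline odds ratio 1.12 |
| instruments `n_snps` | 67 | the reported joint instrument count |
| exposure SE scale | 0.01 | binary-trait GWAS arithmetic at the exposure cohort's size (≈219k, 16% cases): `SE ≈ 1/√(2N·2f(1−f)·φ(1−φ))` ≈ 0.009–0.01 |
| outcome SE scale | 0.05 | reproduces the published outcome CI widths (IVW SE ≈ 0.035 at k=67) |
| mediator SE scale | 0.03 | small immune-phenotype cohort; gives step-1 SE ≈ 0.02, matching the printed β_XY CI |
| σ_γ (true effect spread) | 0.15 | log-OR effect sizes typical of top diabetes loci |
| φ (exposure→mediator) | −0.13 | printed step-1 effect |
| ψ (mediator→outcome, conditional) | −0.09 | printed step-2 effect |
| direct effect | θ − φψ = 0.0983 | enforced identity `θ = direct + φ·ψ` |
| mediator panel | 731 traits, 730 decoys | the screened panel's width |

True exposure effects are `N(0, σ_γ²)` truncated to genome-wide
detectability (`|γ| > 5.45·SE_x`), so every simulated instrument is a
legitimate instrument. Pleiotropic offsets `α_j ~ N(μ, σ²)` (with a
configurable affected fraction) are applied **relative to the
instrument-raising allele** — the convention under which a directional mean
is what the Egger intercept estimates; a strand-symmetric application would
cancel under Egger's orientation and is not a directional-pleiotropy model.
The mediation triangle gives the target mediator its own detectable
instruments (`σ_δ = 0.25`, SE scale 0.03) that reach the outcome only
through ψ; these are what identify ψ in the step-2 MVMR. The multivariable
generator draws equicorrelated effect vectors (pairwise ρ = 0.5) with each
variant detectable for its primary exposure.

What the generator does **not** emulate: realistic allele-frequency spectra
and LD (LD is block-diagonal or identity by construction), sample overlap
between cohorts, winner's-curse inflation of selected effects,
non-collapsibility of odds ratios (the log-odds scale is treated as linear
throughout — the standard two-sample MR approximation), and between-variant
correlation of pleiotropy with instrument strength (InSIDE violations).
Passing tests therefore certify the inference machinery under its own
assumptions, not robustness to the ways real GWAS data break them.

## Numerical choices

- Empirical p-values (PRESSO global and outlier) use add-one smoothing
  `(count+1)/(n_sim+1)` so no finite simulation reports p = 0; 1000
  simulations by default — with ~30 instruments the Bonferroni-adjusted
  outlier p cannot fall below 0.05 with many fewer.
- All stochastic stages take explicit seeds; the pipeline derives stage
  seeds from the config seed in a fixed order, so reports are byte-identical
  across reruns.
- Clumping ties (equal p) break lexicographically by variant ID; proxy ties
  (equal r²) likewise.
- Degenerate inputs raise typed errors (`NoInstrumentsError`,
  `InsufficientInstrumentsError`, `DegenerateFrequencyError`,
  `CollinearityError`, …) rather than returning NaNs; estimator minimums
  are 2 (IVW), 3 (Egger, weighted median, leave-one-out), 4 (PRESSO),
  m+1 / m+2 (MVMR IVW / Egger).
- Exact-fit edge cases (zero residual variance) report SE 0 with p clamped
  into (0, 1].
- Screening skips mediators with fewer than 3 overlapping instruments (the
  triangulation rule needs Egger) and logs them; they are tallied, not
  silently dropped.

## Test problem sizes

The Monte-Carlo tests run at the sizes their claims need: 1000 replicates
for null IVW calibration and Q uniformity, 200 for PRESSO uniformity and
planted-outlier recovery (1000 inner simulations each), 500 for θ and
mediated-proportion recovery, 200–500 for MVMR/Egger recovery, one full
731-trait screen. Together the suite completes in a few minutes on one CPU.

## Known limitations

- The mediated-proportion CI uses the delta method; the source analysis does
  not state its interval method and its printed interval is not a
  reproduction target.
- IVW-family estimators carry a small attenuation from exposure-side
  measurement error (NOME violation); at the default instrument strength
  (mean per-variant F ≈ 250) this is ≲ 0.5% and invisible at the tested
  Monte-Carlo resolution.
- MVMR-Egger's intercept is mildly attenuated (~5% at default noise) because
  orientation uses the observed, noisy sign of the orientation exposure.
- Under the triangulation screen the null retention rate is strictly below
  the nominal α, because direction-consistency rejects some IVW-significant
  nulls; the IVW-only rule retains nulls at α exactly.
- The MR-PRESSO distortion test, mode-based estimators, Steiger filtering,
  and GWAS-VCF input are out of scope.
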