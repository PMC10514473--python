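# Methods

`clockmr` implements a summary-statistics causal-inference workflow for an
epigenetic-clock exposure (DNA-methylation age acceleration, HannumAge-style)
and a disease outcome (lung cancer), with blood proteins or metabolites as
candidate mediators. Everything operates on GWAS summary statistics — per-SNP
effect estimates with standard errors — never on individual-level data.

## Two-sample Mendelian randomization

### Model and assumptions

For instrument SNP *j*, let γ_j be its true effect on the exposure and θ the
causal effect of the exposure on the outcome (log odds for a binary outcome).
The observed summaries are modelled as

    β̂x_j ~ N(γ_j, σx_j²),    β̂y_j ~ N(θ·γ_j + α_j, σy_j²)

with known standard errors and α_j a possible horizontal-pleiotropy term.
Valid instruments require relevance (γ_j ≠ 0, enforced by the selection
thresholds and the F statistic), independence from confounders (supported by
LD clumping and a user-supplied exclusion list), and exclusion restriction
(α_j = 0, probed by the diagnostics below). The two samples (exposure and
outcome GWAS) are assumed non-overlapping.

### Instrument selection

Defaults follow standard two-sample MR practice: P < 5×10⁻⁸, minor-allele
frequency > 0.01, greedy p-value-ranked clumping at r² < 0.001 within
10,000 kb, and per-SNP F = (β/SE)² ≥ 10. Ties in p are broken by snp_id so
clumping is invariant to input row order. When a pair of SNPs falls inside
the clumping window but no r² is available, the default is conservative
removal (as when clumping against a reference panel one does not ship);
`missing_ld="retain"` suits synthetic data generated without LD. Rows with
missing allele frequency pass the MAF filter, because published instrument
tables often omit frequencies.

### Harmonization

Outcome records are oriented to the exposure's effect allele: direct or
strand-complement matches are kept, swapped alleles negate β_y and reflect
the allele frequency, and allele sets matching in neither orientation are
dropped as incompatible. A/T and C/G (palindromic) SNPs are letter-ambiguous
across strands, so they are oriented by allele frequency (minor/major side
must agree between studies) and dropped when either frequency lies within
0.08 of 0.5 or is missing. The window is configurable; 0.08 is the common
community default. Harmonization is idempotent and assigns exactly one
status per SNP.

### Estimators

All estimators pool per-SNP Wald ratios θ̂_j = β̂y_j/β̂x_j in different ways;
95% intervals use the multiplier 1.959964 and odds ratios are exp(θ̂).

* **IVW** — weighted mean with w_j = β̂x_j²/σy_j² (equivalently weighted
  regression through the origin). Fixed-effect SE is (Σw_j)^{-1/2}; the
  random-effects model inflates it by √max(1, Q/(J−1)) (multiplicative
  heterogeneity, never deflating below the fixed-effect SE).
* **Maximum likelihood** — profiles the nuisance γ_j out of the joint
  normal likelihood, leaving nll(θ) = ½Σ(β̂y_j−θβ̂x_j)²/(σy_j²+θ²σx_j²),
  minimized numerically; SE from the profile curvature. Accounts for
  exposure-side noise that plain IVW ignores.
* **MR-Egger** — weighted regression of β̂y on β̂x with a free intercept,
  instruments oriented so every β̂x ≥ 0. The slope is the causal estimate
  and the intercept estimates average directional pleiotropy; its test is
  the pleiotropy diagnostic. SEs use multiplicative overdispersion
  max(1, RSS_w/(J−2)). P-values use the normal reference, consistent with
  the fixed CI multiplier (a t reference on J−2 df is slightly wider at
  small J).
* **Weighted median** — interpolates the weight-ordered ratios at
  cumulative weight 0.5; consistent when ≥50% of weight is on valid
  instruments. SE by seeded parametric bootstrap (resampling β̂x and β̂y
  from their SEs, 1000 draws by default).
* **RAPS** — robust adjusted profile score. With standardized residuals
  t_j = (β̂y_j−θβ̂x_j)/√(σy_j²+θ²σx_j²+τ²), solves the profile-score
  equation Σψ(t_j)(β̂x_j/σ_j + t_jθσx_j²/σ_j²) = 0 jointly with the
  overdispersion equation Σ(ψ(t_j)t_j − δ)/σ_j² = 0, τ² ≥ 0 clamped, where
  δ = E[ψ(T)T] for standard-normal T (1 for the identity score, 2Φ(k)−1
  for the Huber score with k = 1.345). Both equations are exactly unbiased
  at the truth (the Huber case via Stein's identity). SE is the sandwich
  |A|⁻¹√B with A the numerical score derivative and B the summed squared
  score contributions; the τ²-estimation covariance is neglected.
* **MR-PRESSO** — residual-sum-of-squares framework. Observed
  RSS = Σ_j (β̂y_j − θ̂_(−j)β̂x_j)²/σy_j² with leave-one-out IVW
  predictions; the null distribution comes from parametric simulation of
  both β̂x and β̂y. Global p is the fraction of simulated RSS at least as
  large; per-SNP outlier p-values are Bonferroni-adjusted and flagged at
  0.05; the reported estimate is IVW with flagged SNPs removed. The
  distortion test compares the corrected estimate against removals of
  equally many random SNPs and is reported, never used to veto. Residuals
  are weighted by 1/σy_j², the inverse-variance weight natural for an
  outcome-scale residual; observed and simulated RSS use the same weights.

### Diagnostics

Cochran's Q (referenced to the fixed-effect IVW estimate, the standard
choice) with I² = max(0, (Q−df)/Q); the Egger intercept test; leave-one-out
IVW re-fits flagging omissions that exit the all-instrument CI; and funnel
coordinates (ratio vs |β̂x|/σy) with IVW/Egger reference lines, rendering
optional so the core stays headless. The Q used by the random-effects IVW
and the Q reported here are one computation.

## Genetic correlation

A method-of-moments estimator from genome-wide z-statistic pairs and LD
scores ℓ_j, assuming non-overlapping cohorts of sizes N1, N2 and M SNPs:

    ĥ² = M(mean(z²) − 1)/(N·mean(ℓ))
    ρ̂_g = M·mean(z1·z2)/(√(N1N2)·mean(ℓ))
    r̂_g = ρ̂_g/√(ĥ1²·ĥ2²)

Uncertainty by leave-one-block-out jackknife over 200 contiguous,
position-ordered SNP blocks (the LD-score-regression convention);
heritabilities are clipped to [0,1] and r_g to [−1,1] for reporting, raw
values retained. When either ĥ² ≤ 0, r_g is undefined and only the genetic
covariance is reported (with its jackknife SE). The sample-overlap
correction of the full covariance-analysis method is deliberately omitted:
the synthetic cohorts are disjoint by construction, and overlapping real
cohorts (e.g. shared controls) would need the product-moment noise term.
This is the main gap between this estimator and published genome-wide
correlation tools.

## Mediation (network MR)

Three univariable IVW steps: total (exposure instruments vs outcome), step b
(exposure instruments vs mediator), step c (mediator instruments vs
outcome, "one-to-one"). The indirect effect is the product θ̂_b·θ̂_c with
delta-method SE √(θ_b²se_c² + θ_c²se_b²) assuming independent steps (true in
the two-sample setting for b vs c; total and b share instruments, which the
delta method for the proportion ignores — a documented approximation). The
mediated proportion is indirect/total, reported as-is with a warning when
outside [0,1] (inconsistent mediation), never clipped. A mediation result is
withheld unless all three steps succeed.

Step c instruments come from the mediator GWAS under the same selection
thresholds, optionally restricted to a cis-region SNP list. This matters:
SNPs that act on the mediator only through the exposure estimate
(d + b·c)/b in step c, not c, whenever a direct path d ≠ 0 exists. Mediator-
specific (cis-pQTL-like) variants avoid that bias, which is why the
synthetic triplet carries its own cis instrument set and why protein
mediators are instrumented by variants near the encoding gene in practice.

The many-mediator screen runs step b for every candidate, takes raw
step-b p < α (default 0.05) forward, reports Benjamini–Hochberg-adjusted
step-b p-values alongside (the screen itself thresholds the raw value;
the adjustment is reported for transparency), and ranks complete results by
|indirect effect|.

## Synthetic data generator

The triplet generator emulates post-clumping GWAS instrument tables: J
LD-independent instrument SNPs with exposure effects γ_j, K mediator-specific
SNPs with effects δ_j, the causal chain exposure →(b)→ mediator →(c)→ outcome
plus a direct path d (total effect d + b·c), optional balanced or directional
pleiotropy α_j on the instrument SNPs, alleles with a configurable palindromic
fraction, EAF ~ U(0.05, 0.95), and two-sided normal p-values. Allele
recoding (random sign) negates all of a SNP's betas jointly, preserving Wald
ratios and the orientation of directional pleiotropy relative to the
exposure-increasing allele. Identical config and seed give bitwise-identical
tables.

Default magnitudes are chosen once to match the published instrument regime
for the exposure: γ ~ N(0.25, 0.10²) with random sign (the published 11
instruments have |β| 0.16–0.54), σx = 0.04 (published SEs 0.035–0.073, so
F ≈ 20–60), σy = 0.02 (case-control log-OR SE at intermediate MAF for a
~85k-sample lung-cancer GWAS), σm = 0.03 and δ ~ N(0.25, 0.05²) over K = 25
cis SNPs (protein-QTL scale for a few-thousand-sample proteomic GWAS). The
z-pair generator draws per-SNP bivariate normal z's with
Var = 1 + N·h²·ℓ/M and Cov = √(N1N2)·r_g·√(h1²h2²)·ℓ/M (no overlap term),
ℓ ~ 1 + Gamma(2, 25); defaults M = 20,000, h² = 0.3, r_g = 0.135,
N = 20,000 — the genetic-correlation regime the pipeline is meant to detect.

What the generator does **not** emulate: LD between instruments (tables are
post-clumping by construction), winner's curse beyond explicit p-value
selection, sample overlap, population stratification, allele-frequency-
dependent SE heterogeneity, or individual-level genotypes. Passing tests
therefore demonstrate correctness of the estimators under their own
assumptions and calibrated behaviour under the stated violations
(heterogeneity, balanced/directional pleiotropy, single outliers) — not
robustness to the full messiness of real GWAS.

## Numerical and testing choices

* CI multiplier fixed at 1.959964; OR reporting is exactly exp(θ).
* ML uses bounded scalar minimization (xatol 1e-12) bracketed around the
  IVW estimate; the SE uses a central-difference second derivative.
* RAPS solves θ by bracketed root-finding expanded from the IVW estimate
  and τ² by outer bisection with the clamp at 0 applied when residuals are
  underdispersed; no root in the expanded bracket is a hard error naming
  the bracket.
* All stochastic procedures (bootstrap, PRESSO simulation, generators) take
  explicit seeds; identical seeds give identical output, and the pipeline
  manifest records seeds, versions, row counts and table checksums.
* Monte-Carlo suite sizes (200–500 replicates, J = 50 instruments,
  M = 10–20k SNPs, PRESSO at 500–1000 simulations) are chosen so every
  distributional check has enough resolution for its stated band while the
  whole suite stays interactive on one CPU.
* The robustness-ordering experiment spikes one instrument by 30 outcome
  SEs. Estimator errors share the instruments' sampling noise (error
  correlation ≈ 0.8), so an outlier-robust method beats plain IVW at most
  Φ(bias/2σ) of the time; a 10-SE spike (right for testing outlier
  *flagging*) caps that probability near 0.76 regardless of estimator,
  while 30 SEs (log-OR 0.6, the scale of a strong smoking-behaviour locus)
  puts the single-SNP bias near 4σ and makes the ordering a property of
  robustness rather than luck.
* The mediated-proportion recovery check compares the mean estimate over
  200 replicates against the estimator's own delta-method SE. The per-
  replicate proportion is a ratio statistic with an O(cv²) convexity bias
  and heavy right tails from the reciprocal of the total effect, so its
  Monte-Carlo mean is not a SEM-consistent estimator of the target; the
  delta-SE band is stable across seed families and still falsifies sign,
  product and scale errors.

## Known limitations

* No multivariable MR, Steiger filtering, CAUSE-style or contamination-
  mixture models; no trim-and-fill or Rücker model selection.
* Genetic correlation: no sample-overlap correction and no annotation-
  stratified covariance; LD scores are inputs, never estimated from
  genotypes.
* First-order Wald SEs throughout; at the instrument strengths targeted
  (F ≥ 20) higher-order terms are negligible, but weak-instrument settings
  (F near 10) would understate uncertainty slightly.
* The confounder screen is an exclusion list supplied by the user; no live
  catalogue lookups.
* Proportion CIs use the delta method; bootstrap or Fieller intervals would
  be preferable when the total effect is imprecise.
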