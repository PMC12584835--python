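# Methods

This note documents the statistical model behind `mrkit`, the defaults
and numerical choices, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Model and assumptions

Two-sample MR treats genetic variants as instrumental variables: a
variant j with per-allele effect b_X,j on the exposure (SE s_X,j,
estimated in one cohort) and b_Y,j on the outcome (SE s_Y,j, a second,
non-overlapping cohort) identifies the causal effect θ as the slope
b_Y,j ≈ θ·b_X,j, provided the three IV conditions hold: association
with the exposure, independence from confounders, and no path to the
outcome other than through the exposure (no horizontal pleiotropy).
Binary traits are handled on the log-odds scale; a slope then
exponentiates to an odds ratio per unit exposure.

Estimators (all on a harmonized set of n variants, weights
w_j = 1/s_Y,j² unless stated):

- **IVW**: θ̂ = Σw·b_X·b_Y / Σw·b_X², the weighted regression through
  the origin. Fixed-effects SE = (Σw·b_X²)^(-1/2); the default
  multiplicative random-effects model inflates it by
  max(1, √(Q/(n−1))), where Q = Σw(b_Y − θ̂·b_X)² is Cochran's
  heterogeneity statistic (chi-square, n−1 df). The inflation is never
  allowed below 1, so the estimator is mildly conservative under exact
  homogeneity (measured type-I error ≈ 4–5% at α = 0.05).
- **MR-Egger**: the same regression with a free intercept, fitted after
  flipping variant signs so every b_X ≥ 0 (the standard identifiability
  orientation). The intercept estimates average directional pleiotropy;
  its two-sided test is the pleiotropy test. SEs use the n−2 residual
  scaling, same max(1, ·) rule.
- **Weighted median**: the interpolated 50th percentile of the
  ratio-estimate distribution (ratios b_Y/b_X, weights 1/ratio-SE²,
  cumulative midpoints s_j = cum(w)_j − w_j/2). Consistent when valid
  instruments carry > 50% of weight.
- **Weighted mode**: argmax of a Gaussian-kernel weighted density of
  the ratios; bandwidth = factor × 0.9·min(sd, MAD/0.6745)·n^(−1/5)
  (MAD-robust modified Silverman rule), argmax on a 512-point grid
  spanning the ratio range ± 3 bandwidths. Consistent when the largest
  homogeneous cluster is valid.
- Median/mode SEs: seeded parametric bootstrap (default 1000
  replicates) redrawing per-variant effects from their estimated
  normal distributions.
- **MR-PRESSO**: observed RSS = Σ over j of the weighted squared
  residual of variant j about the IVW fit excluding j; its null
  distribution comes from parametric simulation (default 1000 draws)
  around the leave-one-out fitted values. Global p, per-variant
  outlier p (Bonferroni × n) and a distortion test (estimate shift
  after outlier removal vs the shift from removing random subsets of
  the same size). Empirical p-values use add-one smoothing, so the
  resolution is 1/(n_sim+1) and the smallest achievable
  Bonferroni-adjusted outlier p is n/(n_sim+1): detecting outliers
  among n variants needs n_sim comfortably above n/α.
- **MVMR-IVW**: weighted multiple regression of b_Y on the matrix of
  several exposures' effects, no intercept; per-coefficient covariance
  from the weighted normal equations, scaled by max(1, √(Q/(n−k))).
- **Two-step mediation**: β₀ (total, univariable IVW after PRESSO
  pruning), β₁ (exposure→mediator, univariable IVW), β₂
  (mediator→outcome adjusted for the exposure, MVMR). Indirect
  = β₁β₂, direct = β₀ − β₁β₂ (additivity holds exactly by
  construction), proportion = β₁β₂/β₀. First-order delta variances:
  Var(β₁β₂) = β₁²se₂² + β₂²se₁² (independent two-sample estimates,
  covariance taken as zero — a documented approximation), and for the
  proportion Var = Var(β₁β₂)/β₀² + (β₁β₂)²Var(β₀)/β₀⁴; propagation of
  the β₀ term can be disabled for sensitivity. Pathways are screened
  at nominal α = 0.05 on β₁ and β₂ with sign consistency against β₀;
  no multiple-testing correction across candidate mediators by
  default (a Bonferroni switch exists).

## Instrument selection and harmonization

Selection: p < 5×10⁻⁸ (strict), minor-allele frequency > 0.01 (strict;
variants with unreported EAF dropped by default), greedy clumping
(smallest p first, ties broken by chromosome, position, then variant
id; window 10,000 kb centre-to-centre inclusive; r² threshold 0.001
when an LD matrix is supplied, distance-only otherwise), then
F = (β/se)² > 10 (strict). A user-supplied exclusion list implements
confounder-associated-variant removal. All stages log attrition
counts.

Harmonization aligns on allele labels (literal comparison, leading
"chr" stripped from chromosomes, 1-based positions): a label swap
negates the effect and reflects the EAF. Palindromic A/T and C/G pairs
cannot be resolved by labels; they are oriented by EAF concordance
when both frequencies lie outside the ambiguity band [0.42, 0.58]
(configurable) and dropped as ambiguous otherwise — missing EAF on
either side means ambiguous. Within-table duplicate ids keep the
smallest-p record. No strand inference from a reference genome, no
liftover, no indel normalization.

## Synthetic data generator

The generator simulates summary statistics directly at the summary
level (no individual genotypes) from the structural model
X → M → Y with coefficients θ_XM, θ_MY and direct path θ_XY; the true
marginal effects are b_X = γ, b_M = θ_XM·γ + δ, b_Y = (θ_XY +
θ_XM·θ_MY)·γ + θ_MY·δ + α + η, where γ, δ, η are
exposure-/mediator-/outcome-specific instrument effects and α is
horizontal pleiotropy (applied to exposure instruments and null
variants, oriented relative to the exposure-raising allele so that a
positive mean biases the causal estimate upward). Observed effects are
drawn as normal(true, se²) with se = (2·n·EAF·(1−EAF))^(−1/2) (the
per-allele, unit-variance-trait approximation) from three independent
streams — the non-overlapping cohorts of a two-sample design.

Defaults are the study conditions of the motivating application:
θ_XY = 0.10, θ_XM = 0.385 (= log 1.47), θ_MY = 0.19 (= log 1.21),
hence a true total effect of 0.173 log-odds (OR 1.19) and a true
mediated proportion of 42.25%; cohorts of 300,000; 100 exposure and
100 mediator instruments plus 10× as many null variants so selection
and attrition logic is exercised. Per-instrument strength is
controlled through the F statistic: a target F is drawn as f_floor +
Exponential(mean = f_mean − f_floor) with f_mean = 60 and f_floor = 35,
and |γ_j| = se_j·√(F_j − 1), so the expected observed F equals the
drawn target. The floor keeps planted instruments almost always
genome-wide significant (z ≳ 5.8) while the mean matches a
strong-instrument GWAS regime; a handful of the weakest instruments
still miss the p < 5×10⁻⁸ cut in any one realization, which is
realistic attrition. Planted signals are laid out more than one
clumping window apart (round-robin over 22 chromosomes of 250 Mb);
optional block-diagonal LD with within-block decay r²(d) = ρ^d
supports clumping tests.

What the generator does **not** emulate: LD between signal and null
variants (beyond the optional blocks), population structure,
relatedness, sample overlap, winner's curse in the discovery GWAS,
allele-frequency differences between cohorts, binary-trait
noncollapsibility, or strand errors. Passing tests therefore
demonstrate correctness of the estimators and pipeline logic under the
stated sampling model, not robustness to those real-data complications.

## Numerical choices

- p-values: two-sided normal for all slope/intercept tests (no
  t-distribution), chi-square for Q; empirical p-values with add-one
  smoothing for PRESSO.
- 95% intervals use z = 1.96 (normal quantile); ORs are exp of the
  log-odds point and interval.
- Weighted regressions solve the normal equations via
  `numpy.linalg.solve`; the test suite cross-checks against an
  independent QR/lstsq route at 1e-10 relative tolerance.
- Rank deficiency in MVMR raises an error naming the most collinear
  exposure pair (detected via matrix rank, attribution via the
  largest absolute column correlation).
- Degenerate inputs: zero exposure effects are excluded from ratio
  estimates with a warning path; constant exposure effects make
  PRESSO refuse; an all-identical-ratio set returns that ratio from
  the median/mode with a floor bandwidth.
- Seed policy: every stochastic component takes an explicit seed;
  pipeline stages derive child seeds from the run seed and a stable
  CRC of the stage name, so runs are bit-reproducible and stages are
  decoupled.

## Design decisions taken where the design was open

- Multiplicative random-effects scaling as the default for IVW, Egger
  and MVMR (fixed-effects by flag): the dominant two-sample
  convention, conservative under heterogeneity.
- PRESSO outliers are always removed before re-estimation; the
  distortion test is reported but never vetoes removal.
- The total effect β₀ entering the mediated proportion is the IVW
  estimate after PRESSO pruning.
- MVMR instruments: union of per-exposure selections, jointly
  re-clumped with the smallest cross-exposure p as priority.
- Reverse-direction analyses with too few instruments return a
  structured "not estimable" result instead of raising.

## Known limitations

- **Weak-instrument attenuation.** IVW's denominator Σw·b̂_X² is
  inflated by exposure measurement error, giving E[θ̂] ≈ θ·(1 − 1/F̄);
  MVMR coefficients are diluted the same way. At the generator's mean
  F = 60 the repeated-simulation calibration
  (`analysis/04_calibration_study.py`, and the acceptance suite)
  measures the mediated proportion a few percent of its value below
  the generative truth, while the delta-method CIs still achieve
  93–97% coverage. No dilution correction (e.g. debiased IVW) is
  implemented.
- **PRESSO outlier specificity.** A strong outlier shifts every
  leave-one-out fit, displacing clean variants' residuals by roughly
  (offset)·s_Y/n and inflating the family-wise false-flag rate of the
  Bonferroni outlier test above its nominal level (measured ~5–7% for
  a 10×SE spike among 30 instruments, against a nominal ~3% that the
  implementation attains exactly under a clean null). Co-flagging of
  one clean variant alongside a true outlier therefore occurs in a few
  percent of datasets.
- The weighted median's midpoint-interpolation rule is not exactly
  invariant to splitting a variant's weight in half when the split
  variant brackets the median (the interpolation knots move); the
  invariance holds exactly for non-bracketing variants.
- β₁/β₂ covariance is assumed zero; with genuinely non-overlapping
  cohorts this is correct to first order, but shared instruments
  induce a small dependence through the selection step.
- The first-order delta method describes the bulk spread of the
  proportion; when the total effect is within a few SEs of zero the
  true sampling distribution of a normal ratio is heavy-tailed and
  the CI should not be trusted (the `proportion_out_of_unit_interval`
  and `inconsistent_sign` flags mark the symptomatic cases).
- Continuous mediators are analysed on their native scale; the
  mediated proportion is scale-invariant to mediator units, but OR
  reporting only makes sense for binary traits.
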