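# mrkit — two-sample Mendelian randomization with mediation analysis

`mrkit` implements the complete causal-inference workflow used in
summary-statistics Mendelian randomization (MR) studies of disease
progression — the motivating application is the question of whether
gastroesophageal reflux disease (GERD) causally raises the risk of
chronic-kidney-disease progression, and how much of that effect runs
through metabolic mediators such as type 2 diabetes and systolic blood
pressure.  It is aimed at genetic epidemiologists who work from GWAS
summary statistics rather than individual-level data.

## What it computes

Given per-variant association tables (beta, SE, p, alleles, EAF) for an
exposure *X*, mediator(s) *M* and outcome(s) *Y* from non-overlapping
cohorts:

* **Instrument selection** — genome-wide significance (p < 5×10⁻⁸),
  MAF > 0.01, greedy LD clumping (10,000 kb window, r² ≤ 0.001) and the
  per-variant strength filter F = (β/se)² > 10.
* **Harmonization** — effect alleles aligned across tables; palindromic
  (A/T, C/G) variants resolved by allele-frequency concordance or
  dropped when ambiguous.
* **Univariable MR** — inverse-variance-weighted (IVW) regression
  through the origin (primary), MR-Egger with its intercept test for
  directional pleiotropy, weighted median, weighted mode, and Cochran's
  Q heterogeneity test.
* **MR-PRESSO** — simulation-based global residual-sum-of-squares test,
  per-variant outlier test (Bonferroni-corrected empirical p-values)
  and distortion test; flagged outliers are removed before
  re-estimation.
* **Multivariable MR** — weighted multiple regression of outcome
  effects on several exposures' effects, giving each exposure's direct
  effect conditional on the others.
* **Two-step mediation** — with β₀ the total *X→Y* effect, β₁ the
  *X→M* effect (univariable) and β₂ the *M→Y* effect adjusted for *X*
  (multivariable), the indirect effect is β₁β₂, the direct effect
  β₀ − β₁β₂, and the mediated proportion β₁β₂/β₀, with first-order
  delta-method confidence intervals:
  Var(β₁β₂) = β₁²se₂² + β₂²se₁², and for the proportion
  Var = Var(β₁β₂)/β₀² + (β₁β₂)²Var(β₀)/β₀⁴.
* **Bidirectional analysis** — the same pipeline with exposure and
  outcome roles swapped.
* **Synthetic data** — a generator that simulates two-sample GWAS
  summary statistics from a known structural model
  (θ_XM, θ_MY, θ_XY; per-variant instrument effects scaled to a target
  F distribution; optional pleiotropy and LD blocks), so every stage is
  testable against a recorded ground truth.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
at the default conditions (θ_XY = 0.10, θ_XM = 0.385, θ_MY = 0.19,
three cohorts of 300,000, ~100 instruments per trait, so the true total
effect is 0.173 log-odds and the true mediated proportion 42.25%):

```bash
python analysis/01_simulate_cohorts.py 7
python analysis/02_total_and_reverse_effects.py 7
python analysis/03_mediation_decomposition.py 7
```

which prints (seed 7):

```
forward (total) effect, exposure -> outcome:
         method  n_snp   beta   or  or_low  or_high         pval
            ivw     85 0.1614 1.18    1.14     1.21 2.878609e-33
          egger     85 0.0664 1.07    0.95     1.20 2.515541e-01
weighted_median     85 0.1607 1.17    1.13     1.22 8.841679e-18
  weighted_mode     85 0.1530 1.17    1.08     1.26 1.765687e-04
attrition: {'input': 2200, ..., 'after_f_filter': 85}; PRESSO global p = 0.791
reverse direction not estimable: no instruments remain for 'outcome'

beta0 (total)    = 0.1614 +/- 0.0134
beta1 (X -> M)   = 0.3687 +/- 0.0161
beta2 (M -> Y|X) = 0.1678 +/- 0.0133
indirect = beta1*beta2 = 0.0619; direct = 0.0995
mediated proportion = 38.34% (95% CI 29.10%, 47.57%)
generative truth     = 42.25%
```

Reading this: 85 of the 100 planted instruments survive selection at
this noise level; the IVW odds ratio 1.18 estimates the true total
effect exp(0.173) = 1.19; the decomposition satisfies
direct + indirect = β₀ exactly by construction; and the delta-method CI
for the mediated proportion covers the generative truth.  The reverse
analysis is correctly reported as not estimable because the simulated
outcome has no genome-wide-significant variants of its own.
`analysis/04_calibration_study.py` repeats the study hundreds of times
to measure bias, CI coverage and type-I error.

A thin CLI wraps the same functions for shell use:
`mrkit simulate`, `mrkit clump`, `mrkit mr`, `mrkit presso`,
`mrkit mvmr`, `mrkit run --config study.yaml` (see `mrkit --help`).

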