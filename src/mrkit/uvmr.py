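"""Univariable two-sample MR estimators and diagnostics.

All estimators operate on a harmonized set of per-variant exposure
effects bx_j (SE sx_j) and outcome effects by_j (SE sy_j):

* IVW — weighted regression of by on bx through the origin, weights
  1/sy^2; the primary estimator.
* MR-Egger — the same regression with a free intercept; the intercept
  and its test quantify directional horizontal pleiotropy.
* Weighted median — the 50th percentile of the inverse-variance-weighted
  empirical distribution of per-variant ratio estimates; consistent when
  valid instruments carry more than half the weight.
* Weighted mode — the maximum of a kernel-smoothed weighted density of
  the ratios; consistent when the largest homogeneous cluster is valid.
* Cochran's Q — weighted residual sum of squares around the causal fit,
  a chi-square heterogeneity test.

Standard errors for IVW/Egger use multiplicative random-effects scaling
(never below the fixed-effects SE); p-values use the normal
approximation throughout.  Median/mode SEs come from a seeded parametric
bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import AnalysisError
from .sumstats import HarmonizedSet

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds (or native) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_value: float | None = None
    or_low: float | None = None
    or_high: float | None = None
    q_stat: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    def __post_init__(self) -> None:
        if self.or_value is None:
            self.or_value = float(np.exp(self.beta))
            self.or_low = float(np.exp(self.ci_low))
            self.or_high = float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _estimate(method: str, beta: float, se: float, n_snp: int, **extra) -> MREstimate:
    beta, se = float(beta), float(se)
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else (0.0 if beta else 1.0)
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=p,
        n_snp=n_snp,
        **extra,
    )


def wald_ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-variant ratio estimates by/bx with first-order SEs sy/|bx|.

    Variants with a zero exposure effect are excluded (the ratio is
    undefined there).  Returns (ratios, ses, variant_ids).
    """
    bx, by, sy = h.bx, h.by, h.by_se
    ok = bx != 0
    ids = [v for v, m in zip(h.variant_ids, ok) if m]
    return by[ok] / bx[ok], sy[ok] / np.abs(bx[ok]), ids


def cochran_q(h: HarmonizedSet, beta: float) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic about a given causal slope.

    Q = sum_j w_j (by_j - beta * bx_j)^2 with w_j = 1/sy_j^2, referred to
    a chi-square with n_snp - 1 degrees of freedom.
    """
    if h.n_snp < 2:
        raise AnalysisError("Cochran's Q requires at least 2 variants")
    w = 1.0 / h.by_se**2
    q = float(np.sum(w * (h.by - beta * h.bx) ** 2))
    return q, float(stats.chi2.sf(q, h.n_snp - 1))


def ivw(
    h: HarmonizedSet,
    effects_model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted estimate (regression through the origin).

    beta = sum(w bx by) / sum(w bx^2), w = 1/sy^2.  Under the
    multiplicative random-effects model (default) the fixed-effects SE is
    inflated by sqrt(Q / (n-1)) when that exceeds 1.
    """
    if h.n_snp < 2:
        raise AnalysisError("IVW requires at least 2 variants")
    bx, by, sy = h.bx, h.by, h.by_se
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = float(1.0 / np.sqrt(np.sum(w * bx**2)))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_pval = float(stats.chi2.sf(q, h.n_snp - 1))
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / (h.n_snp - 1)))
    elif effects_model == "fixed":
        se = se_fixed
    else:
        raise AnalysisError(f"unknown effects model {effects_model!r}")
    return _estimate("ivw", beta, se, h.n_snp, q_stat=q, q_pval=q_pval)


def egger(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> MREstimate:
    """MR-Egger regression: weighted fit of by = a + b*bx, weights 1/sy^2.

    Variant signs are first flipped so every exposure effect is
    non-negative (the standard identifiability orientation).  The
    intercept a estimates the average directional pleiotropy; its
    two-sided test is the Egger pleiotropy test.  SEs are scaled by
    sqrt(Q / (n-2)) when that exceeds 1.
    """
    if h.n_snp < 3:
        raise AnalysisError("MR-Egger requires at least 3 variants")
    bx, by, sy = h.bx.copy(), h.by.copy(), h.by_se
    flip = bx < 0
    bx[flip], by[flip] = -bx[flip], -by[flip]
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    dof = h.n_snp - 2
    q_pval = float(stats.chi2.sf(q, dof)) if dof > 0 else np.nan
    scale = 1.0
    if effects_model == "multiplicative_random" and dof > 0:
        scale = max(1.0, np.sqrt(q / dof))
    cov = np.linalg.inv(xtwx) * scale**2
    a, b = float(coef[0]), float(coef[1])
    se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_a = float(2 * stats.norm.sf(abs(a) / se_a)) if se_a > 0 else (0.0 if a else 1.0)
    return _estimate(
        "egger",
        b,
        se_b,
        h.n_snp,
        q_stat=q,
        q_pval=q_pval,
        egger_intercept=a,
        egger_intercept_se=se_a,
        egger_intercept_pval=p_a,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50th percentile of the weighted empirical distribution.

    With sorted ratios r_(j) and normalized weights w_(j), the cumulative
    midpoints s_j = (cumsum(w)_j - w_j/2) bracket 0.5 and the median is
    found by piecewise-linear interpolation between adjacent ratios.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _bootstrap_ratio_draws(
    h: HarmonizedSet, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric bootstrap: redraw per-variant betas from their normals.

    Returns (ratios, ses) each of shape (n_boot, n_snp).
    """
    bx = rng.normal(h.bx, h.bx_se, size=(n_boot, h.n_snp))
    by = rng.normal(h.by, h.by_se, size=(n_boot, h.n_snp))
    bx = np.where(bx == 0, np.finfo(float).tiny, bx)
    return by / bx, h.by_se / np.abs(bx)


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median MR estimate with parametric-bootstrap SE."""
    if h.n_snp < 3:
        raise AnalysisError("weighted median requires at least 3 variants")
    ratios, ses, _ = wald_ratios(h)
    weights = 1.0 / ses**2
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boot_r, boot_se = _bootstrap_ratio_draws(h, n_boot, rng)
    boot_w = 1.0 / boot_se**2
    boots = np.array(
        [_weighted_median_point(boot_r[b], boot_w[b]) for b in range(n_boot)]
    )
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", beta, se, h.n_snp)


def _silverman_bandwidth(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Modified Silverman rule on the ratio spread (MAD-robust)."""
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    spread = min(s for s in (sd, mad) if s > 0) if max(sd, mad) > 0 else 0.0
    if spread == 0.0:
        return max(1e-8, 1e-3 * max(1.0, float(np.abs(ratios).max())))
    return 0.9 * spread * n ** (-0.2)


def _weighted_mode_point(
    ratios: np.ndarray,
    weights: np.ndarray,
    bandwidth: float,
    grid_points: int = 512,
) -> float:
    """Argmax of the Gaussian-kernel weighted density over a dense grid."""
    lo = ratios.min() - 3 * bandwidth
    hi = ratios.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, grid_points)
    z = (grid[:, None] - ratios[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2) @ (weights / weights.sum())
    return float(grid[np.argmax(dens)])


def weighted_mode(
    h: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based MR estimate (weighted kernel density argmax), bootstrap SE."""
    if h.n_snp < 3:
        raise AnalysisError("weighted mode requires at least 3 variants")
    ratios, ses, _ = wald_ratios(h)
    weights = 1.0 / ses**2
    bandwidth = bandwidth_factor * _silverman_bandwidth(ratios, weights)
    beta = _weighted_mode_point(ratios, weights, bandwidth)

    rng = np.random.default_rng(seed)
    boot_r, boot_se = _bootstrap_ratio_draws(h, n_boot, rng)
    boot_w = 1.0 / boot_se**2
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bw = bandwidth_factor * _silverman_bandwidth(boot_r[b], boot_w[b])
        boots[b] = _weighted_mode_point(boot_r[b], boot_w[b], bw)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_mode", beta, se, h.n_snp)


def estimate_all(
    h: HarmonizedSet,
    seed: int | None = None,
    n_boot: int = 1000,
    effects_model: str = "multiplicative_random",
) -> dict[str, MREstimate]:
    """Run IVW, MR-Egger, weighted median and weighted mode together.

    The bootstrap-based estimators receive independent child seeds spawned
    from ``seed`` so results are reproducible as a bundle.
    """
    if h.n_snp < 3:
        raise AnalysisError("estimate_all requires at least 3 variants")
    ss = np.random.SeedSequence(seed)
    s_med, s_mode = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    return {
        "ivw": ivw(h, effects_model=effects_model),
        "egger": egger(h, effects_model=effects_model),
        "weighted_median": weighted_median(h, n_boot=n_boot, seed=s_med),
        "weighted_mode": weighted_mode(h, n_boot=n_boot, seed=s_mode),
    }
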