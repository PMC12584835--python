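"""MR-PRESSO: simulation-based pleiotropy residual sum of squares and outlier test.

The global test compares the observed leave-one-out weighted residual
sum of squares (RSS) of the IVW fit against its parametric null
distribution, obtained by redrawing every variant's exposure and outcome
effect from normal distributions centred on the (leave-one-out) fitted
values with the observed standard errors.  The per-variant outlier test
compares each variant's observed residual with its own simulated
residuals, Bonferroni-corrected across variants.  When outliers are
found, the distortion test asks whether removing them changes the causal
estimate more than removing an equally sized random subset would, and
the estimate is recomputed on the pruned set.

Empirical p-values use add-one smoothing, (1 + #{null >= obs}) /
(n_sim + 1), so they are never exactly zero and have resolution
1/(n_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AnalysisError
from .sumstats import HarmonizedSet
from .uvmr import MREstimate, ivw


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    n_sim: int
    outlier_ids: list[str]
    outlier_pvals: dict[str, float]
    distortion_pval: float | None
    estimate_before: MREstimate
    estimate_after: MREstimate | None


def _loo_residuals(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted squared residual of each variant about the IVW fit excluding it.

    Supports batched input: arrays of shape (..., n) are processed along
    the last axis with leave-one-out slopes computed from running sums.
    """
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    beta_loo = (s_xy - w * bx * by) / (s_xx - w * bx * bx)
    return w * (by - beta_loo * bx) ** 2


def presso_test(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
    run_distortion: bool = True,
) -> PressoResult:
    """Run the global, outlier and distortion tests on a harmonized set.

    ``outlier_alpha`` applies to the Bonferroni-adjusted per-variant
    p-values; flagged variants are removed before ``estimate_after`` is
    computed (IVW on the pruned set).  Note the smallest achievable
    adjusted p is n_snp/(n_sim + 1): detecting outliers among many
    variants requires proportionally many simulations.
    """
    if h.n_snp < 4:
        raise AnalysisError("MR-PRESSO requires at least 4 variants")
    bx, sx, by, sy = h.bx, h.bx_se, h.by, h.by_se
    if np.allclose(bx, bx[0]):
        raise AnalysisError("degenerate input: no variance in exposure effects")
    n = h.n_snp
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    obs_resid = _loo_residuals(bx, by, w)
    rss_obs = float(np.sum(obs_resid))

    # parametric null: effects redrawn about the leave-one-out fitted values
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    beta_loo = (s_xy - w * bx * by) / (s_xx - w * bx * bx)
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, n))
    sim_resid = _loo_residuals(bx_sim, by_sim, np.broadcast_to(w, (n_sim, n)))
    rss_sim = np.sum(sim_resid, axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    exceed = (1 + np.sum(sim_resid >= obs_resid, axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, exceed * n)
    outlier_mask = adj < outlier_alpha
    ids = h.variant_ids
    outlier_ids = [v for v, m in zip(ids, outlier_mask) if m]
    outlier_pvals = {v: float(p) for v, p in zip(ids, adj)}

    estimate_before = ivw(h)
    estimate_after = None
    distortion_pval = None
    if outlier_ids:
        pruned = h.drop_variants(outlier_ids)
        if pruned.n_snp >= 2:
            estimate_after = ivw(pruned)
        if run_distortion and estimate_after is not None and estimate_after.beta != 0:
            d_obs = (
                estimate_before.beta - estimate_after.beta
            ) / abs(estimate_after.beta)
            k = len(outlier_ids)
            d_null = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(n, size=k, replace=False)
                keep = np.ones(n, bool)
                keep[drop] = False
                b = np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(
                    w[keep] * bx[keep] ** 2
                )
                d_null[s] = (estimate_before.beta - b) / abs(b) if b != 0 else np.inf
            distortion_pval = float(
                (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1)
            )
    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        n_sim=n_sim,
        outlier_ids=outlier_ids,
        outlier_pvals=outlier_pvals,
        distortion_pval=distortion_pval,
        estimate_before=estimate_before,
        estimate_after=estimate_after,
    )
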