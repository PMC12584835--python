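"""Multivariable MR: joint weighted regression on several exposures.

Regressing the per-variant outcome effects on the effect matrix of all
exposures (no intercept, weights 1/outcome-SE^2) yields each exposure's
direct effect conditional on the others.  In the two-step mediation
design this supplies the mediator's effect on the outcome controlling
for the primary exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError
from .instruments import LDMatrix, SelectionConfig, clump, select_instruments
from .sumstats import HarmonizedSet, SumStatsTable, harmonize
from .uvmr import Z95


@dataclass
class MVMRInput:
    """Joint instrument set across exposures, aligned to the outcome."""

    variant_ids: list[str]
    exposure_labels: list[str]
    exposure_beta: np.ndarray  # n_snp x n_exposures
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray

    def __post_init__(self) -> None:
        self.exposure_beta = np.atleast_2d(np.asarray(self.exposure_beta, float))
        self.exposure_se = np.atleast_2d(np.asarray(self.exposure_se, float))
        self.outcome_beta = np.asarray(self.outcome_beta, float)
        self.outcome_se = np.asarray(self.outcome_se, float)
        n, k = self.exposure_beta.shape
        if k != len(self.exposure_labels):
            raise AnalysisError("exposure matrix does not match labels")
        if n != len(self.variant_ids) or self.outcome_beta.shape != (n,):
            raise AnalysisError("inconsistent MVMR input dimensions")
        if n <= k + 1:
            raise AnalysisError(
                f"MVMR needs more instruments ({n}) than exposures + 1 ({k + 1})"
            )

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    @classmethod
    def from_harmonized(cls, h: HarmonizedSet) -> "MVMRInput":
        bx, sx = h.exposure_matrix()
        return cls(
            variant_ids=h.variant_ids,
            exposure_labels=list(h.exposure_labels),
            exposure_beta=bx,
            exposure_se=sx,
            outcome_beta=h.by,
            outcome_se=h.by_se,
        )


@dataclass
class MVMREstimate:
    """Direct effect of one exposure conditional on the others."""

    exposure: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    conditional_q: float
    or_value: float = field(init=False)
    or_low: float = field(init=False)
    or_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.or_value = float(np.exp(self.beta))
        self.or_low = float(np.exp(self.ci_low))
        self.or_high = float(np.exp(self.ci_high))


def build_mvmr_input(
    exposure_tables: list[SumStatsTable],
    outcome: SumStatsTable,
    ld: LDMatrix | None = None,
    cfg: SelectionConfig | None = None,
    exclusion_list: list[str] | None = None,
) -> MVMRInput:
    """Assemble the joint instrument set for multivariable MR.

    Instruments are selected per exposure (significance, MAF, clumping,
    F filter), unioned, then jointly re-clumped with each variant's
    smallest p-value across exposures as its clumping priority, and
    finally harmonized across every exposure table and the outcome.
    Variants missing an effect in any table are dropped during
    harmonization.
    """
    cfg = cfg or SelectionConfig()
    if len(exposure_tables) < 2:
        raise AnalysisError("MVMR requires at least two exposure tables")
    selected: dict[str, dict] = {}
    for tbl in exposure_tables:
        inst = select_instruments(tbl, ld=ld, cfg=cfg, exclusion_list=exclusion_list)
        for _, row in inst.table.df.iterrows():
            vid = row["variant_id"]
            if vid not in selected or row["pval"] < selected[vid]["pval"]:
                selected[vid] = row.to_dict()
    union = pd.DataFrame(selected.values())
    union_tbl = SumStatsTable("union", union[_canonical_cols(union)], "")
    clumped = clump(union_tbl, ld, cfg)
    ids = clumped.variant_ids

    restricted = [t.restrict(ids) for t in exposure_tables]
    h = harmonize(restricted, outcome.restrict(ids))
    out = MVMRInput.from_harmonized(h)
    return out


def _canonical_cols(df: pd.DataFrame) -> list[str]:
    from .sumstats import CANONICAL_COLUMNS

    return [c for c in CANONICAL_COLUMNS if c in df.columns]


def mvmr_ivw(
    inp: MVMRInput,
    effects_model: str = "multiplicative_random",
) -> list[MVMREstimate]:
    """Multivariable IVW: weighted multiple regression with no intercept.

    Coefficient covariance comes from the weighted normal equations,
    multiplied by the residual heterogeneity Q/(n-k) when that exceeds 1
    (multiplicative random effects).  A rank-deficient design raises an
    :class:`AnalysisError` naming the most collinear exposure pair.
    """
    X = inp.exposure_beta
    y = inp.outcome_beta
    w = 1.0 / inp.outcome_se**2
    n, k = X.shape
    xtwx = X.T @ (w[:, None] * X)
    rank = np.linalg.matrix_rank(xtwx)
    if rank < k:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise AnalysisError(
            "collinear exposure columns: "
            f"{inp.exposure_labels[i]!r} and {inp.exposure_labels[j]!r}"
        )
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    dof = n - k
    scale = 1.0
    if effects_model == "multiplicative_random" and dof > 0:
        scale = max(1.0, np.sqrt(q / dof))
    elif effects_model not in ("multiplicative_random", "fixed"):
        raise AnalysisError(f"unknown effects model {effects_model!r}")
    cov = np.linalg.inv(xtwx) * scale**2
    ses = np.sqrt(np.diag(cov))
    out = []
    for lab, b, s in zip(inp.exposure_labels, coef, ses):
        b, s = float(b), float(s)
        p = float(2 * stats.norm.sf(abs(b) / s)) if s > 0 else (0.0 if b else 1.0)
        out.append(
            MVMREstimate(
                exposure=lab,
                beta=b,
                se=s,
                ci_low=b - Z95 * s,
                ci_high=b + Z95 * s,
                pval=p,
                n_snp=n,
                conditional_q=q,
            )
        )
    return out
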