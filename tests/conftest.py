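"""Shared fixtures: small summary-stats tables and independent WLS oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrkit import HarmonizedSet, SumStatsTable
from mrkit.sumstats import CANONICAL_COLUMNS


def make_table(rows: list[dict], label: str = "trait", unit: str = "") -> SumStatsTable:
    """Build a SumStatsTable from partial row dicts, filling sane defaults."""
    full = []
    for i, row in enumerate(rows):
        rec = {
            "variant_id": f"rs{i}",
            "chrom": "1",
            "pos": 1000 + i,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "beta": 0.1,
            "se": 0.01,
            "pval": 1e-10,
            "n": 100000,
        }
        rec.update(row)
        full.append(rec)
    df = pd.DataFrame(full, columns=CANONICAL_COLUMNS)
    return SumStatsTable(label, df, unit)


def random_harmonized(
    rng: np.random.Generator,
    n_snp: int,
    slope: float | None = None,
    intercept: float = 0.0,
    noise: float = 1.0,
) -> HarmonizedSet:
    """Random small single-exposure fixture for oracle comparisons."""
    if slope is None:
        slope = rng.normal(0, 0.5)
    bx = rng.uniform(0.05, 0.5, n_snp) * rng.choice([-1, 1], n_snp)
    bx_se = rng.uniform(0.005, 0.05, n_snp)
    by_se = rng.uniform(0.01, 0.1, n_snp)
    by = intercept + slope * bx + noise * rng.normal(0, by_se)
    return HarmonizedSet.from_arrays(bx, bx_se, by, by_se)


def wls_oracle(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via the sqrt-weight QR route (lstsq).

    Independent of the normal-equations path used by the package.
    Returns (coefficients, unscaled SEs, weighted RSS).
    """
    sw = np.sqrt(w)
    Xs = X * sw[:, None]
    ys = y * sw
    coef, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ coef
    rss = float(resid @ resid)
    cov = np.linalg.pinv(Xs.T @ Xs)
    return coef, np.sqrt(np.diag(cov)), rss


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def proportional_set() -> HarmonizedSet:
    """Zero-noise fixture: by = 0.5 * bx exactly."""
    bx = np.array([0.2, 0.3, 0.5, -0.4])
    return HarmonizedSet.from_arrays(
        bx, np.full(4, 0.01), 0.5 * bx, np.array([0.05, 0.04, 0.06, 0.05])
    )
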