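"""Instrument selection: significance and MAF filters, LD clumping, F-statistics.

Instruments for two-sample MR are variants robustly associated with the
exposure (p < 5e-8 genome-wide), common enough to be well measured
(MAF > 0.01), approximately independent of each other (greedy clumping
within 10,000 kb windows at r^2 <= 0.001), and individually strong
(per-variant F = (beta/se)^2 > 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ConfigurationError
from .sumstats import SumStatsTable, _norm_chrom


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection.

    pval_threshold : genome-wide significance cut-off (strict ``<``).
    maf_min        : minimum minor-allele frequency (strict ``>``).
    clump_window_kb: clumping window, centre-to-centre, inclusive.
    clump_r2       : maximum tolerated LD r^2 between retained variants.
    f_min          : minimum per-variant F statistic (strict ``>``).
    keep_missing_eaf : retain variants whose EAF is unreported.
    """

    pval_threshold: float = 5e-8
    maf_min: float = 0.01
    clump_window_kb: int = 10_000
    clump_r2: float = 0.001
    f_min: float = 10.0
    keep_missing_eaf: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.pval_threshold < 1:
            raise ConfigurationError("pval_threshold must be in (0, 1)")
        if not 0 <= self.maf_min < 0.5:
            raise ConfigurationError("maf_min must be in [0, 0.5)")
        if not 0 <= self.clump_r2 <= 1:
            raise ConfigurationError("clump_r2 must be in [0, 1]")
        if self.f_min < 0:
            raise ConfigurationError("f_min must be non-negative")
        if self.clump_window_kb < 0:
            raise ConfigurationError("clump_window_kb must be non-negative")


@dataclass
class LDMatrix:
    """Square symmetric r^2 matrix over an ordered list of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ConfigurationError(
                f"LD matrix shape {self.r2.shape} does not match {n} variant ids"
            )
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ConfigurationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ConfigurationError("LD matrix diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ConfigurationError("LD r^2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(float))

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


def f_statistic(beta: float, se: float) -> float:
    """Per-variant instrument-strength statistic F = (beta / se)^2."""
    if se <= 0:
        raise ConfigurationError("standard error must be positive")
    return (beta / se) ** 2


def significance_filter(table: SumStatsTable, cfg: SelectionConfig) -> SumStatsTable:
    """Keep genome-wide-significant, common variants.

    Retains p < ``pval_threshold`` and min(EAF, 1-EAF) > ``maf_min``;
    variants with missing EAF are dropped unless ``cfg.keep_missing_eaf``.
    An empty result is legal.
    """
    df = table.df
    sig = df["pval"] < cfg.pval_threshold
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    common = maf > cfg.maf_min
    if cfg.keep_missing_eaf:
        common = common | df["eaf"].isna()
    else:
        common = common & df["eaf"].notna()
    out = df[sig & common].reset_index(drop=True)
    return SumStatsTable(table.trait_label, out, table.unit_note)


def _clump_order(df: pd.DataFrame) -> pd.DataFrame:
    # deterministic, order-independent priority: p, then (chrom, pos), then id
    return df.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)


def clump(
    table: SumStatsTable,
    ld: LDMatrix | None,
    cfg: SelectionConfig,
) -> SumStatsTable:
    """Greedy LD clumping.

    Repeatedly takes the remaining variant with the smallest p-value as an
    index variant and removes every remaining same-chromosome variant
    within ``clump_window_kb`` of it — additionally requiring r^2 >
    ``clump_r2`` against the index when an LD matrix is supplied
    (distance-only pruning otherwise).  Ties on p are broken by (chrom,
    pos) then variant id, making the result independent of input order.
    """
    df = _clump_order(table.df)
    if ld is not None:
        missing = [v for v in df["variant_id"] if v not in ld._index]
        if missing:
            raise ConfigurationError(
                f"LD matrix is missing table variants: {missing[:5]}"
            )
    window_bp = cfg.clump_window_kb * 1000
    chrom = df["chrom"].map(_norm_chrom).to_numpy()
    pos = df["pos"].to_numpy(np.int64)
    ids = df["variant_id"].to_numpy()

    alive = np.ones(len(df), bool)
    keep: list[int] = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        keep.append(i)
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        near[i] = False
        if ld is not None and near.any():
            idx_i = ld._index[ids[i]]
            r2_row = ld.r2[idx_i]
            cols = np.array([ld._index[v] for v in ids[near]])
            near_idx = np.flatnonzero(near)
            near[near_idx] = r2_row[cols] > cfg.clump_r2
        alive[near] = False
    out = df.iloc[keep].reset_index(drop=True)
    return SumStatsTable(table.trait_label, out, table.unit_note)


@dataclass
class SelectionReport:
    """Per-stage attrition counts from :func:`select_instruments`."""

    input: int = 0
    after_exclusion: int = 0
    after_significance: int = 0
    after_clump: int = 0
    after_f_filter: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "after_exclusion": self.after_exclusion,
            "after_significance": self.after_significance,
            "after_clump": self.after_clump,
            "after_f_filter": self.after_f_filter,
        }


@dataclass
class InstrumentSet:
    """Selected instruments (summary-stats rows plus an ``f_stat`` column)."""

    table: SumStatsTable
    attrition: SelectionReport = field(default_factory=SelectionReport)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table.variant_ids


def select_instruments(
    table: SumStatsTable,
    ld: LDMatrix | None = None,
    cfg: SelectionConfig | None = None,
    exclusion_list: Iterable[str] | None = None,
) -> InstrumentSet:
    """Full instrument-selection pipeline.

    Order: user exclusion list (e.g. variants tied to known confounders)
    -> significance + MAF filter -> LD clumping -> F-statistic annotation
    -> drop F <= ``f_min``.  Raises :class:`AnalysisError` with the
    per-stage attrition counts if nothing survives.
    """
    cfg = cfg or SelectionConfig()
    rep = SelectionReport(input=len(table))

    df = table.df
    if exclusion_list is not None:
        banned = set(exclusion_list)
        df = df[~df["variant_id"].isin(banned)].reset_index(drop=True)
    work = SumStatsTable(table.trait_label, df, table.unit_note)
    rep.after_exclusion = len(work)

    work = significance_filter(work, cfg)
    rep.after_significance = len(work)

    if len(work):
        work = clump(work, ld, cfg)
    rep.after_clump = len(work)

    out = work.df.copy()
    out["f_stat"] = (out["beta"] / out["se"]) ** 2
    out = out[out["f_stat"] > cfg.f_min].reset_index(drop=True)
    rep.after_f_filter = len(out)

    if len(out) == 0:
        raise AnalysisError(
            f"no instruments remain for {table.trait_label!r}; "
            f"attrition: {rep.as_dict()}"
        )
    return InstrumentSet(SumStatsTable(table.trait_label, out, table.unit_note), rep)
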