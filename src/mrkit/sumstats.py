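"""GWAS summary-statistic tables: reading, validation, writing, harmonization.

A summary-statistics table holds one row per variant with the marginal
association of that variant with a single trait in a single cohort:
effect/other allele, effect-allele frequency (EAF), effect size (log-odds
for binary traits, native units otherwise), its standard error, p-value
and sample size.

Before any two-sample MR step the per-variant effects of every trait must
be expressed for the same effect allele; :func:`harmonize` performs that
alignment, resolving palindromic (A/T, C/G) variants through allele-
frequency concordance and dropping the irresolvable ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ConfigurationError, InputError

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

MANDATORY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
]

_VALID_BASES = frozenset("ACGT")

#: complement map used only to recognise palindromic allele pairs
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

NOT_PALINDROMIC = "not_palindromic"
PALINDROMIC_INFERABLE = "palindromic_inferable"
PALINDROMIC_AMBIGUOUS = "palindromic_ambiguous"

DROP_ALLELE_MISMATCH = "allele_mismatch"
DROP_PALINDROMIC_AMBIGUOUS = "palindromic_ambiguous"
DROP_MISSING_IN_OUTCOME = "missing_in_outcome"
DROP_DUPLICATE = "duplicate"


@dataclass
class SumStatsTable:
    """Validated per-variant association records for one trait/cohort.

    Parameters
    ----------
    trait_label
        Human-readable trait name, used to label columns downstream.
    df
        DataFrame with the canonical columns (``variant_id``, ``chrom``,
        ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
        ``se``, ``pval``, ``n``).  ``eaf`` and ``n`` may be NaN.
    unit_note
        Free text describing the effect-size units (e.g. "log-odds",
        "mmHg", "1-SD").
    rejected
        Rows that failed validation during reading, with a ``reason``
        column; kept for reporting, never analysed.
    """

    trait_label: str
    df: pd.DataFrame
    unit_note: str = ""
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=CANONICAL_COLUMNS + ["reason"])
    )

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"table is missing canonical columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise InputError(f"duplicate variant_id within table: {sorted(set(dups))}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def restrict(self, variant_ids: Iterable[str]) -> "SumStatsTable":
        """Return a copy keeping only the given variants (original order)."""
        wanted = set(variant_ids)
        sub = self.df[self.df["variant_id"].isin(wanted)].reset_index(drop=True)
        return SumStatsTable(self.trait_label, sub, self.unit_note)


def _norm_chrom(chrom: object) -> str:
    s = str(chrom).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw frame into (valid, rejected-with-reason)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & (reasons == "")
        reasons[new] = reason

    allele_ok = df["effect_allele"].map(
        lambda a: isinstance(a, str) and len(a) >= 1 and set(a) <= _VALID_BASES
    ) & df["other_allele"].map(
        lambda a: isinstance(a, str) and len(a) >= 1 and set(a) <= _VALID_BASES
    )
    flag(~allele_ok, "invalid allele")
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    flag(~(df["se"] > 0), "nonpositive se")
    flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0, 1]")
    eaf_bad = df["eaf"].notna() & ~((df["eaf"] >= 0) & (df["eaf"] <= 1))
    flag(eaf_bad, "eaf outside [0, 1]")
    flag(~(df["pos"] > 0), "nonpositive position")
    n_bad = df["n"].notna() & ~(df["n"] > 0)
    flag(n_bad, "nonpositive n")
    flag(df["beta"].isna(), "missing beta")

    # within-table duplicates: keep the smallest p-value, reject the rest
    order = df.assign(_reason=reasons).sort_values(
        ["variant_id", "pval"], kind="mergesort"
    )
    dup = order.duplicated("variant_id", keep="first")
    dup_idx = order.index[dup & (order["_reason"] == "")]
    reasons[dup_idx] = "duplicate"

    bad = reasons != ""
    rejected = df[bad].copy()
    rejected["reason"] = reasons[bad]
    return df[~bad].reset_index(drop=True), rejected.reset_index(drop=True)


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
    unit_note: str = "",
) -> SumStatsTable:
    """Read a tab-separated summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's column names (for
    files using a different dialect).  Missing optional columns (``eaf``,
    ``n``) are filled with NaN; missing mandatory columns raise
    :class:`ConfigurationError`.  Rows violating the record invariants
    (nonpositive SE, p-value outside (0, 1], malformed alleles, duplicate
    variant ids, ...) are moved to ``table.rejected`` with a reason.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ConfigurationError(
                f"mandatory column {col!r} not found in {path} "
                f"(available: {list(raw.columns)})"
            )
    for col in ("eaf", "n"):
        if col not in raw.columns:
            raw[col] = np.nan
    raw = raw[CANONICAL_COLUMNS].copy()
    if len(raw) == 0:
        raise InputError(f"empty summary-statistics table: {path}")
    for col in ("effect_allele", "other_allele"):
        raw[col] = raw[col].astype(str).str.upper()
    raw["chrom"] = raw["chrom"].map(_norm_chrom)
    raw["pos"] = pd.to_numeric(raw["pos"], errors="coerce")
    for col in ("eaf", "beta", "se", "pval", "n"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")

    valid, rejected = _validate_rows(raw)
    valid["pos"] = valid["pos"].astype(np.int64)
    return SumStatsTable(
        trait_label or str(path), valid, unit_note=unit_note, rejected=rejected
    )


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write a table in the canonical tab-separated dialect ("NA" for missing)."""
    out = table.df[CANONICAL_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def flag_palindromic(
    effect_allele: str,
    other_allele: str,
    eaf: float | None,
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> str:
    """Classify a variant's strand resolvability.

    A/T and C/G allele pairs read identically on both strands, so the
    effect allele cannot be matched across datasets by label alone.  If
    the effect-allele frequency is clearly away from 0.5 (outside
    ``ambiguity_band``) the minor allele identifies the orientation;
    otherwise the variant is ambiguous.  Missing EAF means ambiguous.
    """
    ea, oa = effect_allele.upper(), other_allele.upper()
    if len(ea) != 1 or len(oa) != 1 or _COMPLEMENT.get(ea) != oa:
        return NOT_PALINDROMIC
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        return PALINDROMIC_AMBIGUOUS
    low, high = ambiguity_band
    if low <= eaf <= high:
        return PALINDROMIC_AMBIGUOUS
    return PALINDROMIC_INFERABLE


@dataclass
class HarmonizedSet:
    """Exposure(s) and outcome effects aligned to a common effect allele.

    ``df`` has one row per retained variant with columns ``variant_id``,
    ``chrom``, ``pos``, ``aligned_allele``, then ``beta_<label>`` /
    ``se_<label>`` per exposure and ``outcome_beta`` / ``outcome_se``.
    ``dropped`` records every excluded variant with its ``drop_reason``.
    """

    df: pd.DataFrame
    exposure_labels: list[str]
    outcome_label: str
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "drop_reason"])
    )

    @property
    def n_snp(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def _single_label(self) -> str:
        if len(self.exposure_labels) != 1:
            raise AnalysisError(
                "operation requires a single-exposure harmonized set; "
                f"got exposures {self.exposure_labels}"
            )
        return self.exposure_labels[0]

    @property
    def bx(self) -> np.ndarray:
        return self.df[f"beta_{self._single_label()}"].to_numpy(float)

    @property
    def bx_se(self) -> np.ndarray:
        return self.df[f"se_{self._single_label()}"].to_numpy(float)

    @property
    def by(self) -> np.ndarray:
        return self.df["outcome_beta"].to_numpy(float)

    @property
    def by_se(self) -> np.ndarray:
        return self.df["outcome_se"].to_numpy(float)

    def exposure_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (betas, ses) as n_snp x n_exposures arrays."""
        bx = np.column_stack(
            [self.df[f"beta_{lab}"].to_numpy(float) for lab in self.exposure_labels]
        )
        sx = np.column_stack(
            [self.df[f"se_{lab}"].to_numpy(float) for lab in self.exposure_labels]
        )
        return bx, sx

    def subset(self, keep_ids: Iterable[str]) -> "HarmonizedSet":
        wanted = set(keep_ids)
        sub = self.df[self.df["variant_id"].isin(wanted)].reset_index(drop=True)
        return HarmonizedSet(sub, list(self.exposure_labels), self.outcome_label)

    def drop_variants(self, drop_ids: Iterable[str]) -> "HarmonizedSet":
        banned = set(drop_ids)
        return self.subset([v for v in self.variant_ids if v not in banned])

    @classmethod
    def from_arrays(
        cls,
        bx: np.ndarray,
        bx_se: np.ndarray,
        by: np.ndarray,
        by_se: np.ndarray,
        variant_ids: Sequence[str] | None = None,
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
    ) -> "HarmonizedSet":
        """Build a single-exposure set directly from effect arrays.

        Convenience constructor for simulation studies and tests where
        the allele bookkeeping has already been done.
        """
        bx = np.asarray(bx, float)
        n = len(bx)
        ids = list(variant_ids) if variant_ids is not None else [f"v{i}" for i in range(n)]
        df = pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": "1",
                "pos": np.arange(1, n + 1),
                "aligned_allele": "A",
                f"beta_{exposure_label}": bx,
                f"se_{exposure_label}": np.asarray(bx_se, float),
                "outcome_beta": np.asarray(by, float),
                "outcome_se": np.asarray(by_se, float),
            }
        )
        return cls(df, [exposure_label], outcome_label)


def _align_row(
    ref: pd.Series,
    other: pd.Series,
    ambiguity_band: tuple[float, float],
) -> tuple[float, float] | str:
    """Align one table's record to the reference alleles.

    Returns ``(signed_beta, aligned_eaf)`` on success or a drop reason.
    Palindromic pairs are aligned by allele-frequency concordance: after
    label alignment, if the reference and other EAFs sit on opposite
    sides of 0.5 the strands disagree and the effect is flipped.
    """
    ea, oa = ref["effect_allele"], ref["other_allele"]
    beta, eaf = other["beta"], other["eaf"]
    if (other["effect_allele"], other["other_allele"]) == (ea, oa):
        pass
    elif (other["effect_allele"], other["other_allele"]) == (oa, ea):
        beta = -beta
        eaf = 1.0 - eaf if pd.notna(eaf) else np.nan
    else:
        return DROP_ALLELE_MISMATCH

    if flag_palindromic(ea, oa, None) == PALINDROMIC_AMBIGUOUS:
        # palindromic pair: label alignment is not trustworthy, check EAF
        ref_flag = flag_palindromic(ea, oa, ref["eaf"], ambiguity_band)
        oth_flag = flag_palindromic(ea, oa, eaf, ambiguity_band)
        if PALINDROMIC_AMBIGUOUS in (ref_flag, oth_flag):
            return DROP_PALINDROMIC_AMBIGUOUS
        if (ref["eaf"] - 0.5) * (eaf - 0.5) < 0:
            beta = -beta
            eaf = 1.0 - eaf
    return beta, eaf


def harmonize(
    exposures: SumStatsTable | Sequence[SumStatsTable],
    outcome: SumStatsTable,
    drop_ambiguous_palindromes: bool = True,
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align one or more exposure tables and an outcome table allele-wise.

    The first exposure table defines the reference effect allele per
    variant.  For every variant present in all tables: a label swap in
    another table negates its beta (and reflects its EAF); palindromic
    variants are oriented by EAF concordance when both frequencies are
    outside the ambiguity band, otherwise dropped (when
    ``drop_ambiguous_palindromes``, the default) or kept as labelled.
    Variants missing from any table, with irreconcilable alleles, or
    ambiguous are recorded in ``dropped`` with a reason.
    """
    if isinstance(exposures, SumStatsTable):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise ConfigurationError("at least one exposure table is required")
    tables = exposures + [outcome]
    labels = [t.trait_label or f"exposure{i}" for i, t in enumerate(exposures)]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}_{i}" for i, lab in enumerate(labels)]

    indexed = [t.df.set_index("variant_id") for t in tables]
    shared = set(indexed[0].index)
    for idx in indexed[1:]:
        shared &= set(idx.index)
    all_ids = set().union(*(set(i.index) for i in indexed))
    dropped_rows = [
        {"variant_id": v, "drop_reason": DROP_MISSING_IN_OUTCOME}
        for v in sorted(all_ids - shared)
    ]
    if not shared:
        raise AnalysisError("no overlapping instruments between exposure and outcome")

    ref_df = indexed[0]
    # preserve the exposure table's row order
    ordered = [v for v in exposures[0].variant_ids if v in shared]
    rows = []
    for vid in ordered:
        ref = ref_df.loc[vid]
        rec: dict[str, object] = {
            "variant_id": vid,
            "chrom": ref["chrom"],
            "pos": ref["pos"],
            "aligned_allele": ref["effect_allele"],
            f"beta_{labels[0]}": ref["beta"],
            f"se_{labels[0]}": ref["se"],
        }
        reason = None
        ref_is_palindromic = (
            flag_palindromic(ref["effect_allele"], ref["other_allele"], None)
            == PALINDROMIC_AMBIGUOUS
        )
        if ref_is_palindromic:
            ref_flag = flag_palindromic(
                ref["effect_allele"], ref["other_allele"], ref["eaf"], ambiguity_band
            )
            if ref_flag == PALINDROMIC_AMBIGUOUS and drop_ambiguous_palindromes:
                reason = DROP_PALINDROMIC_AMBIGUOUS
        if reason is None:
            for tbl_idx, (idx, tbl) in enumerate(zip(indexed[1:], tables[1:]), start=1):
                res = _align_row(ref, idx.loc[vid], ambiguity_band)
                if isinstance(res, str):
                    if res == DROP_PALINDROMIC_AMBIGUOUS and not drop_ambiguous_palindromes:
                        res = (idx.loc[vid]["beta"], idx.loc[vid]["eaf"])
                    else:
                        reason = res
                        break
                beta, _ = res
                if tbl_idx < len(exposures):
                    rec[f"beta_{labels[tbl_idx]}"] = beta
                    rec[f"se_{labels[tbl_idx]}"] = idx.loc[vid]["se"]
                else:
                    rec["outcome_beta"] = beta
                    rec["outcome_se"] = idx.loc[vid]["se"]
        if reason is None:
            rows.append(rec)
        else:
            dropped_rows.append({"variant_id": vid, "drop_reason": reason})

    cols = ["variant_id", "chrom", "pos", "aligned_allele"]
    for lab in labels:
        cols += [f"beta_{lab}", f"se_{lab}"]
    cols += ["outcome_beta", "outcome_se"]
    df = pd.DataFrame(rows, columns=cols)
    dropped = pd.DataFrame(dropped_rows, columns=["variant_id", "drop_reason"])
    return HarmonizedSet(df, labels, outcome.trait_label, dropped)
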