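"""I/O, validation and allele harmonization of summary-statistics tables."""

from __future__ import annotations


import numpy as np
import pandas as pd
import pytest

import mrkit as mk
from mrkit.sumstats import (
    DROP_ALLELE_MISMATCH,
    DROP_MISSING_IN_OUTCOME,
    DROP_PALINDROMIC_AMBIGUOUS,
    NOT_PALINDROMIC,
    PALINDROMIC_AMBIGUOUS,
    PALINDROMIC_INFERABLE,
)

from conftest import make_table


class TestReadWrite:
    def test_round_trip_preserves_table(self, tmp_path):
        table = make_table(
            [
                {"variant_id": "rs1", "beta": 0.123456789012345, "eaf": 0.21},
                {"variant_id": "rs2", "beta": -0.2, "eaf": np.nan, "n": np.nan},
                {"variant_id": "rs3", "chrom": "12", "pos": 99},
            ]
        )
        path = tmp_path / "t.tsv"
        mk.write_sumstats(table, path)
        back = mk.read_sumstats(path, trait_label=table.trait_label)
        pd.testing.assert_frame_equal(back.df, table.df)
        # missing fields are serialized as NA
        assert "NA" in path.read_text()

    def test_alleles_uppercased_and_rows_validated(self, tmp_path):
        df = make_table(
            [
                {"variant_id": "rs1"},
                {"variant_id": "rs2", "se": 0.0},
                {"variant_id": "rs3", "pval": 0.0},
                {"variant_id": "rs4", "effect_allele": "A", "other_allele": "A"},
            ]
        ).df.copy()
        df.loc[0, "effect_allele"] = "a"
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = mk.read_sumstats(path)
        assert table.df["effect_allele"].tolist() == ["A"]
        reasons = set(table.rejected["reason"])
        assert reasons == {"nonpositive se", "pval outside (0, 1]", "identical alleles"}

    def test_duplicate_keeps_smallest_pval(self, tmp_path):
        df = make_table(
            [
                {"variant_id": "rs1", "pval": 1e-9, "beta": 0.2},
                {"variant_id": "dup", "pval": 1e-12, "beta": 0.3},
            ]
        ).df.assign(variant_id="rs1")
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = mk.read_sumstats(path)
        assert len(table) == 1
        assert table.df.loc[0, "beta"] == 0.3
        assert table.rejected["reason"].tolist() == ["duplicate"]

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        make_table([{}]).df.drop(columns=["se"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(mk.ConfigurationError, match="se"):
            mk.read_sumstats(path)

    def test_column_map_resolves_foreign_dialect(self, tmp_path):
        df = make_table([{}]).df.rename(columns={"variant_id": "SNP", "pval": "P"})
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = mk.read_sumstats(path, column_map={"variant_id": "SNP", "pval": "P"})
        assert table.df.loc[0, "variant_id"] == "rs0"

    def test_empty_table_is_input_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        make_table([{}]).df.iloc[:0].to_csv(path, sep="\t", index=False)
        with pytest.raises(mk.InputError):
            mk.read_sumstats(path)


class TestFlagPalindromic:
    @pytest.mark.parametrize(
        "ea,oa,eaf,expected",
        [
            ("A", "G", 0.5, NOT_PALINDROMIC),
            ("C", "T", 0.10, NOT_PALINDROMIC),
            ("A", "T", 0.50, PALINDROMIC_AMBIGUOUS),
            ("A", "T", 0.42, PALINDROMIC_AMBIGUOUS),
            ("T", "A", 0.30, PALINDROMIC_INFERABLE),
            ("C", "G", 0.10, PALINDROMIC_INFERABLE),
            ("G", "C", np.nan, PALINDROMIC_AMBIGUOUS),
        ],
    )
    def test_classification(self, ea, oa, eaf, expected):
        assert mk.flag_palindromic(ea, oa, eaf) == expected

    def test_custom_band(self):
        assert (
            mk.flag_palindromic("A", "T", 0.45, ambiguity_band=(0.48, 0.52))
            == PALINDROMIC_INFERABLE
        )


def _brute_force_palindrome_alignment(eaf_exp, beta_out, eaf_out):
    """Enumerate the four allele/strand alignments of a palindromic pair
    and return the outcome beta under the unique EAF-concordant one."""
    candidates = []
    for swap in (False, True):
        b = -beta_out if swap else beta_out
        f = 1 - eaf_out if swap else eaf_out
        if (eaf_exp - 0.5) * (f - 0.5) > 0:
            candidates.append(b)
    assert len(set(candidates)) == 1
    return candidates[0]


class TestHarmonize:
    def test_swapped_alleles_negate_outcome_beta(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.10}], "x")
        out = make_table(
            [{"effect_allele": "G", "other_allele": "A", "beta": -0.20, "eaf": 0.7}], "y"
        )
        h = mk.harmonize(exp, out)
        assert h.n_snp == 1
        assert h.by[0] == pytest.approx(0.20)

    def test_palindrome_aligned_by_frequency_concordance(self):
        exp = make_table(
            [{"effect_allele": "A", "other_allele": "T", "beta": 0.10, "eaf": 0.10}], "x"
        )
        out = make_table(
            [{"effect_allele": "A", "other_allele": "T", "beta": 0.30, "eaf": 0.88}], "y"
        )
        h = mk.harmonize(exp, out)
        expected = _brute_force_palindrome_alignment(0.10, 0.30, 0.88)
        assert h.by[0] == pytest.approx(expected)
        assert expected == -0.30

    def test_ambiguous_palindrome_dropped_with_reason(self):
        exp = make_table(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}], "x"
        )
        out = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}], "y")
        h = mk.harmonize(exp, out)
        assert h.n_snp == 0
        assert h.dropped["drop_reason"].tolist() == [DROP_PALINDROMIC_AMBIGUOUS]

    def test_irreconcilable_alleles_dropped(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G"}], "x")
        out = make_table([{"effect_allele": "A", "other_allele": "C"}], "y")
        h = mk.harmonize(exp, out)
        assert h.n_snp == 0
        assert h.dropped["drop_reason"].tolist() == [DROP_ALLELE_MISMATCH]

    def test_variant_missing_from_outcome_recorded(self):
        exp = make_table([{"variant_id": "rs0"}, {"variant_id": "rs9"}], "x")
        out = make_table([{"variant_id": "rs0", "beta": 0.05}], "y")
        h = mk.harmonize(exp, out)
        assert h.variant_ids == ["rs0"]
        assert (
            h.dropped.set_index("variant_id").loc["rs9", "drop_reason"]
            == DROP_MISSING_IN_OUTCOME
        )

    def test_empty_intersection_raises(self):
        exp = make_table([{"variant_id": "rsA"}], "x")
        out = make_table([{"variant_id": "rsB"}], "y")
        with pytest.raises(mk.AnalysisError, match="overlap"):
            mk.harmonize(exp, out)

    def test_idempotent_on_aligned_pair(self):
        exp = make_table(
            [{"variant_id": f"rs{i}", "beta": 0.1 * (i + 1), "eaf": 0.2} for i in range(4)],
            "x",
        )
        out = make_table(
            [{"variant_id": f"rs{i}", "beta": 0.05 * (i + 1), "eaf": 0.2} for i in range(4)],
            "y",
        )
        h1 = mk.harmonize(exp, out)
        # feed the already-aligned outcome back through
        out2 = out.restrict(h1.variant_ids)
        out2.df["beta"] = h1.df["outcome_beta"].to_numpy()
        h2 = mk.harmonize(exp, out2)
        pd.testing.assert_frame_equal(h1.df, h2.df)

    def test_sign_consistency_under_allele_swap(self):
        """Swapping both outcome alleles and negating beta is a no-op."""
        exp = make_table(
            [
                {"variant_id": "rs0", "effect_allele": "A", "other_allele": "G"},
                {"variant_id": "rs1", "effect_allele": "C", "other_allele": "G",
                 "eaf": 0.15},
            ],
            "x",
        )
        out = make_table(
            [
                {"variant_id": "rs0", "effect_allele": "A", "other_allele": "G",
                 "beta": 0.2, "eaf": 0.4},
                {"variant_id": "rs1", "effect_allele": "C", "other_allele": "G",
                 "beta": -0.1, "eaf": 0.2},
            ],
            "y",
        )
        swapped = out.df.copy()
        swapped["effect_allele"], swapped["other_allele"] = (
            out.df["other_allele"],
            out.df["effect_allele"],
        )
        swapped["beta"] = -out.df["beta"]
        swapped["eaf"] = 1 - out.df["eaf"]
        out_swapped = mk.SumStatsTable("y", swapped)
        h1 = mk.harmonize(exp, out)
        h2 = mk.harmonize(exp, out_swapped)
        pd.testing.assert_frame_equal(h1.df, h2.df)

    @pytest.mark.parametrize("drop_flag", [True, False])
    def test_count_conservation(self, rng, drop_flag):
        """retained + dropped = size of the variant intersection (plus
        non-shared variants recorded as missing)."""
        alleles = [("A", "G"), ("A", "T"), ("C", "G"), ("T", "C")]
        rows_x, rows_y = [], []
        for i in range(20):
            ea, oa = alleles[i % 4]
            rows_x.append(
                {"variant_id": f"rs{i}", "effect_allele": ea, "other_allele": oa,
                 "eaf": float(rng.uniform(0.01, 0.99))}
            )
            if i % 5 != 0:  # some variants missing from the outcome
                swap = bool(rng.integers(2))
                rows_y.append(
                    {"variant_id": f"rs{i}",
                     "effect_allele": oa if swap else ea,
                     "other_allele": ea if swap else oa,
                     "eaf": float(rng.uniform(0.01, 0.99))}
                )
        exp = make_table(rows_x, "x")
        out = make_table(rows_y, "y")
        h = mk.harmonize(exp, out, drop_ambiguous_palindromes=drop_flag)
        shared = set(exp.variant_ids) & set(out.variant_ids)
        union = set(exp.variant_ids) | set(out.variant_ids)
        dropped_shared = h.dropped[
            h.dropped["drop_reason"] != DROP_MISSING_IN_OUTCOME
        ]
        assert h.n_snp + len(dropped_shared) == len(shared)
        assert h.n_snp + len(h.dropped) == len(union)
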