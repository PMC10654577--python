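import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import lev_recursive
from spatialtcr.model import Clone, SpotTable
from spatialtcr.repertoire import (
    JoinError,
    cluster_cdr3,
    clones_to_frame,
    levenshtein,
    normalize_tcr,
    preprocess_tcr,
)

peptides = st.text(alphabet="ACDF", min_size=0, max_size=8)


class TestLevenshtein:
    def test_empty_against_word(self):
        assert levenshtein("", "CASS") == 4
        assert levenshtein("CASS", "") == 4

    def test_identity(self):
        assert levenshtein("CASSLG", "CASSLG") == 0

    def test_classic_example(self):
        assert levenshtein("KITTEN", "SITTING") == 3

    @given(peptides, peptides)
    @settings(max_examples=200, deadline=None)
    def test_matches_recursive_oracle(self, a, b):
        assert levenshtein(a, b) == lev_recursive(a, b)

    @given(peptides, peptides, peptides)
    @settings(max_examples=150, deadline=None)
    def test_metric_axioms(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


def rec_row(cdr3_aa, barcode="A" * 16, locus="TRB", v="V1", j="J1", umi=1):
    return {
        "barcode": barcode,
        "locus": locus,
        "v_call": v,
        "j_call": j,
        "c_call": "C1",
        "cdr3_nt": "",
        "cdr3_aa": cdr3_aa,
        "v_identity": 0.9,
        "j_identity": 0.8,
        "umi_count": umi,
    }


class TestPreprocess:
    def test_short_cdr3_dropped(self):
        df = pd.DataFrame([rec_row("CASF")])
        assert preprocess_tcr(df, min_len=5).empty

    def test_missing_j_dropped_when_vj_required(self):
        df = pd.DataFrame([rec_row("CASSLGF", j="")])
        assert preprocess_tcr(df, require_vj=True).empty
        assert len(preprocess_tcr(df, require_vj=False)) == 1

    def test_in_range_record_kept_unchanged(self):
        df = pd.DataFrame([rec_row("CASSLGF", umi=2)])
        out = preprocess_tcr(df, min_umi=2)
        pd.testing.assert_frame_equal(out, df)

    def test_stop_and_x_dropped(self):
        df = pd.DataFrame([rec_row("CAS*LGF"), rec_row("CASXLGF")])
        assert preprocess_tcr(df).empty


class TestClusterCdr3:
    def test_single_edit_merges_with_lexicographic_representative(self):
        df = pd.DataFrame([rec_row("CASSLF"), rec_row("CASSLY", barcode="C" * 16)])
        (clone,) = cluster_cdr3(df, min_dist=2)
        assert clone.members == {"CASSLF", "CASSLY"}
        assert clone.representative_cdr3_aa == "CASSLF"  # tie -> lexicographic

    def test_distance_two_stays_separate(self):
        df = pd.DataFrame([rec_row("CASSLF"), rec_row("CATTRG")])
        assert len(cluster_cdr3(df, min_dist=2)) == 2

    def test_longest_member_is_representative(self):
        df = pd.DataFrame([rec_row("CASSF"), rec_row("CASSFF")])
        (clone,) = cluster_cdr3(df, min_dist=2)
        assert clone.representative_cdr3_aa == "CASSFF"

    def test_spots_accumulate(self):
        rows = [rec_row("CASSLGF", barcode=b * 16) for b in "ACG"]
        (clone,) = cluster_cdr3(pd.DataFrame(rows))
        assert clone.n_spots == 3 and clone.total_umis == 3

    def test_min_dist_one_is_distinct_partition(self):
        rng = np.random.default_rng(2)
        seqs = {"".join(rng.choice(list("ACDEF"), size=7)) for _ in range(15)}
        df = pd.DataFrame([rec_row(s) for s in seqs])
        clones = cluster_cdr3(df, min_dist=1)
        assert {c.representative_cdr3_aa for c in clones} == seqs
        assert all(len(c.members) == 1 for c in clones)

    def test_loci_never_merge(self):
        df = pd.DataFrame(
            [rec_row("CASSLGF", locus="TRA"), rec_row("CASSLGF", locus="TRB")]
        )
        clones = cluster_cdr3(df)
        assert {c.locus for c in clones} == {"TRA", "TRB"}

    def test_umi_totals_conserved(self):
        rng = np.random.default_rng(8)
        rows = [
            rec_row(
                "".join(rng.choice(list("ACDEFGH"), size=rng.integers(5, 9))),
                barcode="".join(rng.choice(list("ACGT"), size=16)),
                umi=int(rng.integers(1, 6)),
            )
            for _ in range(40)
        ]
        df = pd.DataFrame(rows)
        clones = cluster_cdr3(df)
        assert sum(c.total_umis for c in clones) == df["umi_count"].sum()

    def test_identities_averaged_and_frame_export(self):
        df = pd.DataFrame([rec_row("CASSLF"), rec_row("CASSLY")])
        df.loc[1, "v_identity"] = 0.7
        (clone,) = cluster_cdr3(df)
        assert clone.mean_v_identity == pytest.approx(0.8)
        frame = clones_to_frame([clone])
        assert frame.loc[0, "members"] == "CASSLF;CASSLY"

    def test_planted_variants_merge_and_distinct_stay(self):
        base = "CASSLGELFF"
        variant = "CASSLGELFY"  # 1 substitution
        far = "CARRQQPKHF"  # >= 2 edits from base
        assert levenshtein(base, far) >= 2
        df = pd.DataFrame([rec_row(base), rec_row(variant), rec_row(far)])
        clones = cluster_cdr3(df)
        members = sorted(tuple(sorted(c.members)) for c in clones)
        assert members == sorted([(base, variant), (far,)])


class TestNormalize:
    def _spots(self):
        return SpotTable(
            pd.DataFrame(
                {
                    "barcode": ["A" * 16, "C" * 16],
                    "x": [0.0, 1.0],
                    "y": [0.0, 0.0],
                    "in_tissue": True,
                    "n_cells": [10, 0],
                    "total_umis": [2000, 500],
                }
            )
        )

    def _clone(self, spot_umis):
        return Clone("TRB-0000", "TRB", "CASSLGF", {"CASSLGF"}, 1.0, 1.0, spot_umis)

    def test_umis_per_cell_normalization(self):
        out, _ = normalize_tcr([self._clone({"A" * 16: 4})], self._spots())
        assert out.iloc[0]["normalized"] == pytest.approx(4 / 200.0)

    def test_zero_cell_spot_excluded_and_tallied(self):
        out, tally = normalize_tcr([self._clone({"C" * 16: 3})], self._spots())
        assert out.empty and tally["zero_cell_spots"] == 1

    def test_below_min_expr_excluded(self):
        out, tally = normalize_tcr(
            [self._clone({"A" * 16: 1})], self._spots(), min_expr=2
        )
        assert out.empty and tally["below_min_expr"] == 1

    def test_unknown_barcode_is_join_error(self):
        with pytest.raises(JoinError, match="GGGG"):
            normalize_tcr([self._clone({"G" * 16: 1})], self._spots())
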