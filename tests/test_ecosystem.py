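import math

import numpy as np
import pandas as pd
import pytest

from spatialtcr.ecosystem import (
    CLONAL_MARKERS,
    EXHAUSTION_MARKERS,
    ConfigError,
    ProfileError,
    clone_state_matrix,
    composite_tcell_score,
    create_cell_graph,
    enhance_celltype_expression,
    rank_rl,
    rl_kld,
)
from spatialtcr.model import Clone
from spatialtcr.spatial import GeometryError, delaunay_graph


def cells_frame(coords, feature="T"):
    return pd.DataFrame(
        {
            "barcode": [f"c{i:02d}" for i in range(len(coords))],
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "feature": feature,
        }
    )


class TestCellGraph:
    def test_three_cells_three_edges(self):
        g = create_cell_graph(cells_frame([(0, 0), (1, 0), (0, 1)]))
        assert g.n_edges == 3
        assert g.edges == {("c00", "c01"), ("c00", "c02"), ("c01", "c02")}

    def test_feature_filter_too_few_cells(self):
        df = cells_frame([(0, 0), (1, 0), (0, 1), (1, 1)])
        df.loc[2:, "feature"] = "B"
        with pytest.raises(GeometryError):
            create_cell_graph(df, features=["B"])

    def test_grid_matches_spot_level_graph(self):
        from spatialtcr.model import SpotTable

        coords = [(i, j) for i in range(4) for j in range(4)]
        cells = cells_frame(coords)
        spot_table = SpotTable(
            pd.DataFrame(
                {"barcode": cells["barcode"], "x": cells["x"], "y": cells["y"]}
            )
        )
        assert create_cell_graph(cells).edges == delaunay_graph(spot_table).edges


class TestEnhancement:
    def test_neutral_spec_is_exact_identity(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(
            rng.random((5, 4)) * 10,
            index=[f"G{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(4)],
        )
        spec = {"G0": -1.0, "G2": -1.0}  # e = 0
        x = pd.Series(0.0, index=M.columns)  # f' = 1
        out = enhance_celltype_expression(M, spec, x)
        pd.testing.assert_frame_equal(out, M)

    def test_hand_computed_single_cell(self):
        M = pd.DataFrame([[2.0]], index=["G"], columns=["S"])
        out = enhance_celltype_expression(
            M, {"G": -0.5}, pd.Series({"S": 0.0})
        )  # e = 0.5: step1 -> 3.0, step2 neutral
        assert out.loc["G", "S"] == pytest.approx(3.0)

    def test_negative_entry_absolute_value_rule(self):
        M = pd.DataFrame([[-1.0]], index=["G"], columns=["S"])
        out = enhance_celltype_expression(M, {"G": 0.0}, pd.Series({"S": 0.0}))
        assert out.loc["G", "S"] == 0.0  # -1 + |-1|*1 = 0

    def test_monotone_in_enhancer_factor(self):
        rng = np.random.default_rng(1)
        M = pd.DataFrame(
            rng.random((3, 5)),
            index=["A", "B", "C"],
            columns=[f"S{i}" for i in range(5)],
        )
        x = pd.Series(rng.random(5), index=M.columns)
        low = enhance_celltype_expression(M, {"A": 0.2}, x)
        high = enhance_celltype_expression(M, {"A": 0.8}, x)
        assert (high.loc["A"] >= low.loc["A"]).all()

    def test_multi_mode_averages_exponentials(self):
        M = pd.DataFrame([[1.0, 1.0]], index=["G"], columns=["S0", "S1"])
        scores = pd.DataFrame(
            [[0.0, 1.0], [0.0, 3.0]], index=["ctA", "ctB"], columns=["S0", "S1"]
        )
        out = enhance_celltype_expression(M, {}, scores, mode="multi")
        f = (math.exp(1.0) + math.exp(3.0)) / 2
        assert out.loc["G", "S1"] == pytest.approx(1.0 * f)  # e_bar = 0

    def test_missing_gene_listed_in_error(self):
        M = pd.DataFrame([[1.0]], index=["G"], columns=["S"])
        with pytest.raises(ConfigError, match="MISSING"):
            enhance_celltype_expression(M, {"MISSING": 1.0}, pd.Series({"S": 0.0}))


def make_clone(cid, spot_umis):
    return Clone(cid, "TRB", "CASSLGF", {"CASSLGF"}, 1.0, 1.0, spot_umis)


class TestCloneStateMatrix:
    STATES = pd.DataFrame(
        [[0.2, 0.3, 0.0], [0.1, 0.4, 0.0]],
        index=["cytotoxic", "exhausted"],
        columns=["B1", "B2", "B3"],
    )

    def test_single_spot_clone_copies_scores(self):
        out = clone_state_matrix(self.STATES, [make_clone("c1", {"B2": 1})])
        assert out["c1"].tolist() == [0.3, 0.4]

    def test_multi_spot_clone_sums(self):
        out = clone_state_matrix(self.STATES, [make_clone("c1", {"B1": 1, "B2": 2})])
        assert out.loc["cytotoxic", "c1"] == pytest.approx(0.5)

    def test_zero_score_support_gives_zero_column(self):
        out = clone_state_matrix(self.STATES, [make_clone("c1", {"B3": 1})])
        assert (out["c1"] == 0).all()

    def test_total_mass_conserved(self):
        clones = [
            make_clone("c1", {"B1": 1, "B3": 1}),
            make_clone("c2", {"B2": 1}),
        ]
        out = clone_state_matrix(self.STATES, clones)
        expected = sum(
            float(self.STATES[list(c.spot_umis)].sum().sum()) for c in clones
        )
        assert out.values.sum() == pytest.approx(expected)

    def test_unknown_spot_rejected(self):
        with pytest.raises(ConfigError):
            clone_state_matrix(self.STATES, [make_clone("c1", {"NOPE": 1})])


class TestRlKld:
    def test_identical_profiles_zero(self):
        p = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert rl_kld(p, p.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two_spot_example(self):
        p = pd.Series([0.5, 0.5], index=["s1", "s2"])
        q = pd.Series([0.9, 0.1], index=["s1", "s2"])
        expected = 0.5 * math.log(0.5 / 0.9) + 0.5 * math.log(0.5 / 0.1)
        assert rl_kld(p, q) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(0.5108, abs=5e-4)

    def test_nonnegative_and_reorder_invariant(self):
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(10)]
        p = pd.Series(rng.random(10), index=idx)
        q = pd.Series(rng.random(10), index=idx)
        v = rl_kld(p, q)
        assert v >= 0
        perm = list(reversed(idx))
        assert rl_kld(p[perm], q[perm]) == pytest.approx(v)

    def test_all_zero_profile_named_in_error(self):
        p = pd.Series([0.0, 0.0], index=["s1", "s2"], name="GENEX")
        q = pd.Series([1.0, 1.0], index=["s1", "s2"])
        with pytest.raises(ProfileError, match="GENEX"):
            rl_kld(p, q)

    def test_rank_returns_all_when_fewer_than_top(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(60)]
        M = pd.DataFrame(
            rng.random((60, 8)) + 0.01, index=genes, columns=[f"s{i}" for i in range(8)]
        )
        pairs = [(genes[i], genes[i + 30]) for i in range(30)]
        out = rank_rl(pairs, M)
        assert len(out) == 30
        assert (out["kld"].diff().dropna() >= 0).all()

    def test_rank_drops_missing_genes(self):
        M = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["s1", "s2"])
        out = rank_rl([("A", "NOPE")], M)
        assert out.empty and out.attrs["n_skipped"] == 1


class TestCompositeScore:
    def _matrix(self, rng, n_spots=30):
        genes = CLONAL_MARKERS + EXHAUSTION_MARKERS + ["BG0"]
        return pd.DataFrame(
            rng.random((len(genes), n_spots)) + 0.5,
            index=genes,
            columns=[f"s{i}" for i in range(n_spots)],
        )

    def test_spot_without_tcr_is_unscored(self):
        rng = np.random.default_rng(0)
        M = self._matrix(rng)
        presence = pd.Series(True, index=M.columns)
        presence["s0"] = False
        out = composite_tcell_score(M, presence)
        assert out.loc["s0", "label"] == "unscored"
        assert (out.loc[presence, "label"] != "unscored").all()

    def test_clonal_dominance_is_productive(self):
        rng = np.random.default_rng(1)
        M = self._matrix(rng)
        M.loc[CLONAL_MARKERS, "s1"] = 50.0
        M.loc[EXHAUSTION_MARKERS, "s1"] = 0.0
        out = composite_tcell_score(M, pd.Series(True, index=M.columns))
        assert out.loc["s1", "label"] == "productive"

    def test_constant_marker_row_skipped(self):
        rng = np.random.default_rng(2)
        M = self._matrix(rng)
        M.loc["IL2"] = 1.0  # zero variance
        out = composite_tcell_score(M, pd.Series(True, index=M.columns))
        assert "IL2" in out.attrs["skipped_constant_markers"]

    def test_no_markers_at_all_is_config_error(self):
        M = pd.DataFrame([[1.0, 2.0]], index=["BG0"], columns=["s1", "s2"])
        with pytest.raises(ConfigError):
            composite_tcell_score(M, pd.Series(True, index=M.columns))

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        M = self._matrix(rng)
        presence = pd.Series(True, index=M.columns)
        base = composite_tcell_score(M, presence)
        scaled = M.mul(
            pd.Series(rng.random(len(M.index)) * 4 + 0.5, index=M.index), axis=0
        ).add(pd.Series(rng.random(len(M.index)) * 3, index=M.index), axis=0)
        out = composite_tcell_score(scaled, presence)
        assert (out["label"] == base["label"]).all()
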