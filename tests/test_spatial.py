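import math

import numpy as np
import pandas as pd
import pytest

from oracles import brute_delaunay_edges
from spatialtcr.model import Clone, SpotTable
from spatialtcr.spatial import (
    GeometryError,
    classify_spots,
    clonality_index,
    delaunay_graph,
    spot_diversity,
    spot_metrics,
    spot_summaries,
)


def spots_from_coords(coords, prefix="S"):
    return SpotTable(
        pd.DataFrame(
            {
                "barcode": [f"{prefix}{i:02d}" for i in range(len(coords))],
                "x": [c[0] for c in coords],
                "y": [c[1] for c in coords],
            }
        )
    )


def clone_at(barcodes, cid="TRB-0000", umis=1):
    return Clone(
        cid, "TRB", "CASSLGF", {"CASSLGF"}, 1.0, 1.0, {b: umis for b in barcodes}
    )


TRIANGLE = spots_from_coords([(0, 0), (1, 0), (0.5, 1)])
SQUARE = spots_from_coords([(0, 0), (1, 0), (0, 1), (1, 1)])
HEXAGON = spots_from_coords(
    [(math.cos(k * math.pi / 3), math.sin(k * math.pi / 3)) for k in range(6)]
    + [(0.0, 0.0)]
)


class TestDelaunayGraph:
    def test_triangle_has_three_edges(self):
        assert delaunay_graph(TRIANGLE).n_edges == 3

    def test_unit_square_has_five_edges(self):
        g = delaunay_graph(SQUARE, prune_factor=float("inf"))
        assert g.n_edges == 5

    def test_hexagon_center_has_degree_six(self):
        g = delaunay_graph(HEXAGON, prune_factor=float("inf"))
        assert g.degree("S06") == 6

    def test_collinear_points_raise_geometry_error(self):
        line = spots_from_coords([(0, 0), (1, 1), (2, 2), (3, 3)])
        with pytest.raises(GeometryError, match="k-nearest"):
            delaunay_graph(line)

    def test_pruning_removes_border_artifact(self):
        coords = [(0, 0), (1, 0), (0, 1), (1, 1), (50, 0.5)]
        g_all = delaunay_graph(spots_from_coords(coords), prune_factor=float("inf"))
        g_pruned = delaunay_graph(spots_from_coords(coords), prune_factor=3.0)
        assert g_pruned.degree("S04") == 0 < g_all.degree("S04")

    def test_euler_bound(self, small_bundle):
        g = delaunay_graph(small_bundle.spot_table)
        n = len(g.barcodes)
        assert g.n_edges <= 3 * n - 6

    def test_matches_circumcircle_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            pts = rng.random((8, 2))
            got = {
                tuple(sorted((int(a[1:]), int(b[1:]))))
                for a, b in delaunay_graph(
                    spots_from_coords(pts), prune_factor=float("inf")
                ).edges
            }
            assert got == brute_delaunay_edges(pts)

    def test_duplicate_coordinates_jittered_not_fatal(self):
        coords = [(0, 0), (0, 0), (1, 0), (0, 1)]
        g = delaunay_graph(spots_from_coords(coords))
        assert g.n_edges >= 3


class TestClonalityIndex:
    def test_isolated_spot_scores_zero(self):
        g = delaunay_graph(TRIANGLE)
        (stat,) = clonality_index(g, [clone_at(["S00"])])
        assert stat.clonality_index == 0.0
        assert stat.per_spot_m == {"S00": 0}

    def test_adjacent_pair_scores_one(self):
        g = delaunay_graph(TRIANGLE)
        (stat,) = clonality_index(g, [clone_at(["S00", "S01"])])
        assert stat.clonality_index == 1.0

    def test_full_triangle_scores_two(self):
        g = delaunay_graph(TRIANGLE)
        (stat,) = clonality_index(g, [clone_at(["S00", "S01", "S02"])])
        assert stat.clonality_index == 2.0
        assert stat.clonality_sum == 6

    def test_rigid_motion_invariance(self):
        coords = np.random.default_rng(3).random((12, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = coords @ R.T + np.array([5.0, -2.0])
        support = [f"S{i:02d}" for i in (0, 3, 5, 8)]
        a = clonality_index(delaunay_graph(spots_from_coords(coords)), [clone_at(support)])
        b = clonality_index(delaunay_graph(spots_from_coords(moved)), [clone_at(support)])
        assert a[0].clonality_index == b[0].clonality_index

    def test_expanded_beats_dispersed_on_one_bundle(self, small_bundle):
        g = delaunay_graph(small_bundle.spot_table)
        clones = [
            Clone(ct.clone_id, ct.locus, ct.cdr3_aa, {ct.cdr3_aa}, 1.0, 1.0, ct.spot_umis)
            for ct in small_bundle.clone_truths
        ]
        stats = {s.clone_id: s.clonality_index for s in clonality_index(g, clones)}
        by_pattern = {"expanded": [], "dispersed": []}
        for ct in small_bundle.clone_truths:
            by_pattern[ct.pattern].append(stats[ct.clone_id])
        assert np.mean(by_pattern["expanded"]) > np.mean(by_pattern["dispersed"])


class TestSpotDiversity:
    def test_single_cdr3_is_zero(self):
        assert spot_diversity(["CASSLGF"]) == 0.0

    def test_pair_at_distance_four(self):
        assert spot_diversity(["AAAA", "TTTT"]) == 4.0

    def test_three_sequences_hand_computed(self):
        # pairwise distances {2, 4, 6}; per-sequence means {4, 3, 5}
        x, y, z = "AAAAAA", "AAAABB", "BBBBBB"
        assert spot_diversity([x, y, z]) == 4.0

    def test_equals_mean_of_ordered_pairs(self):
        from spatialtcr.repertoire import levenshtein

        rng = np.random.default_rng(17)
        seqs = list(
            {"".join(rng.choice(list("ACDEF"), size=rng.integers(4, 9))) for _ in range(8)}
        )
        direct = np.mean(
            [
                levenshtein(a, b)
                for i, a in enumerate(seqs)
                for j, b in enumerate(seqs)
                if i != j
            ]
        )
        assert spot_diversity(seqs) == pytest.approx(direct)


class TestSpotSummariesAndClassification:
    def test_umi_threshold_on_clone_count(self):
        clones = [
            clone_at(["S00"], cid="TRB-0000", umis=6),
            clone_at(["S00"], cid="TRB-0001", umis=2),
        ]
        out = spot_summaries(clones, min_umi=5)
        row = out.set_index("barcode").loc["S00"]
        assert row["total_tcr_umis"] == 8 and row["n_clones"] == 1

    def test_min_umi_one_counts_all(self):
        clones = [clone_at(["S00"], cid=f"TRB-000{i}", umis=1) for i in range(3)]
        out = spot_summaries(clones, min_umi=1)
        assert out.set_index("barcode").loc["S00", "n_clones"] == 3

    def test_empty_spot_reports_zeros(self):
        out = spot_summaries([clone_at(["S00"])], spot_table=TRIANGLE)
        row = out.set_index("barcode").loc["S02"]
        assert row["total_tcr_umis"] == 0 and row["n_clones"] == 0

    def _classified(self, clones, **kwargs):
        g = delaunay_graph(TRIANGLE)
        stats = clonality_index(g, clones)
        metrics = spot_metrics(clones, spot_table=TRIANGLE, min_umi=1)
        return classify_spots(metrics, stats, clones, **kwargs).set_index("barcode")

    def test_no_tcr_spot_is_none(self):
        out = self._classified([clone_at(["S00"])])
        assert out.loc["S02", "label"] == "none"

    def test_expanded_clone_labels_expansion(self):
        # clone with 10+ UMIs on adjacent spots: index 1 is not > 1,
        # so use the full triangle (index 2 > 1) with > 5 UMIs
        out = self._classified([clone_at(["S00", "S01", "S02"], umis=4)])
        assert (out["label"] == "expansion").all()

    def test_diverse_spot_labels_diversity(self):
        cdr3s = ["CASSLGFAA", "CTTRRQPYY", "CGGKKMMWW", "CPPHHDDEE"]
        clones = [
            Clone(f"TRB-{i:04d}", "TRB", s, {s}, 1.0, 1.0, {"S00": 1})
            for i, s in enumerate(cdr3s)
        ]
        out = self._classified(clones)
        assert out.loc["S00", "label"] == "diversity"

    def test_labels_exhaustive_and_exclusive(self, small_bundle):
        clones = [
            Clone(ct.clone_id, ct.locus, ct.cdr3_aa, {ct.cdr3_aa}, 1.0, 1.0, ct.spot_umis)
            for ct in small_bundle.clone_truths
        ]
        g = delaunay_graph(small_bundle.spot_table)
        stats = clonality_index(g, clones)
        metrics = spot_metrics(clones, spot_table=small_bundle.spot_table)
        out = classify_spots(metrics, stats, clones)
        assert set(out["label"]) <= {"none", "expansion", "diversity", "ambiguous"}
        assert (out.loc[out["total_tcr_umis"] == 0, "label"] == "none").all()
        assert len(out) == len(small_bundle.spot_table)
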