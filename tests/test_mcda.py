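"""AHP weighting, prioritization schemes, ROI, weight space, Pareto
frontiers, gap tables and solution comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pieces
from pieces.errors import MatrixError, TableError


def brute_force_front(pts):
    """O(k^2) dominance filter (maximize both axes): the independent oracle."""
    pts = np.unique(np.asarray(pts, dtype=float), axis=0)
    keep = []
    for p in pts:
        dominated = any(
            (q[0] >= p[0] and q[1] >= p[1]) and (q[0] > p[0] or q[1] > p[1])
            for q in pts
        )
        if not dominated:
            keep.append(p)
    return np.array(sorted(map(tuple, keep)))


class TestAHP:
    def test_all_ones_matrix(self):
        res = pieces.ahp_weights(np.ones((4, 4)))
        assert np.allclose(res.weights, 0.25)
        assert res.lambda_max == pytest.approx(4.0)
        assert res.consistency_ratio == pytest.approx(0.0, abs=1e-12)

    def test_consistent_matrix_recovers_ratios(self):
        v = np.array([0.5, 0.25, 0.125, 0.125])
        res = pieces.ahp_weights(v[:, None] / v[None, :])
        assert np.allclose(res.weights, v, atol=1e-10)
        assert res.consistency_ratio == pytest.approx(0.0, abs=1e-9)

    def test_inconsistent_matrix_matches_dense_eigen_oracle(self):
        a = np.array([[1.0, 3.0, 5.0], [1 / 3, 1.0, 1 / 2], [1 / 5, 2.0, 1.0]])
        res = pieces.ahp_weights(a)
        eigvals, eigvecs = np.linalg.eig(a)
        idx = int(np.argmax(eigvals.real))
        oracle = np.abs(eigvecs[:, idx].real)
        oracle /= oracle.sum()
        assert np.abs(res.weights - oracle).max() < 1e-8
        assert res.lambda_max == pytest.approx(float(eigvals.real[idx]), abs=1e-8)
        assert res.consistency_ratio > 0

    def test_weights_positive_sum_one_on_random_reciprocal(self):
        rng = np.random.default_rng(2)
        for n in (3, 4, 6):
            upper = rng.uniform(1 / 9, 9, size=(n, n))
            a = np.ones((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    a[i, j] = upper[i, j]
                    a[j, i] = 1 / upper[i, j]
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                res = pieces.ahp_weights(a)
            assert (res.weights > 0).all()
            assert res.weights.sum() == pytest.approx(1.0)

    def test_non_reciprocal_rejected(self):
        a = np.ones((3, 3))
        a[0, 1] = 2.0
        with pytest.raises(MatrixError):
            pieces.ahp_weights(a)

    def test_saaty_scale_enforcement(self):
        a = np.array([[1.0, 12.0], [1 / 12.0, 1.0]])
        pieces.ahp_weights(a)  # fine when not enforced
        with pytest.raises(MatrixError):
            pieces.ahp_weights(a, saaty=True)


class TestSchemes:
    def test_ed_seed_bank_toy_enumeration(self):
        table = pd.DataFrame(
            {
                "taxon": list("abcde"),
                "rank": ["R1", "R2", "R3", "R4", "R5"],
                "n_seed": [0, 2, 0, 1, 3],
                "n_living": [0, 0, 1, 1, 2],
                "ed": [1.0, 9.0, 5.0, 2.0, 3.0],
            }
        )
        sel = pieces.scheme_selection("EDSeedBank", table, n=2)
        assert sel == ["c", "a"]  # the two unbanked taxa, ED-descending

    def test_endangered_replicates_within_top_stratum(self, fixture500):
        _, table, ed = fixture500
        n_r1 = (table["rank"] == "R1").sum()
        fams = pieces.scheme_selection(
            "Endangered", table, ed, n=n_r1 - 5, n_subsamples=10, seed=4
        )
        r1 = set(table.loc[table["rank"] == "R1", "taxon"])
        assert len(fams) == 10
        for sel in fams:
            assert len(sel) == n_r1 - 5
            assert set(sel) <= r1

    def test_endangered_fills_across_strata(self, fixture500):
        _, table, ed = fixture500
        n_r1 = (table["rank"] == "R1").sum()
        fams = pieces.scheme_selection(
            "Endangered", table, ed, n=n_r1 + 10, n_subsamples=5, seed=4
        )
        r1 = set(table.loc[table["rank"] == "R1", "taxon"])
        for sel in fams:
            assert r1 <= set(sel)
            extra = set(sel) - r1
            assert len(extra) == 10
            assert extra <= set(table.loc[table["rank"] == "R2", "taxon"])

    def test_exsitu_replicates_from_uncollected_pool(self, fixture500):
        _, table, ed = fixture500
        pool = set(
            table.loc[(table["n_seed"] == 0) & (table["n_living"] == 0), "taxon"]
        )
        fams = pieces.scheme_selection(
            "ExSitu", table, ed, n=50, n_subsamples=8, seed=1
        )
        for sel in fams:
            assert set(sel) <= pool and len(sel) == 50

    def test_pieces_scheme_deterministic(self, fixture500):
        _, table, ed = fixture500
        a = pieces.scheme_selection(
            "PIECES", table, ed, n=100, weights=pieces.PUBLISHED_WEIGHTS
        )
        b = pieces.scheme_selection(
            "PIECES", table, ed, n=100, weights=pieces.PUBLISHED_WEIGHTS
        )
        assert a == b

    def test_unknown_scheme(self, fixture500):
        _, table, ed = fixture500
        with pytest.raises(ValueError):
            pieces.scheme_selection("Random", table, ed, n=10)


class TestROI:
    def test_toy_arithmetic(self):
        table = pd.DataFrame(
            {
                "taxon": ["a", "b"],
                "rank": ["R1", "R5"],
                "n_seed": [0, 3],
                "n_living": [1, 0],
                "ed": [2.0, 4.0],
            }
        )
        rec = pieces.roi(["a", "b"], table)
        assert rec.new_seed == 1
        assert rec.new_living == 1
        assert rec.mean_threat == pytest.approx(2.0)
        assert rec.mean_ed == pytest.approx(3.0)

    def test_all_uncollected_selection(self, fixture500):
        _, table, ed = fixture500
        pool = table.loc[
            (table["n_seed"] == 0) & (table["n_living"] == 0), "taxon"
        ].tolist()[:20]
        rec = pieces.roi(pool, table, ed)
        assert rec.new_seed == 20 and rec.new_living == 20

    def test_unknown_taxon_rejected(self, fixture500):
        _, table, ed = fixture500
        with pytest.raises(TableError):
            pieces.roi(["not_a_taxon", table["taxon"].iloc[0]], table, ed)


class TestWeightSpace:
    def test_simplex_sampling_moments(self):
        ws = pieces.sample_weight_vectors(100_000, dims=4, seed=0)
        assert np.abs(ws.sum(axis=1) - 1).max() < 1e-12
        assert np.abs(ws.mean(axis=0) - 0.25).max() < 0.005
        assert np.array_equal(ws, pieces.sample_weight_vectors(100_000, dims=4, seed=0))

    def test_k1_reduces_to_rank_select_roi(self, fixture500):
        """Any single-weight-vector row must equal the rank_select + roi
        composition under the same weights."""
        _, table, ed = fixture500
        cloud = pieces.weight_space_analysis(table, ed, k=3, n=80, seed=9)
        for _, row in cloud.iterrows():
            w = row[["w1", "w2", "w3", "w4"]].to_numpy()
            w = w / w.sum()
            scored = pieces.pieces_scores(table, w, ed)
            sel = pieces.rank_select(
                pd.Series(scored["pieces"].to_numpy(), index=scored["taxon"].to_numpy()),
                80,
            )
            rec = pieces.roi(sel, table, ed)
            assert rec.new_seed == row["new_seed"]
            assert rec.mean_ed == pytest.approx(row["mean_ed"])

    def test_cloud_bounds(self, fixture500):
        _, table, ed = fixture500
        cloud = pieces.weight_space_analysis(table, ed, k=50, n=60, seed=2)
        assert (cloud["new_seed"] <= 60).all()
        assert (cloud["new_living"] <= 60).all()
        assert cloud["mean_threat"].between(0, 4).all()


class TestParetoFront:
    def test_worked_example(self):
        front = pieces.pareto_front([(1, 1), (2, 0), (0, 2), (0.5, 0.5)])
        assert front.tolist() == [[0, 2], [1, 1], [2, 0]]

    def test_single_point_and_curve(self):
        assert pieces.pareto_front([(3, 4)]).tolist() == [[3, 4]]
        xs = np.linspace(0, 1, 20)
        curve = np.c_[xs, 1 - xs]
        assert len(pieces.pareto_front(curve)) == 20

    def test_min_orientation(self):
        pts = [(1, 1), (0, 0), (2, 2), (0, 3)]
        front = pieces.pareto_front(pts, orientation=("min", "min"))
        assert front.tolist() == [[0, 0]]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=-5, max_value=5),
                st.integers(min_value=-5, max_value=5),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_brute_force_oracle(self, pts):
        front = pieces.pareto_front(pts)
        oracle = brute_force_front(pts)
        assert np.array_equal(np.array(sorted(map(tuple, front))), oracle)

    def test_roi_cloud_inside_its_front(self, fixture500):
        _, table, ed = fixture500
        cloud = pieces.weight_space_analysis(table, ed, k=40, n=50, seed=3)
        for x, y in (("new_seed", "mean_ed"), ("mean_threat", "new_living")):
            pts = cloud[[x, y]].to_numpy()
            front = pieces.pareto_front(pts)
            for p in pts:
                assert any((f[0] >= p[0]) and (f[1] >= p[1]) for f in front)


class TestGapTable:
    def test_perfect_independence(self):
        table = pd.DataFrame(
            {
                "taxon": [f"t{i}" for i in range(40)],
                "rank": ["R1"] * 20 + ["R2"] * 20,
                "n_seed": ([1] * 10 + [0] * 10) * 2,
                "n_living": [0] * 40,
            }
        )
        counts, chi2, p = pieces.gap_table(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert counts.to_numpy().sum() == 40

    def test_matches_closed_form(self):
        # 2x2 block: seed_only vs neither across R1/R2 with known marginals
        table = pd.DataFrame(
            {
                "taxon": [f"t{i}" for i in range(30)],
                "rank": ["R1"] * 10 + ["R2"] * 20,
                "n_seed": [1] * 8 + [0] * 2 + [1] * 4 + [0] * 16,
                "n_living": [0] * 30,
            }
        )
        counts, chi2, p = pieces.gap_table(table)
        obs = np.array([[8, 4], [2, 16]])
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        manual = ((obs - exp) ** 2 / exp).sum()
        assert chi2 == pytest.approx(manual)

    def test_counts_partition_table(self, fixture500):
        _, table, _ = fixture500
        counts, chi2, p = pieces.gap_table(table)
        assert counts.to_numpy().sum() == len(table)
        assert chi2 >= 0


class TestCompareSolutions:
    def test_self_similarity(self, fixture500):
        tree, table, ed = fixture500
        sel = pieces.scheme_selection(
            "PIECES", table, ed, n=60, weights=pieces.PUBLISHED_WEIGHTS
        )
        jac, phy = pieces.compare_solutions({"a": sel, "b": list(sel)}, tree)
        assert jac.loc["a", "b"] == pytest.approx(1.0)
        assert phy.loc["a", "b"] == pytest.approx(1.0)

    def test_disjoint_clades(self):
        tree = pieces.read_newick(
            "((A1:1,A2:1,A3:1):5,(B1:1,B2:1,B3:1):5);"
        )
        jac, phy = pieces.compare_solutions(
            {"left": ["A1", "A2"], "right": ["B1", "B2"]}, tree
        )
        assert jac.loc["left", "right"] == 0.0
        assert phy.loc["left", "right"] == 0.0

    def test_family_mean_and_symmetry(self, fixture500):
        tree, table, ed = fixture500
        det = pieces.scheme_selection(
            "PIECES", table, ed, n=50, weights=pieces.PUBLISHED_WEIGHTS
        )
        fam = pieces.scheme_selection(
            "ExSitu", table, ed, n=50, n_subsamples=6, seed=0
        )
        jac, phy = pieces.compare_solutions({"PIECES": det, "ExSitu": fam}, tree)
        assert jac.loc["PIECES", "ExSitu"] == jac.loc["ExSitu", "PIECES"]
        assert 0 <= phy.loc["PIECES", "ExSitu"] <= 1
        # mean over family replicates equals the hand-rolled mean
        manual = np.mean(
            [pieces.jaccard_similarity(det, f) for f in fam]
        )
        assert jac.loc["PIECES", "ExSitu"] == pytest.approx(manual)
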