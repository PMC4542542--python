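"""Bray-Curtis, PCoA, NMDS, RDA/dbRDA and forward selection against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

import sedlineage as sl
from sedlineage.errors import DegenerateInputError, InvalidArgumentError
from sedlineage.ordination import _stress_and_disparities


def euclid_dm(points, ids=None):
    return DistanceMatrix(squareform(pdist(np.asarray(points, float))), ids=ids)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = sl.bray_curtis(pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["a", "b"]))
        assert d["a", "b"] == 0.0

    def test_disjoint_rows_one(self):
        d = sl.bray_curtis(pd.DataFrame([[1, 1, 0], [0, 0, 1]], index=["a", "b"]))
        assert d["a", "b"] == 1.0

    def test_hand_formula(self):
        d = sl.bray_curtis(pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"]))
        assert d["a", "b"] == pytest.approx(0.5)

    def test_binarization_applied_by_default(self):
        abundant = pd.DataFrame([[10, 10, 0], [1, 0, 1]], index=["a", "b"])
        assert sl.bray_curtis(abundant)["a", "b"] == pytest.approx(0.5)

    def test_negative_entries_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sl.bray_curtis(pd.DataFrame([[-1, 0], [0, 1]]))

    def test_double_zero_pair_defined_as_zero(self):
        with pytest.warns(UserWarning, match="empty samples"):
            d = sl.bray_curtis(pd.DataFrame([[0, 0], [0, 0], [1, 0]], index=list("abc")))
        assert d["a", "b"] == 0.0


class TestPcoa:
    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.standard_normal((15, 2))
        res = sl.pcoa(euclid_dm(pts))
        got = res.coordinates[:, :2]
        # Procrustes: compare pairwise distances instead of raw coordinates
        assert np.allclose(pdist(got), pdist(pts), atol=1e-8)

    def test_three_equidistant_points(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        res = sl.pcoa(d)
        pos = res.positive_eigenvalues
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])

    def test_total_inertia_bookkeeping(self, rng):
        res = sl.pcoa(euclid_dm(rng.standard_normal((10, 3))))
        assert res.total_inertia == pytest.approx(res.positive_eigenvalues.sum())
        assert res.total_inertia == pytest.approx((res.coordinates**2).sum())

    def test_matches_skbio_eigenvalues(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        d = euclid_dm(rng.standard_normal((12, 3)))
        mine = sl.pcoa(d)
        theirs = skbio_pcoa(d)
        assert np.allclose(mine.eigenvalues[:6], theirs.eigvals.values[:6], atol=1e-10)

    def test_corrections_remove_negative_eigenvalues(self):
        # Bray-Curtis matrices are generally non-Euclidean
        rng = np.random.default_rng(5)
        occ = pd.DataFrame(rng.integers(0, 2, size=(10, 8)))
        d = sl.bray_curtis(occ)
        for policy in ("lingoes", "cailliez"):
            res = sl.pcoa(d, negative_policy=policy)
            tol = -1e-8 * max(1.0, abs(res.eigenvalues[0]))
            assert (res.eigenvalues >= tol).all()
            assert res.correction >= 0.0


class TestNmds:
    def test_perfect_input_has_near_zero_stress(self, rng):
        pts = rng.standard_normal((10, 2))
        res = sl.nmds(euclid_dm(pts), k=2, n_starts=4, seed=0)
        assert res.stress < 0.01

    def test_four_point_grid_search_oracle(self):
        d = DistanceMatrix(
            np.array(
                [[0, 3, 1, 2], [3, 0, 2, 1], [1, 2, 0, 3], [2, 1, 3, 0]], float
            )
        )
        res = sl.nmds(d, k=1, n_starts=30, seed=0)
        # dense grid over 1-D configurations x=(0, a, b, 1)
        grid = np.linspace(-0.6, 1.6, 111)
        best = np.inf
        iu = np.triu_indices(4, k=1)
        dissim = d.data[iu]
        for a in grid:
            for b in grid:
                x = np.array([[0.0], [a], [b], [1.0]])
                conf = squareform(pdist(x))[iu]
                stress, _ = _stress_and_disparities(dissim, conf)
                best = min(best, stress)
        assert res.stress <= best + 1e-3

    def test_more_dimensions_never_hurt(self, rng):
        d = euclid_dm(rng.standard_normal((8, 3)))
        s1 = sl.nmds(d, k=1, n_starts=8, seed=1).stress
        s2 = sl.nmds(d, k=2, n_starts=8, seed=1).stress
        assert s2 <= s1 + 1e-9

    def test_stress_scale_invariant(self, rng):
        pts = rng.standard_normal((9, 3))
        d1 = euclid_dm(pts)
        d2 = DistanceMatrix(d1.data * 7.3)
        r1 = sl.nmds(d1, k=2, n_starts=3, seed=2)
        r2 = sl.nmds(d2, k=2, n_starts=3, seed=2)
        assert r1.stress == pytest.approx(r2.stress, abs=1e-6)


class TestDummyCoding:
    def _table(self):
        return pd.DataFrame({"veg": ["a", "b", "c", "d"] * 5 + ["a"]})

    def test_reference_dropped(self):
        x = sl.dummy_code(self._table(), "veg")
        assert x.shape[1] == 3
        assert set(x.columns) == {"veg[b]", "veg[c]", "veg[d]"}

    def test_row_sums_before_drop(self):
        x = sl.dummy_code(self._table(), "veg", drop_reference=False)
        assert (x.sum(axis=1) == 1).all()

    def test_single_level_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sl.dummy_code(pd.DataFrame({"veg": ["a", "a"]}), "veg")

    def test_r2_invariant_to_reference_choice(self, rng):
        table = self._table()
        y = rng.standard_normal((len(table), 3))
        r_a = sl.rda(y, sl.dummy_code(table, "veg", reference="a"), n_perm=19, seed=0)
        r_c = sl.rda(y, sl.dummy_code(table, "veg", reference="c"), n_perm=19, seed=0)
        assert r_a.r2 == pytest.approx(r_c.r2, abs=1e-12)


class TestRda:
    def test_orthogonal_explanatory_gives_null_fit(self):
        n = 24
        y = np.zeros((n, 1))
        y[: n // 2, 0] = 1.0
        x = np.tile([1.0, -1.0], n // 2)[:, None]  # orthogonal to y by construction
        res = sl.rda(y - y.mean(), x, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.5

    def test_univariate_matches_squared_pearson(self, rng):
        y = rng.standard_normal(30)
        x = 0.5 * y + rng.standard_normal(30)
        res = sl.rda(y, x, n_perm=9, seed=0)
        r = np.corrcoef(x, y)[0, 1]
        assert res.r2 == pytest.approx(r**2, abs=1e-10)

    def test_perfect_fit(self, rng):
        x = rng.standard_normal((20, 2))
        y = x @ rng.standard_normal((2, 3))
        res = sl.rda(y, x, n_perm=9, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_adjusted_never_exceeds_r2(self, rng):
        for _ in range(10):
            y = rng.standard_normal((15, 2))
            x = rng.standard_normal((15, 3))
            res = sl.rda(y, x, n_perm=9, seed=0)
            assert res.adj_r2 <= res.r2 + 1e-12

    def test_rank_deficient_columns_warned(self, rng):
        x = rng.standard_normal((15, 2))
        x = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = sl.rda(rng.standard_normal((15, 2)), x, n_perm=9, seed=0)
        assert res.rank == 2


class TestDbrda:
    def test_equivalence_with_rda_on_euclidean_distances(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 31))
            m = int(rng.integers(2, 6))
            y = rng.standard_normal((n, 4))
            x = pd.DataFrame(rng.standard_normal((n, m)))
            raw = sl.rda(y, x, n_perm=9, seed=1)
            x.index = [str(i) for i in range(n)]
            via_d = sl.dbrda(euclid_dm(y, ids=list(x.index)), x, n_perm=9, seed=1)
            assert via_d.r2 == pytest.approx(raw.r2, abs=1e-9)

    def test_constant_explanatory_rejected(self, rng):
        d = euclid_dm(rng.standard_normal((10, 2)))
        with pytest.raises(DegenerateInputError):
            sl.dbrda(d, np.ones((10, 1)), n_perm=9, seed=0)


class TestForwardSelection:
    def test_perfect_single_candidate_selected_first(self, rng):
        x = pd.DataFrame(rng.standard_normal((20, 3)), columns=["c1", "c2", "c3"])
        y = np.outer(x["c1"], [1.0, -2.0])
        res = sl.forward_select(y, x, alpha=0.1, n_perm=99, seed=0)
        assert res.selected[0] == "c1"
        assert res.final.r2 >= 0.99

    def test_orthogonal_candidate_rarely_selected(self):
        """Null calibration: selection rate of a pure-noise candidate ~ alpha."""
        selected = 0
        runs = 200
        for s in range(runs):
            rng = np.random.default_rng(s)
            y = rng.standard_normal((15, 2))
            x = pd.DataFrame({"noise": rng.standard_normal(15)})
            res = sl.forward_select(y, x, alpha=0.1, n_perm=99, seed=s)
            selected += bool(res.selected)
        # binomial 99% band around 0.1 at 200 runs: +/- 2.58*sqrt(.1*.9/200) ~ 0.055
        assert 0.045 <= selected / runs <= 0.155

    def test_collinear_candidates_select_exactly_one(self, rng):
        base = rng.standard_normal(25)
        x = pd.DataFrame({"a": base, "b": base * 2.0})
        y = np.outer(base, [1.0, 1.0]) + 0.01 * rng.standard_normal((25, 2))
        res = sl.forward_select(y, x, alpha=0.1, n_perm=99, seed=0)
        assert len(res.selected) == 1

    def test_distance_response_uses_pcoa_axes(self, rng):
        pts = rng.standard_normal((18, 2))
        x = pd.DataFrame({"x0": pts[:, 0]}, index=[str(i) for i in range(18)])
        d = euclid_dm(pts, ids=list(x.index))
        res = sl.forward_select(d, x, alpha=0.1, n_perm=99, seed=0)
        assert res.selected == ["x0"]


class TestPermutationCalibration:
    def test_rda_null_rejection_rate_near_alpha(self):
        """Exchangeable null: empirical size of the permutation test ~ 0.05."""
        rej = 0
        runs = 300
        for s in range(runs):
            rng = np.random.default_rng(s)
            y = rng.standard_normal((12, 2))
            x = rng.standard_normal((12, 1))
            rej += sl.rda(y, x, n_perm=99, seed=s + 1).p_value <= 0.05
        # binomial 99% band around 0.05 at 300 runs
        band = 2.576 * np.sqrt(0.05 * 0.95 / runs)
        assert abs(rej / runs - 0.05) <= band
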