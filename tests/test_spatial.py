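"""Mantel tests, PCNM eigenvectors, forward selection, db-RDA and
variation partitioning."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from phylorao.spatial import (
    _tri,
    dbrda_r2,
    euclidean_plot_distances,
    ezekiel_adjusted_r2,
    forward_select,
    gradient_distance,
    mantel,
    partial_mantel,
    pcnm_basis,
    pcoa_coordinates,
    variation_partition,
)
from tests.conftest import random_distance_matrix


def coords_frame(xy):
    return pd.DataFrame(xy, columns=["easting", "northing"],
                        index=[f"p{i}" for i in range(len(xy))])


class TestEuclidean:
    def test_three_four_five(self):
        dm = euclidean_plot_distances(coords_frame([(0, 0), (3, 4)]))
        assert dm["p0", "p1"] == pytest.approx(5.0)

    def test_translation_invariance(self, rng):
        xy = rng.normal(size=(8, 2))
        a = euclidean_plot_distances(coords_frame(xy)).data
        b = euclidean_plot_distances(coords_frame(xy + 1000)).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_matches_brute_force(self, rng):
        xy = rng.normal(size=(6, 2)) * 10
        dm = euclidean_plot_distances(coords_frame(xy)).data
        for i in range(6):
            for j in range(6):
                expected = np.hypot(*(xy[i] - xy[j]))
                assert dm[i, j] == pytest.approx(expected, abs=1e-9)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        a = random_distance_matrix(rng, 10)
        r, p = mantel(a, a, n_perm=99, rng=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_affine_invariance(self, rng):
        a = random_distance_matrix(rng, 10)
        b = random_distance_matrix(rng, 10)
        r1, _ = mantel(a, b, n_perm=99, rng=0)
        r2, _ = mantel(a, 3 * b + 5, n_perm=99, rng=0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_r_matches_skbio_oracle(self, rng):
        for _ in range(5):
            a = random_distance_matrix(rng, 12)
            b = random_distance_matrix(rng, 12)
            r_ours, _ = mantel(a, b, n_perm=99, rng=0)
            ids = [str(i) for i in range(12)]
            r_skbio, _, _ = __import__("skbio.stats.distance", fromlist=["mantel"]).mantel(
                DistanceMatrix(a, ids), DistanceMatrix(b, ids),
                permutations=0,
            )
            assert r_ours == pytest.approx(float(r_skbio), abs=1e-10)

    def test_min_permutations_enforced(self, rng):
        a = random_distance_matrix(rng, 5)
        with pytest.raises(ValueError):
            mantel(a, a, n_perm=10)


class TestPartialMantel:
    def test_reduces_to_simple_when_c_independent(self, rng):
        # diagnostic identity r_AB|C = r_AB at r_AC = r_BC = 0 is checked
        # through the formula on residualized inputs
        a = random_distance_matrix(rng, 12)
        b = random_distance_matrix(rng, 12)
        c = random_distance_matrix(rng, 12)
        r_simple, _ = mantel(a, b, n_perm=99, rng=0)
        r_part, _ = partial_mantel(a, b, c, n_perm=99, rng=0)
        # c is random so the partial r should be near the simple r
        assert abs(r_part - r_simple) < 0.35

    def test_conditioning_on_b_itself_is_degenerate(self, rng):
        # r_BC = 1 makes the partial correlation 0/0; refuse rather than
        # return an arbitrary value
        a = random_distance_matrix(rng, 10)
        b = random_distance_matrix(rng, 10)
        with pytest.raises(ValueError, match="degenerate"):
            partial_mantel(a, b, b + 0.0, n_perm=99, rng=0)

    def test_near_duplicate_conditioning_drives_r_to_zero(self, rng):
        # the B = C limit: conditioning on an almost-identical copy of B
        # leaves (numerically) no partial association
        a = random_distance_matrix(rng, 10)
        b = random_distance_matrix(rng, 10)
        c = b + random_distance_matrix(rng, 10) * 1e-3
        r, _ = partial_mantel(a, b, c, n_perm=99, rng=0)
        assert abs(r) < 0.1

    def test_matches_residual_correlation_oracle(self, rng):
        for _ in range(10):
            a = random_distance_matrix(rng, 10)
            b = random_distance_matrix(rng, 10)
            c = random_distance_matrix(rng, 10)
            r, _ = partial_mantel(a, b, c, n_perm=99, rng=0)
            # oracle: regress triangles of a and b on c, correlate residuals
            at, bt, ct = _tri(a), _tri(b), _tri(c)
            X = np.column_stack([np.ones_like(ct), ct])
            ra = at - X @ np.linalg.lstsq(X, at, rcond=None)[0]
            rb = bt - X @ np.linalg.lstsq(X, bt, rcond=None)[0]
            expected = np.corrcoef(ra, rb)[0, 1]
            assert r == pytest.approx(expected, abs=1e-10)

    def test_degenerate_conditioning_rejected(self, rng):
        b = random_distance_matrix(rng, 8)
        a = random_distance_matrix(rng, 8)
        with pytest.raises(ValueError, match="degenerate"):
            partial_mantel(a, b, 2 * b, n_perm=99, rng=0)


class TestPCNM:
    def test_line_of_points_sinusoid_sign_changes(self):
        xy = [(float(i * 100), 0.0) for i in range(12)]
        dm = euclidean_plot_distances(coords_frame(xy))
        basis = pcnm_basis(dm)
        signs = []
        for col in basis.eigenvectors.columns[:4]:
            v = basis.eigenvectors[col].to_numpy()
            signs.append(int(np.sum(np.diff(np.sign(v)) != 0)))
        assert signs == sorted(signs)

    def test_orthogonality(self, rng):
        for _ in range(10):
            xy = rng.normal(size=(15, 2)) * 100
            dm = euclidean_plot_distances(coords_frame(xy))
            V = pcnm_basis(dm).eigenvectors.to_numpy()
            np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]),
                                       atol=1e-8)

    def test_positive_eigenvalues_only(self, rng):
        xy = rng.normal(size=(10, 2)) * 100
        basis = pcnm_basis(euclidean_plot_distances(coords_frame(xy)))
        assert (basis.eigenvalues > 0).all()

    def test_reordering_input_reorders_output(self, rng):
        xy = rng.normal(size=(9, 2)) * 50
        df = coords_frame(xy)
        b1 = pcnm_basis(euclidean_plot_distances(df))
        shuffled = df.sample(frac=1, random_state=3)
        b2 = pcnm_basis(euclidean_plot_distances(shuffled))
        v1 = b1.eigenvectors
        v2 = b2.eigenvectors.reindex(v1.index)
        assert v1.shape == v2.shape
        for col in v1.columns:
            assert (np.allclose(v1[col], v2[col], atol=1e-8)
                    or np.allclose(v1[col], -v2[col], atol=1e-8))

    def test_identical_points_rejected(self):
        df = coords_frame([(0.0, 0.0)] * 4)
        with pytest.raises(ValueError):
            pcnm_basis(euclidean_plot_distances(df))


class TestDbRDA:
    def test_ezekiel_closed_form(self):
        assert ezekiel_adjusted_r2(0.5, 11, 1) == pytest.approx(4 / 9)

    def test_own_coordinates_explain_everything(self, rng):
        d = random_distance_matrix(rng, 10, scale=3.0)
        Y = pcoa_coordinates(d)
        r2, _ = dbrda_r2(d, Y[:, :8])
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_random_predictor_adjusted_near_zero(self, rng):
        vals = []
        for _ in range(50):
            d = random_distance_matrix(rng, 14, scale=2.0)
            x = rng.normal(size=14)
            _, adj = dbrda_r2(d, x)
            vals.append(adj)
        assert abs(np.mean(vals)) < 0.05

    def test_too_many_predictors_rejected(self, rng):
        d = random_distance_matrix(rng, 6)
        X = rng.normal(size=(6, 5))
        with pytest.raises(ValueError):
            dbrda_r2(d, X)


class TestForwardSelect:
    def test_single_perfect_candidate_selected_first(self, rng):
        x = rng.normal(size=20)
        Y = np.column_stack([x, 2 * x])
        cands = pd.DataFrame({"x": x, "noise": rng.normal(size=20)})
        sel = forward_select(Y, cands, n_perm=99, rng=0)
        assert sel[:1] == ["x"]

    def test_recovers_true_pair_from_ten(self, rng):
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(rep)
            cands = pd.DataFrame(
                r.normal(size=(30, 10)),
                columns=[f"c{i}" for i in range(10)],
            )
            Y = (3 * cands["c2"] + 3 * cands["c7"]
                 + r.normal(0, 0.3, 30)).to_numpy()[:, None]
            sel = forward_select(Y, cands, n_perm=99, rng=rep)
            hits += set(sel) == {"c2", "c7"}
        assert hits >= 8

    def test_pure_noise_mostly_empty(self, rng):
        empties = 0
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            cands = pd.DataFrame(r.normal(size=(25, 8)),
                                 columns=[f"c{i}" for i in range(8)])
            Y = r.normal(size=(25, 2))
            sel = forward_select(Y, cands, n_perm=99, rng=rep)
            empties += len(sel) == 0
        assert empties >= 15


class TestVariationPartition:
    def test_fractions_sum_to_one(self, rng):
        d = random_distance_matrix(rng, 15, scale=2.0)
        x1 = rng.normal(size=15)
        x2 = rng.normal(size=15)
        x3 = rng.normal(size=(15, 2))
        vp = variation_partition(d, x1, x2, x3, n_perm=99, rng=0)
        assert sum(vp.fractions.values()) == pytest.approx(1.0, abs=1e-6)

    def test_empty_space_set_contributes_zero(self, rng):
        d = random_distance_matrix(rng, 12, scale=2.0)
        vp = variation_partition(d, rng.normal(size=12),
                                 rng.normal(size=12), None,
                                 n_perm=99, rng=0)
        assert vp.fractions["c"] == pytest.approx(0.0, abs=1e-12)
        assert vp.fractions["e"] == pytest.approx(0.0, abs=1e-12)
        assert vp.fractions["f"] == pytest.approx(0.0, abs=1e-12)
        assert any("space" in n for n in vp.notes)
        assert np.isnan(vp.tests["unique_space"])

    def test_orthogonal_predictors_have_small_joints(self, rng):
        # build a response driven by two orthogonal predictors
        n = 20
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 3 * x1[:, None] + 3 * x2[:, None] + rng.normal(0, 0.2, (n, 1))
        d = np.abs(y - y.T)
        np.fill_diagonal(d, 0)
        vp = variation_partition(d, x1, x2, None, n_perm=99, rng=0)
        assert abs(vp.fractions["d"]) < 0.1
        assert vp.fractions["a"] > 0.2
        assert vp.fractions["b"] > 0.2

    def test_dominant_driver_recovered(self, rng):
        x1 = rng.normal(size=18)
        y = 5 * x1[:, None] + rng.normal(0, 0.3, (18, 1))
        d = np.abs(y - y.T)
        np.fill_diagonal(d, 0)
        vp = variation_partition(d, x1, rng.normal(size=18), None,
                                 n_perm=99, rng=0)
        assert vp.fractions["a"] > 0.5
        assert vp.tests["unique_disturbance"] < 0.05


def test_gradient_distance_abs_differences():
    s = pd.Series([1.0, 4.0, 2.0], index=["a", "b", "c"])
    dm = gradient_distance(s)
    assert dm["a", "b"] == pytest.approx(3.0)
    assert dm["b", "c"] == pytest.approx(2.0)
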