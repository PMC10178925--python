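import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from fringescope.community import DistanceMatrix, bray_curtis, normalize_counts
from fringescope.data_model import ASVTable, GeochemTable
from fringescope.ordination import (
    OrdinationError,
    cca_group_test,
    envfit,
    monotone_regression,
    nmds,
    rda_contribution,
)


def pava_oracle(y, weights=None):
    """Minimum-SSE monotone fit by enumerating contiguous block partitions."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    n = len(y)
    best = None
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        means = [np.average(y[a:b], weights=w[a:b])
                 for a, b in zip(bounds[:-1], bounds[1:])]
        if any(m2 < m1 for m1, m2 in zip(means[:-1], means[1:])):
            continue
        fit = np.concatenate([
            np.full(b - a, m) for (a, b), m in zip(zip(bounds[:-1], bounds[1:]), means)
        ])
        sse = float((w * (y - fit) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, fit)
    return best[1]


class TestMonotoneRegression:
    def test_monotone_input_unchanged(self):
        y = [1.0, 2.0, 2.5, 7.0]
        np.testing.assert_allclose(monotone_regression(y), y)

    def test_hand_pava_pools_all(self):
        np.testing.assert_allclose(monotone_regression([3.0, 1.0, 2.0]),
                                   [2.0, 2.0, 2.0])

    def test_constant_input_unchanged(self):
        np.testing.assert_allclose(monotone_regression([4.0] * 5), [4.0] * 5)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            y = rng.normal(size=n)
            np.testing.assert_allclose(monotone_regression(y), pava_oracle(y),
                                       atol=1e-10)

    def test_tied_keys_pooled(self):
        y = np.array([1.0, 5.0, 2.0, 8.0])
        keys = np.array([0.1, 0.5, 0.5, 0.9])
        fit = monotone_regression(y, keys=keys)
        assert fit[1] == pytest.approx(fit[2])       # tied keys share a value
        assert fit[1] == pytest.approx(3.5)          # pooled mean of 5 and 2

    def test_key_order_respected(self):
        y = np.array([5.0, 1.0])
        keys = np.array([2.0, 1.0])                  # ordering reverses y
        np.testing.assert_allclose(monotone_regression(y, keys=keys), [5.0, 1.0])


def procrustes_error(X, Y):
    """Residual after optimally rotating/scaling Y onto X (both centered)."""
    X = X - X.mean(0)
    Y = Y - Y.mean(0)
    U, s, Vt = np.linalg.svd(Y.T @ X)
    R = U @ Vt
    scale = s.sum() / (Y ** 2).sum()
    resid = X - scale * (Y @ R)
    return np.sqrt((resid ** 2).sum() / (X ** 2).sum())


class TestNMDS:
    def test_exactly_embeddable_points_recovered(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 1.2], [1.4, 0.9]])
        d = DistanceMatrix([f"s{i}" for i in range(4)],
                           squareform(pdist(pts)))
        res = nmds(d, n_restarts=5, seed=0)
        assert res.stress <= 1e-4
        assert procrustes_error(pts, res.coordinates) <= 1e-3

    def test_equilateral_three_points(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        res = nmds(d, k=2, n_restarts=3, seed=1)
        assert res.stress <= 1e-6
        dd = pdist(res.coordinates)
        assert np.ptp(dd) / dd.mean() < 1e-3         # equilateral configuration

    def test_stress_history_never_increases(self, study):
        ds, _ = study
        d = bray_curtis(normalize_counts(ds.counts))
        res = nmds(d, n_restarts=3, seed=2)
        h = np.array(res.stress_history)
        assert (np.diff(h) <= 1e-12).all()

    def test_seeded_determinism(self, study):
        ds, _ = study
        d = bray_curtis(normalize_counts(ds.counts))
        a = nmds(d, n_restarts=4, seed=7)
        b = nmds(d, n_restarts=4, seed=7)
        assert a.stress == b.stress
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_coordinates_centered_and_rotated(self, study):
        ds, _ = study
        d = bray_curtis(normalize_counts(ds.counts))
        res = nmds(d, n_restarts=2, seed=3)
        np.testing.assert_allclose(res.coordinates.mean(0), 0, atol=1e-10)
        cross = res.coordinates.T @ res.coordinates
        assert abs(cross[0, 1]) < 1e-8 * cross[0, 0]

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_too_few_samples_rejected(self):
        d = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(OrdinationError):
            nmds(d, k=2)


def _ordination_from_coords(coords):
    from fringescope.ordination import OrdinationResult
    coords = coords - coords.mean(0)
    return OrdinationResult([f"s{i}" for i in range(len(coords))], coords,
                            0.0, 1, True, 0)


def _geochem_from(df):
    return GeochemTable(df, {c: "" for c in df.columns})


class TestEnvfit:
    def test_axis_aligned_variable_is_perfect_fit(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(30, 2))
        ordn = _ordination_from_coords(coords)
        g = _geochem_from(pd.DataFrame({"v": ordn.coordinates[:, 0]},
                                       index=ordn.sample_ids))
        [fit] = envfit(ordn, g, ["v"], n_perm=99, seed=0)
        assert fit.r_squared == pytest.approx(1.0)
        assert abs(fit.direction[0]) == pytest.approx(1.0)
        assert abs(fit.direction[1]) < 1e-8
        assert fit.p_value == pytest.approx(1 / 100)

    def test_r2_equals_squared_correlation_with_fitted(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(25, 2))
        ordn = _ordination_from_coords(coords)
        v = coords[:, 0] * 0.3 + rng.normal(size=25)
        g = _geochem_from(pd.DataFrame({"v": v}, index=ordn.sample_ids))
        [fit] = envfit(ordn, g, ["v"], n_perm=49, seed=1)
        X = ordn.coordinates
        beta, *_ = np.linalg.lstsq(X, v - v.mean(), rcond=None)
        fitted = X @ beta
        r, _ = pearsonr(v, fitted)
        assert fit.r_squared == pytest.approx(r ** 2, rel=1e-9)

    def test_constant_variable_flagged(self):
        coords = np.random.default_rng(2).normal(size=(10, 2))
        ordn = _ordination_from_coords(coords)
        g = _geochem_from(pd.DataFrame({"c": np.ones(10)}, index=ordn.sample_ids))
        [fit] = envfit(ordn, g, ["c"], n_perm=9, seed=0)
        assert not fit.defined and np.isnan(fit.r_squared)

    def test_p_values_on_permutation_lattice_and_reproducible(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(20, 2))
        ordn = _ordination_from_coords(coords)
        g = _geochem_from(pd.DataFrame({"v": rng.normal(size=20)},
                                       index=ordn.sample_ids))
        [a] = envfit(ordn, g, ["v"], n_perm=99, seed=5)
        [b] = envfit(ordn, g, ["v"], n_perm=99, seed=5)
        assert a.p_value == b.p_value
        assert round(a.p_value * 100) == pytest.approx(a.p_value * 100)


def _community(arr, normalized=True):
    arr = np.asarray(arr, dtype=float)
    return ASVTable(
        pd.DataFrame(arr.T, index=[f"A{i}" for i in range(arr.shape[1])],
                     columns=[f"s{i}" for i in range(arr.shape[0])]),
        normalized=normalized)


class TestRDA:
    def test_community_proportional_to_constraint_is_100_percent(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        Y = np.column_stack([2 * x, -0.5 * x])
        t = _community(Y + 10)                      # centering removes offset
        g = _geochem_from(pd.DataFrame({"x": x}, index=t.sample_ids))
        out = rda_contribution(t, g, ["x"], include_combined=False)
        assert out[0].percent == pytest.approx(100.0)

    def test_orthogonal_constraint_zero_percent(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])        # orthogonal to x
        t = _community(np.column_stack([y, 2 * y]) + 5)
        g = _geochem_from(pd.DataFrame({"x": x}, index=t.sample_ids))
        out = rda_contribution(t, g, ["x"], include_combined=False)
        assert out[0].percent == pytest.approx(0.0, abs=1e-10)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        Y = rng.random((8, 6)) * 10
        x = rng.normal(size=8)
        t = _community(Y)
        g1 = _geochem_from(pd.DataFrame({"x": x}, index=t.sample_ids))
        g2 = _geochem_from(pd.DataFrame({"x": 7.5 * x - 3.0}, index=t.sample_ids))
        a = rda_contribution(t, g1, ["x"], include_combined=False)[0].percent
        b = rda_contribution(t, g2, ["x"], include_combined=False)[0].percent
        assert a == pytest.approx(b, rel=1e-9)

    def test_collinear_constraints_rejected_with_names(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        t = _community(rng.random((10, 4)))
        g = _geochem_from(pd.DataFrame({"x": x, "x2": 2 * x},
                                       index=t.sample_ids))
        with pytest.raises(OrdinationError, match="collinear"):
            rda_contribution(t, g, ["x", "x2"])


class TestCCA:
    def _abundances(self, rng, n_per=10):
        # two groups drawing from disjoint taxon pools
        g1 = rng.integers(20, 60, size=(n_per, 5))
        g1 = np.hstack([g1, rng.integers(0, 3, size=(n_per, 5))])
        g2 = rng.integers(0, 3, size=(n_per, 5))
        g2 = np.hstack([g2, rng.integers(20, 60, size=(n_per, 5))])
        return np.vstack([g1, g2])

    def test_disjoint_pools_detected(self):
        rng = np.random.default_rng(6)
        t = _community(self._abundances(rng))
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=t.sample_ids)
        [axis1] = cca_group_test(t, labels, n_perm=199, seed=0)
        assert axis1.p_value <= 0.05
        assert axis1.eigenvalue > 0

    def test_axis_count_is_groups_minus_one(self):
        rng = np.random.default_rng(7)
        t = _community(rng.integers(1, 30, size=(18, 8)))
        labels = pd.Series(["above"] * 6 + ["at"] * 6 + ["below"] * 6,
                           index=t.sample_ids)
        axes = cca_group_test(t, labels, n_perm=49, seed=0)
        assert len(axes) == 2
        assert axes[0].eigenvalue >= axes[1].eigenvalue

    def test_single_group_rejected(self):
        rng = np.random.default_rng(8)
        t = _community(rng.integers(1, 30, size=(6, 4)))
        labels = pd.Series(["a"] * 6, index=t.sample_ids)
        with pytest.raises(OrdinationError):
            cca_group_test(t, labels, n_perm=9)

    def test_singleton_group_warns(self):
        rng = np.random.default_rng(9)
        t = _community(rng.integers(1, 30, size=(7, 4)))
        labels = pd.Series(["a"] * 6 + ["b"], index=t.sample_ids)
        with pytest.warns(UserWarning, match="single sample"):
            cca_group_test(t, labels, n_perm=9, seed=0)
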