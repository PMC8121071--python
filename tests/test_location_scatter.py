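import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mahaniche import (
    DegenerateSampleError,
    EstimatorConfig,
    InfeasibleSubsetError,
    InvalidParameterError,
    estimate_mcd,
    estimate_mve,
    estimate_sample,
    sample_idealised,
    subset_size,
)
from mahaniche.location_scatter import _concentrate, _mean_cov

RAW = dict(reweight=False, rescale=False)


class TestSubsetSize:
    @pytest.mark.parametrize("m, n, k, expected", [
        (10, 2, None, 6),       # standard maximally robust choice
        (160, 2, None, 81),
        (50, 2, 1.0, 50),       # full sample
        (10, 2, 0.55, 5),       # floor(k*m)
        (20, 2, 0.95, 19),      # float-representation guard (0.95*20)
        (100, 2, 0.55, 55),
    ])
    def test_values(self, m, n, k, expected):
        assert subset_size(m, n, k) == expected

    def test_clamped_to_feasible_range(self):
        assert subset_size(3, 2, 0.51) == 3  # floor = 1, clamped up to n+1

    def test_infeasible_sample_raises(self):
        with pytest.raises(InfeasibleSubsetError):
            subset_size(2, 2, None)

    @pytest.mark.parametrize("k", [0.5, 0.49, 1.01, 0.0])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(InvalidParameterError):
            subset_size(100, 2, k)

    @given(st.integers(3, 500), st.floats(0.501, 1.0))
    def test_always_within_bounds(self, m, k):
        h = subset_size(m, 2, k)
        assert 3 <= h <= m


class TestSampleEstimator:
    def test_hand_computed_square(self):
        X = [(0.0, 0.0), (2.0, 0.0), (0.0, 2.0), (2.0, 2.0)]
        ls = estimate_sample(X)
        np.testing.assert_allclose(ls.location, [1.0, 1.0])
        np.testing.assert_allclose(ls.scatter, [[4 / 3, 0.0], [0.0, 4 / 3]])
        assert ls.method == "sample" and ls.h is None

    def test_two_points_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            estimate_sample([(0.0, 0.0), (2.0, 2.0)])

    def test_collinear_points_degenerate(self):
        X = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
        with pytest.raises(DegenerateSampleError):
            estimate_sample(X)

    def test_recovers_location_within_three_se(self, params, rng):
        X = rng.multivariate_normal(params.mu, params.sigma, 1000)
        ls = estimate_sample(X)
        se = np.sqrt(np.diag(params.sigma) / 1000)
        assert np.all(np.abs(ls.location - params.mu) < 3 * se)

    def test_affine_equivariance(self, rng):
        X = rng.normal(size=(40, 2))
        A = np.array([[2.0, 1.0], [0.5, 3.0]])
        b = np.array([5.0, -7.0])
        ls = estimate_sample(X)
        ls_t = estimate_sample(X @ A.T + b)
        np.testing.assert_allclose(ls_t.location, A @ ls.location + b, atol=1e-8)
        np.testing.assert_allclose(ls_t.scatter, A @ ls.scatter @ A.T, atol=1e-8)


class TestMCD:
    def test_feasibility_floor(self, rng):
        X = rng.normal(size=(9, 2))
        with pytest.raises(InfeasibleSubsetError):
            estimate_mcd(X)

    def test_full_subset_equals_sample_estimator(self, rng):
        X = rng.normal(size=(30, 2))
        ls_s = estimate_sample(X)
        ls_m = estimate_mcd(X, EstimatorConfig(k=1.0, rescale=False))
        assert np.array_equal(ls_m.location, ls_s.location)
        np.testing.assert_allclose(ls_m.scatter, ls_s.scatter, atol=1e-10, rtol=0)

    def test_fast_mode_matches_exhaustive_oracle(self, cluster_with_two_outliers):
        X = cluster_with_two_outliers
        fast = estimate_mcd(X, EstimatorConfig(k=0.51, n_trials=500, seed=3, **RAW))
        exact = estimate_mcd(X, EstimatorConfig(k=0.51, exhaustive=True, **RAW))
        assert fast.h == exact.h == 7
        assert fast.objective == pytest.approx(exact.objective, rel=1e-12)
        assert np.array_equal(fast.retained_indices, exact.retained_indices)

    def test_outlier_excluded_from_retained_subset(self, cluster_with_one_outlier):
        ls = estimate_mcd(cluster_with_one_outlier, EstimatorConfig(seed=0))
        assert 20 not in ls.retained_indices

    def test_cstep_determinant_monotone(self, rng):
        X = rng.normal(size=(60, 2))
        X[:5] += 15.0
        loc, S = _mean_cov(X[rng.choice(60, size=3, replace=False)])
        trace = []
        _concentrate(X, 33, loc, S, max_csteps=50, det_trace=trace)
        assert len(trace) >= 2
        assert all(b <= a * (1 + 1e-12) for a, b in zip(trace, trace[1:]))

    def test_exhaustive_mode_cap(self, rng):
        X = rng.normal(size=(60, 2))
        with pytest.raises(Exception, match="cap"):
            estimate_mcd(X, EstimatorConfig(k=0.55, exhaustive=True))

    def test_affine_equivariance_exhaustive_raw(self, cluster_with_two_outliers):
        X = cluster_with_two_outliers
        A = np.array([[1.5, -0.3], [0.2, 0.8]])
        b = np.array([3.0, -2.0])
        cfg = EstimatorConfig(k=0.51, exhaustive=True, **RAW)
        ls = estimate_mcd(X, cfg)
        ls_t = estimate_mcd(X @ A.T + b, cfg)
        np.testing.assert_allclose(ls_t.location, A @ ls.location + b, atol=1e-8)
        np.testing.assert_allclose(ls_t.scatter, A @ ls.scatter @ A.T, atol=1e-8)
        assert np.array_equal(ls.retained_indices, ls_t.retained_indices)

    def test_robust_to_single_receding_outlier(self, rng):
        X = rng.normal(size=(30, 2))
        cfg = EstimatorConfig(k=0.8, seed=1)
        base_robust = estimate_mcd(X, cfg).location
        shifts_robust, shifts_sample = [], []
        for d in (1e3, 1e6):
            Xc = np.vstack([X, [[d, d]]])
            shifts_robust.append(
                np.linalg.norm(estimate_mcd(Xc, cfg).location - base_robust))
            shifts_sample.append(
                np.linalg.norm(estimate_sample(Xc).location - estimate_sample(X).location))
        assert max(shifts_robust) < 0.5
        # the sample location diverges linearly with the outlier distance
        assert shifts_sample[1] / shifts_sample[0] == pytest.approx(1e3, rel=1e-2)

    def test_matches_sklearn_raw_support(self, cluster_with_two_outliers):
        # independent cross-check against scikit-learn's FAST-MCD
        from sklearn.covariance import MinCovDet

        X = cluster_with_two_outliers
        ours = estimate_mcd(X, EstimatorConfig(exhaustive=True, **RAW))  # h=8
        skl = MinCovDet(support_fraction=8 / 14, random_state=0).fit(X)
        assert set(ours.retained_indices) == set(np.flatnonzero(skl.raw_support_))


class TestMVE:
    def test_full_subset_ellipsoid_contains_all_points(self, rng):
        X = rng.normal(size=(25, 2))
        ls = estimate_mve(X, EstimatorConfig(k=1.0, **RAW))
        dev = X - ls.location
        d2 = np.einsum("ij,jk,ik->i", dev, np.linalg.inv(ls.scatter), dev)
        assert np.all(d2 <= 1.0 + 1e-9)

    def test_exhaustive_objective_beats_independent_enumeration(
            self, cluster_with_two_outliers):
        # the oracle is the same elemental enumeration written separately
        X = cluster_with_two_outliers
        m, n = X.shape
        h = 7
        best = np.inf
        for comb in itertools.combinations(range(m), n + 1):
            sub = X[list(comb)]
            c = sub.mean(axis=0)
            C = (sub - c).T @ (sub - c) / n
            if np.linalg.det(C) <= 0:
                continue
            try:
                inv = np.linalg.inv(C)
            except np.linalg.LinAlgError:
                continue
            dev = X - c
            d2 = np.sort(np.einsum("ij,jk,ik->i", dev, inv, dev))
            obj = np.linalg.det(C) * d2[h - 1] ** n
            best = min(best, obj)
        ls = estimate_mve(X, EstimatorConfig(k=0.51, exhaustive=True, **RAW))
        assert ls.objective == pytest.approx(best, rel=1e-10)

    def test_fast_mode_matches_exhaustive(self, cluster_with_two_outliers):
        X = cluster_with_two_outliers
        fast = estimate_mve(X, EstimatorConfig(k=0.51, n_trials=500, seed=5, **RAW))
        exact = estimate_mve(X, EstimatorConfig(k=0.51, exhaustive=True, **RAW))
        assert fast.objective == pytest.approx(exact.objective, rel=1e-12)

    def test_outlier_outside_h_ellipsoid(self, cluster_with_one_outlier):
        X = cluster_with_one_outlier
        ls = estimate_mve(X, EstimatorConfig(seed=0, **RAW))
        cluster = X[:20]
        assert cluster[:, 0].min() <= ls.location[0] <= cluster[:, 0].max()
        assert cluster[:, 1].min() <= ls.location[1] <= cluster[:, 1].max()
        dev = X[20] - ls.location
        assert dev @ np.linalg.inv(ls.scatter) @ dev > 1.0
        assert 20 not in ls.retained_indices

    def test_works_below_mcd_floor(self, rng):
        # MVE only needs h >= n+1, not m >= 5n
        X = rng.normal(size=(6, 2))
        ls = estimate_mve(X, EstimatorConfig(seed=0, **RAW))
        assert ls.method == "mve"

    def test_affine_equivariance_exhaustive_raw(self, cluster_with_two_outliers):
        X = cluster_with_two_outliers
        A = np.array([[1.2, 0.4], [-0.1, 0.9]])
        b = np.array([-1.0, 4.0])
        cfg = EstimatorConfig(k=0.51, exhaustive=True, **RAW)
        ls = estimate_mve(X, cfg)
        ls_t = estimate_mve(X @ A.T + b, cfg)
        np.testing.assert_allclose(ls_t.location, A @ ls.location + b, atol=1e-8)
        np.testing.assert_allclose(ls_t.scatter, A @ ls.scatter @ A.T, atol=1e-7)


class TestConvergenceToClassical:
    def test_k_one_reproduces_sample_for_both_methods(self, params):
        X = sample_idealised(params, 50, seed=9).X
        ls_s = estimate_sample(X)
        ls_m = estimate_mcd(X, EstimatorConfig(k=1.0, rescale=False))
        np.testing.assert_allclose(ls_m.location, ls_s.location, rtol=0, atol=0)
        np.testing.assert_allclose(ls_m.scatter, ls_s.scatter, atol=1e-10)
        # MVE at k=1 covers everything: same centre of mass of retained set
        ls_v = estimate_mve(X, EstimatorConfig(k=1.0, **RAW))
        assert len(ls_v.retained_indices) == 50
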