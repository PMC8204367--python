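"""Battery reduction: deficit transform, z-scoring, PCA, varimax/PROMAX, scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.linalg import subspace_angles

from strokemap.behavior import (
    BatteryTable,
    PromaxPCA,
    component_scores,
    deficit_transform,
    fit_pca,
    ordered_correlation_matrix,
    orient_components,
    promax,
    tucker_congruence,
    varimax,
    zscore_columns,
)
from strokemap.behavior import _varimax_criterion
from strokemap.errors import ValidationError


def _battery(scores, maxima, names=None):
    scores = np.asarray(scores, float)
    names = names or [f"t{j}" for j in range(scores.shape[1])]
    return BatteryTable(
        subject_ids=[f"s{i}" for i in range(scores.shape[0])],
        subtest_names=names,
        scores=scores,
        maxima=np.asarray(maxima, float),
    )


class TestDeficitTransform:
    @pytest.mark.parametrize("score,maximum,expected", [(4, 4, 0.0), (0, 4, 1.0), (3, 4, 0.25)])
    def test_known_values(self, score, maximum, expected):
        b = _battery([[score, 1], [1, 1], [0, 1]], [maximum, 2])
        d = deficit_transform(b)
        assert d.iloc[0, 0] == pytest.approx(expected)

    def test_range_and_orientation(self, rng):
        maxima = np.array([4.0, 10.0, 3.0])
        scores = np.floor(rng.random((20, 3)) * (maxima + 1)).clip(max=maxima)
        d = deficit_transform(_battery(scores, maxima)).to_numpy()
        assert ((0 <= d) & (d <= 1)).all()

    def test_score_above_max_names_subject_and_subtest(self):
        b = _battery([[1, 1], [5, 1], [0, 1]], [4, 2], names=["naming", "gaze"])
        with pytest.raises(ValidationError, match="s1.*naming"):
            deficit_transform(b)

    def test_nonpositive_maximum_rejected(self):
        with pytest.raises(ValidationError, match="naming"):
            _battery([[1, 1]] * 3, [0, 2], names=["naming", "gaze"])


class TestZscore:
    def test_symmetric_column(self):
        dm = zscore_columns(np.array([[0.0], [0.5], [1.0]]))
        assert np.allclose(dm.values[:, 0], [-1, 0, 1])

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.zeros(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            dm = zscore_columns(X, names=["flat", "varies"])
        assert dm.dropped_columns == ["flat"]
        assert dm.subtest_names == ["varies"]

    def test_retained_columns_standardized(self, rng):
        dm = zscore_columns(rng.random((40, 6)))
        assert np.allclose(dm.values.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(dm.values.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_all_constant_errors(self):
        with pytest.raises(ValidationError):
            zscore_columns(np.ones((5, 3)))


def _svd_pca_oracle(Z):
    """Independent route: correlation-matrix PCA through the SVD of Z."""
    Zs = (Z - Z.mean(0)) / Z.std(0, ddof=1)
    n = Z.shape[0]
    _, s, Vt = np.linalg.svd(Zs, full_matrices=False)
    eigvals = s**2 / (n - 1)
    loadings = Vt.T * np.sqrt(eigvals)
    return loadings, eigvals


class TestFitPca:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=30)
        Z = zscore_columns(np.column_stack([x, 2 * x + 1])).values
        _, eigvals, var_prop, _ = fit_pca(Z, 1)
        assert var_prop[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle(self, rng):
        Z = zscore_columns(rng.normal(size=(20, 6))).values
        loadings, eigvals, _, scores = fit_pca(Z, 6)
        oracle_loadings, oracle_eigvals = _svd_pca_oracle(Z)
        assert np.allclose(eigvals, oracle_eigvals, atol=1e-8)
        for j in range(6):
            sign = np.sign(loadings[:, j] @ oracle_loadings[:, j])
            assert np.allclose(loadings[:, j], sign * oracle_loadings[:, j], atol=1e-8)

    def test_total_variance_conserved(self, rng):
        Z = zscore_columns(rng.normal(size=(25, 8))).values
        _, eigvals, _, _ = fit_pca(Z, 3)
        assert eigvals.sum() == pytest.approx(8.0, abs=1e-8)

    def test_k_beyond_rank_errors(self, rng):
        x = rng.normal(size=12)
        Z = zscore_columns(np.column_stack([x, -x, 2 * x])).values
        with pytest.raises(ValidationError):
            fit_pca(Z, 2)


def _varimax_angle_oracle(L, step_deg=0.01):
    """Grid search over planar rotation angle for 2-column loadings."""
    angles = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    c, s = np.cos(angles), np.sin(angles)
    x, y = L[:, 0], L[:, 1]
    Xr = np.outer(x, c) + np.outer(y, s)
    Yr = -np.outer(x, s) + np.outer(y, c)
    p = L.shape[0]
    crit = (
        (Xr**4).sum(0) - (Xr**2).sum(0) ** 2 / p
        + (Yr**4).sum(0) - (Yr**2).sum(0) ** 2 / p
    )
    return angles[np.argmax(crit)], crit.max()


class TestVarimax:
    def test_recovers_45_degree_mixture(self):
        simple = np.zeros((8, 2))
        simple[:4, 0] = [0.9, 0.8, 0.85, 0.7]
        simple[4:, 1] = [0.8, 0.75, 0.9, 0.6]
        theta = np.deg2rad(45.0)
        Q = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        mixed = simple @ Q
        rotated, _ = varimax(mixed, kaiser=False)
        # align columns/signs and compare to the original simple structure
        perm = np.argsort(-np.abs(rotated[0]))
        aligned = rotated[:, perm] * np.sign(rotated[:, perm].sum(0))
        assert np.allclose(aligned, simple, atol=1e-6)
        # the angle-grid oracle confirms the criterion optimum is attained
        _, best_crit = _varimax_angle_oracle(mixed)
        assert _varimax_criterion(rotated) >= best_crit - 1e-6

    def test_simple_structure_is_fixed_point(self):
        simple = np.zeros((6, 2))
        simple[:3, 0] = [0.9, 0.8, 0.7]
        simple[3:, 1] = [0.85, 0.75, 0.8]
        rotated, _ = varimax(simple, kaiser=False)
        assert np.allclose(np.abs(rotated), np.abs(simple), atol=1e-8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(np.float64, (7, 3), elements=st.floats(-1, 1, allow_nan=False)))
    def test_criterion_never_decreases(self, L):
        rotated, T = varimax(L, kaiser=False)
        assert _varimax_criterion(rotated) >= _varimax_criterion(L) - 1e-12
        assert np.allclose(T @ T.T, np.eye(3), atol=1e-10)
        assert np.allclose(L @ T, rotated, atol=1e-10)

    def test_k1_is_identity(self):
        L = np.arange(5.0)[:, None]
        rotated, T = varimax(L)
        assert np.allclose(rotated, L)
        assert T.shape == (1, 1) and T[0, 0] == 1.0


# Oracle values from R stats::promax (m = 4) on the fixed matrix below.
_R_PROMAX_INPUT = np.array(
    [
        [0.8243773664, -0.0831987285, 0.0600360957],
        [0.8252451773, -0.1560828151, -0.1041743605],
        [0.7102272323, -0.0252994074, -0.0013440926],
        [-0.0682435142, 0.8703518380, 0.0622233548],
        [0.0052824558, 0.7901792966, 0.0374007474],
        [-0.0687433970, 0.6795000627, -0.0767106081],
        [0.0702760241, -0.0039940729, 0.7352110109],
        [-0.0544743636, 0.0978033071, 0.6876376414],
    ]
)
_R_PROMAX_PATTERN = np.array(
    [
        [0.829072, 0.011602, 0.078529],
        [0.830514, -0.055458, -0.084237],
        [0.717931, 0.058789, 0.013488],
        [-0.027408, 0.866913, 0.041491],
        [0.043688, 0.795767, 0.019906],
        [-0.033863, 0.679797, -0.093360],
        [0.052216, -0.023950, 0.737608],
        [-0.067828, 0.065703, 0.685197],
    ]
)
_R_PROMAX_PHI = np.array(
    [
        [1.0, -0.166130, -0.003431],
        [-0.166130, 1.0, 0.057377],
        [-0.003431, 0.057377, 1.0],
    ]
)


class TestPromax:
    def test_matches_r_promax_oracle(self):
        vm, _ = varimax(_R_PROMAX_INPUT)
        pattern, _, phi = promax(vm, power=4)
        # columns already come out in the same order/sign for this input
        assert np.allclose(pattern, _R_PROMAX_PATTERN, atol=1e-3)
        assert np.allclose(phi, _R_PROMAX_PHI, atol=1e-3)

    def test_phi_unit_diagonal_exact(self, rng):
        L = rng.normal(scale=0.5, size=(10, 3))
        vm, _ = varimax(L)
        _, _, phi = promax(vm)
        assert np.allclose(np.diag(phi), 1.0, atol=1e-12)
        assert np.allclose(phi, phi.T)
        assert (np.abs(phi) <= 1 + 1e-12).all()

    def test_orthogonal_factor_data_gives_diagonal_phi(self, rng):
        n, p = 2000, 9
        F = rng.normal(size=(n, 3))
        L = np.zeros((p, 3))
        L[:3, 0], L[3:6, 1], L[6:, 2] = 0.8, 0.8, 0.8
        X = F @ L.T + 0.4 * rng.normal(size=(n, p))
        Z = zscore_columns(X).values
        loadings, _, _, _ = fit_pca(Z, 3)
        vm, _ = varimax(loadings)
        _, _, phi = promax(vm)
        off = phi[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_perfect_simple_structure_congruence(self):
        L = np.zeros((9, 3))
        L[:3, 0] = [0.9, 0.8, 0.7]
        L[3:6, 1] = [0.85, 0.8, 0.75]
        L[6:, 2] = [0.8, 0.7, 0.9]
        vm, _ = varimax(L)
        pattern, _, _ = promax(vm)
        for j in range(3):
            cong = max(abs(tucker_congruence(pattern[:, j], L[:, i])) for i in range(3))
            assert cong > 0.999

    def test_singular_loadings_error(self):
        L = np.zeros((6, 2))
        L[:, 0] = [1, 1, 1, 0, 0, 0]
        L[:, 1] = L[:, 0]  # identical columns -> singular X'X
        with pytest.raises(ValidationError, match="components"):
            promax(L)


class TestComponentScores:
    def test_mean_subject_scores_zero(self, rng):
        Z = zscore_columns(rng.normal(size=(50, 5))).values
        model = PromaxPCA(2).fit(Z)
        assert np.allclose(model.scores_.mean(axis=0), 0, atol=1e-10)

    def test_score_correlation_approximates_phi(self, rng):
        n = 2000
        F = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=n)
        L = np.zeros((8, 2))
        L[:4, 0], L[4:, 1] = 0.85, 0.85
        X = F @ L.T + 0.3 * rng.normal(size=(n, 8))
        model = PromaxPCA(2).fit(zscore_columns(X).values)
        emp = np.corrcoef(model.scores_.T)
        assert np.abs(emp[0, 1] - model.phi_[0, 1]) < 0.1

    def test_one_factor_noiseless_recovery(self, rng):
        f = rng.normal(size=300)
        X = np.outer(f, [0.9, 0.7, 0.8, 0.6])
        Z = zscore_columns(X).values
        model = PromaxPCA(1, rotate=False).fit(Z)
        assert abs(np.corrcoef(model.scores_[:, 0], f)[0, 1]) > 0.99


class TestOrientation:
    def test_all_negative_component_flipped(self):
        pattern = np.array([[-0.8, 0.1], [-0.7, 0.9], [-0.6, 0.8]])
        flips = orient_components(pattern)
        assert flips[0] == -1 and flips[1] == 1
        assert (pattern * flips).sum(axis=0)[0] > 0

    def test_involution(self):
        pattern = np.array([[-0.8, 0.2], [-0.5, 0.3]])
        flips = orient_components(pattern)
        assert np.allclose(orient_components(pattern * flips), 1.0)

    def test_high_scores_mean_worse_deficits(self, small_cohort):
        # after orientation, subjects with the top component scores should show
        # larger mean deficits on that component's highest-loading subtests
        from conftest import as_battery_table

        cfg, _, battery, _ = small_cohort
        bt = as_battery_table(cfg, battery)
        deficits = deficit_transform(bt)
        dm = zscore_columns(deficits)
        model = PromaxPCA(3).fit(dm.values)
        D = deficits[dm.subtest_names].to_numpy()
        for c in range(3):
            top_tests = np.argsort(-np.abs(model.pattern_[:, c]))[:3]
            s = model.scores_[:, c]
            hi, lo = s >= np.quantile(s, 0.8), s <= np.quantile(s, 0.2)
            assert D[hi][:, top_tests].mean() > D[lo][:, top_tests].mean()


class TestOrderedCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, rng):
        Z = zscore_columns(rng.normal(size=(40, 6))).values
        model = PromaxPCA(2).fit(Z)
        R, order = ordered_correlation_matrix(Z, model.pattern_)
        M = R.to_numpy()
        assert np.allclose(np.diag(M), 1.0)
        assert np.allclose(M, M.T)
        assert sorted(order.tolist()) == list(range(6))

    def test_duplicate_columns_fully_correlated(self, rng):
        x = rng.normal(size=30)
        Z = zscore_columns(np.column_stack([x, x.copy(), rng.normal(size=30)])).values
        model = PromaxPCA(2).fit(Z)
        R, _ = ordered_correlation_matrix(Z, model.pattern_)
        assert R.to_numpy().max() == pytest.approx(1.0)
        off = R.to_numpy() - np.eye(3)
        assert off.max() == pytest.approx(1.0, abs=1e-10)

    def test_ordering_groups_planted_blocks(self, small_cohort):
        from conftest import as_battery_table

        cfg, _, battery, _ = small_cohort
        bt = as_battery_table(cfg, battery)
        dm = zscore_columns(deficit_transform(bt))
        model = PromaxPCA(3).fit(dm.values)
        _, order = ordered_correlation_matrix(dm.values, model.pattern_)
        assign = np.argmax(np.abs(model.pattern_), axis=1)[order]
        # dominant-component labels must be contiguous along the ordering
        changes = (np.diff(assign) != 0).sum()
        assert changes == len(np.unique(assign)) - 1


class TestPromaxPCAEstimator:
    def test_sklearn_protocol(self, rng):
        from sklearn.base import clone

        est = PromaxPCA(n_components=2, power=3)
        params = est.get_params()
        assert params["n_components"] == 2 and params["power"] == 3
        cloned = clone(est)
        Z = zscore_columns(rng.normal(size=(30, 5))).values
        cloned.fit(Z)
        assert cloned.scores_.shape == (30, 2)
        assert cloned.transform(Z).shape == (30, 2)
        assert np.allclose(cloned.transform(Z), cloned.scores_)

    def test_pattern_spans_unrotated_subspace(self, rng):
        Z = zscore_columns(rng.normal(size=(60, 8))).values
        model = PromaxPCA(3).fit(Z)
        angles = subspace_angles(model.unrotated_loadings_, model.pattern_)
        assert np.max(angles) < 1e-6

    def test_variance_proportions_sum_below_one(self, rng):
        Z = zscore_columns(rng.normal(size=(40, 7))).values
        model = PromaxPCA(3).fit(Z)
        assert 0 < model.variance_explained_.sum() <= 1.0 + 1e-12
        assert (np.diff(model.eigenvalues_all_) <= 1e-10).all()
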