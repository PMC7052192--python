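"""Ridge fitting, regularization selection, accuracy and significance."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from cogspace.encoding import (
    DEFAULT_LAMBDAS,
    RidgeConfig,
    WeightTensor,
    compare_models_wilcoxon,
    cv_select,
    fdr_bh,
    gaussian_null,
    pearson_columns,
    predict_and_score,
    resample_group_lambda,
    ridge_fit,
)


# ---------------------------------------------------------------------------
# ridge_fit
# ---------------------------------------------------------------------------


def test_scalar_ridge_closed_form():
    F = np.array([[1.0], [2.0]])
    R = np.array([[2.0], [4.0]])
    wt = ridge_fit(F, R, lam=5.0)
    # w = x'y / (x'x + lam) = 10 / 10 = 1
    assert wt.values.squeeze() == pytest.approx(1.0)


def test_lambda_grid_default():
    cfg = RidgeConfig()
    assert len(cfg.lambdas) == 18
    assert cfg.lambdas[0] == 100.0
    assert cfg.lambdas[-1] == 100.0 * 2**17
    assert all(b > a for a, b in zip(cfg.lambdas, cfg.lambdas[1:]))


def test_zero_lambda_square_system_inverts(rng):
    F = rng.standard_normal((4, 4))
    R = rng.standard_normal((4, 2))
    wt = ridge_fit(F, R, lam=0.0)
    np.testing.assert_allclose(
        wt.values.reshape(4, 2), np.linalg.solve(F, R), atol=1e-8
    )


def test_ridge_matches_normal_equations_oracle(rng):
    for T, N, V in [(50, 10, 5), (20, 7, 3), (12, 4, 1)]:
        F = rng.standard_normal((T, N))
        R = rng.standard_normal((T, V))
        for lam in (100.0, 100.0 * 2**9):
            wt = ridge_fit(F, R, lam=lam)
            oracle = np.linalg.solve(F.T @ F + lam * np.eye(N), F.T @ R)
            err = np.linalg.norm(wt.values.reshape(N, V) - oracle)
            assert err / np.linalg.norm(oracle) < 1e-8


def test_weight_norm_monotone_in_lambda(rng):
    F = rng.standard_normal((30, 6))
    R = rng.standard_normal((30, 4))
    norms = [
        np.linalg.norm(ridge_fit(F, R, lam=lam).values)
        for lam in DEFAULT_LAMBDAS
    ]
    assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))


def test_non_finite_inputs_raise():
    with pytest.raises(ValueError, match="finite"):
        ridge_fit(np.array([[np.nan], [1.0]]), np.ones((2, 1)), lam=1.0)


# ---------------------------------------------------------------------------
# cv_select
# ---------------------------------------------------------------------------


def test_cv_picks_smallest_lambda_on_noise_free_data(rng):
    F = rng.standard_normal((120, 5))
    W0 = rng.standard_normal((5, 8))
    lam, curve = cv_select(F, F @ W0)
    assert lam == DEFAULT_LAMBDAS[0]
    assert curve.shape == (18,)


def test_cv_accuracy_near_zero_for_pure_noise(rng):
    T, V = 200, 30
    F = rng.standard_normal((T, 4))
    R = rng.standard_normal((T, V))
    cfg = RidgeConfig()
    # independent oracle: per-fold held-out accuracy via direct normal equations
    folds = np.array_split(np.arange(T), cfg.cv_folds)
    accs = np.zeros((cfg.cv_folds, 18))
    for i, held in enumerate(folds):
        train = np.setdiff1d(np.arange(T), held)
        for j, lam in enumerate(cfg.lambdas):
            W = np.linalg.solve(
                F[train].T @ F[train] + lam * np.eye(4), F[train].T @ R[train]
            )
            accs[i, j] = np.nanmean(pearson_columns(F[held] @ W, R[held]))
    se = accs.std(axis=0, ddof=1) / np.sqrt(cfg.cv_folds)
    _lam, curve = cv_select(F, R, cfg)
    np.testing.assert_allclose(curve, accs.mean(axis=0), atol=1e-10)
    assert np.all(np.abs(curve) < 3 * np.maximum(se, 0.02))


def test_cv_selection_is_deterministic(rng):
    F = rng.standard_normal((60, 3))
    R = rng.standard_normal((60, 5))
    lam1, curve1 = cv_select(F, R)
    lam2, curve2 = cv_select(F, R)
    assert lam1 == lam2
    np.testing.assert_array_equal(curve1, curve2)


# ---------------------------------------------------------------------------
# resample_group_lambda
# ---------------------------------------------------------------------------


def test_group_lambda_smallest_on_noise_free_data(rng):
    F = rng.standard_normal((80, 4))
    W0 = rng.standard_normal((4, 6))
    data = [(F, F @ W0), (F, F @ W0)]
    lam, curve = resample_group_lambda(data, n_rep=5, seed=1)
    assert lam == DEFAULT_LAMBDAS[0]
    assert lam == DEFAULT_LAMBDAS[int(np.argmax(curve))]


def test_group_lambda_tracks_unimodal_curve(rng):
    # heteroscedastic features with strong noise: validation accuracy peaks
    # at an interior lambda of the grid
    T, N, V = 200, 20, 30
    scales = np.geomspace(0.5, 8, N)
    F = rng.standard_normal((T, N)) * scales
    W0 = rng.standard_normal((N, V))
    R = F @ W0 + 30.0 * rng.standard_normal((T, V))
    lam, curve = resample_group_lambda([(F, R)], n_rep=8, seed=2)
    peak = int(np.argmax(curve))
    assert lam == DEFAULT_LAMBDAS[peak]
    assert 0 < peak < len(DEFAULT_LAMBDAS) - 1
    # unimodal around the peak
    assert np.all(np.diff(curve[:peak + 1]) >= -1e-12) or peak <= 1
    assert np.all(np.diff(curve[peak:]) <= 1e-12)


# ---------------------------------------------------------------------------
# predict_and_score
# ---------------------------------------------------------------------------


def _wt(W, names=None):
    N, V = W.shape
    return WeightTensor(
        values=W.reshape(1, N, V),
        feature_names=names or [f"f{i}" for i in range(N)],
        chosen_lambda=0.0,
        delays_s=(0.0,),
    )


def test_exact_prediction_gives_unit_correlation(rng):
    F = rng.standard_normal((50, 3))
    W = rng.standard_normal((3, 6))
    acc = predict_and_score(_wt(W), F, F @ W)
    np.testing.assert_allclose(acc.r, 1.0, atol=1e-12)
    assert acc.significant.all()


def test_null_voxels_rarely_reach_significance(rng):
    T, V = 412, 500
    F = rng.standard_normal((T, 4))
    W = rng.standard_normal((4, V))
    R_null = rng.standard_normal((T, V))  # independent of the prediction
    acc = predict_and_score(_wt(W), F, R_null)
    assert acc.significant.mean() <= 0.05


def test_constant_prediction_flagged(rng):
    F = np.ones((20, 1))
    W = np.ones((1, 2))
    R = rng.standard_normal((20, 2))
    acc = predict_and_score(_wt(W), F, R)
    assert np.isnan(acc.r).all()
    assert acc.invalid.all()


# ---------------------------------------------------------------------------
# gaussian_null
# ---------------------------------------------------------------------------


def test_gaussian_null_symmetry_and_extremes():
    assert gaussian_null(0.0, 412) == pytest.approx(0.5)
    assert gaussian_null(1.0, 412) < 1e-12
    assert gaussian_null(-1.0, 412) > 1 - 1e-12
    with pytest.raises(ValueError):
        gaussian_null(0.3, 3)


def test_analytic_and_montecarlo_agree_at_test_length():
    rs = np.array([0.05, 0.0846, 0.12, 0.2])
    p_an = gaussian_null(rs, 412, method="analytic")
    p_mc = gaussian_null(rs, 412, method="montecarlo", n_sim=100_000, seed=4)
    np.testing.assert_allclose(p_an, p_mc, atol=5e-3)  # 2-decimal agreement
    # the p = 0.05 threshold correlation agrees between both methods
    r_grid = np.linspace(0.05, 0.12, 200)
    thr_an = r_grid[np.searchsorted(-gaussian_null(r_grid, 412), -0.05)]
    p_mc_grid = gaussian_null(r_grid, 412, method="montecarlo", seed=4)
    thr_mc = r_grid[np.searchsorted(-p_mc_grid, -0.05)]
    assert abs(thr_an - thr_mc) < 0.005


# ---------------------------------------------------------------------------
# fdr_bh
# ---------------------------------------------------------------------------


def test_bh_step_up_hand_example():
    # sorted p_i <= i*q/m holds for all four: every hypothesis rejected
    reject, thr = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert reject.all()
    assert thr == pytest.approx(0.04)


def test_bh_no_rejections_when_p_is_one():
    reject, thr = fdr_bh([1.0, 1.0, 1.0], q=0.05)
    assert not reject.any()
    assert thr == 0.0


def test_bh_single_small_p_rejected():
    reject, _ = fdr_bh([0.04], q=0.05)
    assert reject.all()


# ---------------------------------------------------------------------------
# compare_models_wilcoxon
# ---------------------------------------------------------------------------


def test_wilcoxon_uniform_advantage_is_significant(rng):
    b = rng.standard_normal(1000) * 0.1
    a = b + 0.01
    assert compare_models_wilcoxon(a, b) < 0.001


def test_wilcoxon_all_ties_undefined():
    x = np.ones(10)
    assert np.isnan(compare_models_wilcoxon(x, x))


def test_wilcoxon_matches_brute_force_enumeration(rng):
    """Exact signed-rank null by enumerating all sign assignments (n=10)."""
    a = rng.standard_normal(10)
    b = a + rng.standard_normal(10) * 0.5
    d = a - b
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array(
        [
            ranks[np.array(signs, dtype=bool)].sum()
            for signs in itertools.product([0, 1], repeat=10)
        ]
    )
    p_brute = np.mean(w_all >= w_obs)
    p_ours = compare_models_wilcoxon(a, b)
    assert p_ours == pytest.approx(p_brute, abs=1e-12)
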