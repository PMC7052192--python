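"""Regularized voxel-wise model fitting, prediction and significance.

The encoding model is ``R_hat = F W`` with ``F`` the FIR-embedded feature
matrix ``[T x 3N]`` and ``W`` the weight matrix ``[3N x V]``, estimated by
L2-regularized (ridge) regression.  The regularization parameter is chosen
from an 18-value grid (100 * 2^k, k = 0..17) by 10-fold cross-validation on
contiguous time blocks, prediction accuracy is the per-voxel Pearson
correlation on the repeat-averaged test data, and significance comes from
the exact null distribution of the sample correlation of two independent
Gaussian vectors, FDR-corrected (Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import DelayedFeatureMatrix, FeatureMatrix
from .preprocess import ResponseMatrix

#: default regularization grid: 100 * 2^k for k = 0..17
DEFAULT_LAMBDAS = tuple(100.0 * 2.0**k for k in range(18))


@dataclass
class RidgeConfig:
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        lams = tuple(float(x) for x in self.lambdas)
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise ValueError("lambdas must be strictly increasing")
        if any(x < 0 for x in lams):
            raise ValueError("lambdas must be non-negative")
        if self.cv_folds < 2:
            raise ValueError("need at least two CV folds")
        self.lambdas = lams


@dataclass
class WeightTensor:
    """Delay-major view of the ridge weights: ``values[d, j, v]``.

    ``intercept`` holds the per-voxel baseline when the model was fit with
    an (unpenalized) intercept; zero otherwise.
    """

    values: np.ndarray  # [n_delays, N, V]
    feature_names: list[str]
    chosen_lambda: float
    delays_s: tuple[float, ...] = (2.0, 4.0, 6.0)
    intercept: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("weights must be [n_delays, N, V]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("weights must be finite")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]

    @property
    def flat(self) -> np.ndarray:
        """``[n_delays * N, V]`` stacking matching the delay-embedded columns."""
        d, n, v = self.values.shape
        return self.values.reshape(d * n, v)

    @property
    def delay_averaged(self) -> np.ndarray:
        """``[N, V]`` mean over the delay axis."""
        return self.values.mean(axis=0)


@dataclass
class AccuracyMap:
    """Per-voxel prediction accuracy with significance flags."""

    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    n_samples: int
    fdr_q: float = 0.05
    threshold_r: float = float("nan")
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        finite = np.isfinite(self.r)
        if np.any(np.abs(self.r[finite]) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Numerics
# ---------------------------------------------------------------------------


def pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between matching columns of ``A`` and ``B``.

    Columns with zero variance yield NaN.
    """
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    na = np.sqrt((A * A).sum(axis=0))
    nb = np.sqrt((B * B).sum(axis=0))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=0) / denom
    r = np.where(denom > 0, r, np.nan)
    return np.clip(r, -1.0, 1.0)


def _svd_ridge_path(F: np.ndarray, R: np.ndarray):
    """Factor ``F`` once; return a solver ``W(lam)`` reusable across lambdas."""
    U, s, Vt = np.linalg.svd(F, full_matrices=False)
    UtR = U.T @ R
    tol = (s.max() if s.size else 0.0) * max(F.shape) * np.finfo(float).eps

    def solve(lam: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(s > tol, s / (s * s + lam), 0.0)
        return Vt.T @ (d[:, None] * UtR)

    return solve


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _as_response(R) -> np.ndarray:
    """Responses as a time-by-voxel array."""
    if isinstance(R, ResponseMatrix):
        return R.values.T
    return np.asarray(R, dtype=float)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def cv_select(
    F, R, config: RidgeConfig | None = None
) -> tuple[float, np.ndarray]:
    """Choose the regularization parameter by blocked cross-validation.

    Folds are contiguous sample blocks (respecting serial correlation).  For
    every lambda the held-out per-voxel Pearson accuracy is averaged over
    voxels and folds; the lambda maximizing the mean accuracy wins, ties
    going to the smaller value.

    Returns the chosen lambda and the per-lambda mean CV accuracy curve.
    """
    config = config or RidgeConfig()
    Fv, Rv = _as_matrix(F), _as_response(R)
    T = Fv.shape[0]
    if T < config.cv_folds:
        raise ValueError(f"T={T} smaller than {config.cv_folds} folds")
    folds = np.array_split(np.arange(T), config.cv_folds)
    acc = np.zeros((config.cv_folds, len(config.lambdas)))
    for i, held in enumerate(folds):
        if held.size < 2:
            raise ValueError(f"fold {i} has fewer than two samples")
        train = np.setdiff1d(np.arange(T), held)
        solve = _svd_ridge_path(Fv[train], Rv[train])
        for j, lam in enumerate(config.lambdas):
            pred = Fv[held] @ solve(lam)
            r = pearson_columns(pred, Rv[held])
            acc[i, j] = np.nanmean(r)
    curve = acc.mean(axis=0)
    return float(config.lambdas[int(np.argmax(curve))]), curve


def ridge_fit(
    F,
    R,
    config: RidgeConfig | None = None,
    lam: float | None = None,
    fit_intercept: bool = False,
) -> WeightTensor:
    """Fit ``W = argmin ||R - F W||^2 + lam ||W||^2``.

    When ``lam`` is not given it is chosen by :func:`cv_select` over the
    config grid.  The solution matches the closed form
    ``(F'F + lam I)^{-1} F' R`` (computed via SVD for stability).

    With ``fit_intercept=True`` an unpenalized per-voxel baseline is fit by
    centering features and responses over the training samples; predictions
    then add it back.  The baseline absorbs the offset that detrending and
    z-scoring leave in task-free bins (task features are all-zero there).
    """
    config = config or RidgeConfig()
    Fv, Rv = _as_matrix(F), _as_response(R)
    if not (np.all(np.isfinite(Fv)) and np.all(np.isfinite(Rv))):
        raise ValueError("non-finite values in features or responses")
    if Fv.shape[0] != Rv.shape[0]:
        raise ValueError(
            f"feature samples ({Fv.shape[0]}) != response samples "
            f"({Rv.shape[0]})"
        )
    if lam is None:
        lam, _ = cv_select(Fv, Rv, config)
    intercept = None
    if fit_intercept:
        f_mean = Fv.mean(axis=0)
        r_mean = Rv.mean(axis=0)
        W = _svd_ridge_path(Fv - f_mean, Rv - r_mean)(lam)
        intercept = r_mean - f_mean @ W
    else:
        W = _svd_ridge_path(Fv, Rv)(lam)
    if isinstance(F, DelayedFeatureMatrix):
        n_delays, names, delays = F.n_delays, F.parent_names, F.delays_s
    else:
        n_delays = 1
        names = list(F.feature_names) if isinstance(F, FeatureMatrix) else [
            f"f{i}" for i in range(Fv.shape[1])
        ]
        delays = (0.0,)
    N = W.shape[0] // n_delays
    return WeightTensor(
        values=W.reshape(n_delays, N, W.shape[1]),
        feature_names=list(names),
        chosen_lambda=float(lam),
        delays_s=tuple(delays),
        intercept=intercept,
    )


def resample_group_lambda(
    subject_data: list[tuple],
    config: RidgeConfig | None = None,
    n_rep: int = 50,
    holdout: float = 0.2,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """One regularization parameter shared by all subjects for group analyses.

    For each subject and repetition the training samples are randomly split
    into 80% training / 20% validation; validation accuracies are computed
    for every lambda, averaged over repetitions and subjects, and the
    argmax lambda is returned together with the mean accuracy curve.
    """
    config = config or RidgeConfig()
    if not subject_data:
        raise ValueError("no subjects")
    rng = np.random.default_rng(seed)
    curves = np.zeros((len(subject_data), len(config.lambdas)))
    for s, (F, R) in enumerate(subject_data):
        Fv, Rv = _as_matrix(F), _as_response(R)
        T = Fv.shape[0]
        n_val = max(int(round(holdout * T)), 1)
        acc = np.zeros((n_rep, len(config.lambdas)))
        for rep in range(n_rep):
            perm = rng.permutation(T)
            val, train = perm[:n_val], perm[n_val:]
            solve = _svd_ridge_path(Fv[train], Rv[train])
            for j, lam in enumerate(config.lambdas):
                r = pearson_columns(Fv[val] @ solve(lam), Rv[val])
                acc[rep, j] = np.nanmean(r)
        curves[s] = acc.mean(axis=0)
    curve = curves.mean(axis=0)
    return float(config.lambdas[int(np.argmax(curve))]), curve


# ---------------------------------------------------------------------------
# Scoring and significance
# ---------------------------------------------------------------------------


def gaussian_null(
    r,
    n: int,
    method: str = "analytic",
    n_sim: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """One-sided p-value(s) of observed correlation(s) under the Gaussian null.

    The null is the distribution of the sample Pearson correlation between
    two independent Gaussian vectors of length ``n``.  ``analytic`` uses the
    exact form (``r * sqrt((n-2)/(1-r^2))`` is Student-t with ``n-2`` df);
    ``montecarlo`` simulates ``n_sim`` independent pairs.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if method == "analytic":
        rc = np.clip(r_arr, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rc * np.sqrt((n - 2) / np.maximum(1.0 - rc * rc, 1e-300))
        p = stats.t.sf(t, df=n - 2)
        p = np.where(np.isfinite(r_arr), p, np.nan)
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        null = np.empty(n_sim)
        chunk = max(1, 10_000_000 // (2 * n))
        done = 0
        while done < n_sim:
            m = min(chunk, n_sim - done)
            x = rng.standard_normal((m, n))
            y = rng.standard_normal((m, n))
            x -= x.mean(axis=1, keepdims=True)
            y -= y.mean(axis=1, keepdims=True)
            num = (x * y).sum(axis=1)
            den = np.sqrt((x * x).sum(axis=1) * (y * y).sum(axis=1))
            null[done : done + m] = num / den
            done += m
        null.sort()
        idx = np.searchsorted(null, r_arr, side="left")
        p = (n_sim - idx) / n_sim
        p = np.where(np.isfinite(r_arr), p, np.nan)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p if np.ndim(r) else float(p[0])


def fdr_bh(p, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level ``q``.

    Returns the rejection flags and the largest rejected p-value (0 when
    nothing is rejected).  NaN p-values are never rejected.
    """
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    ok = np.isfinite(p_arr)
    reject = np.zeros(p_arr.shape, dtype=bool)
    if ok.any():
        rej, _, _, _ = multipletests(p_arr[ok], alpha=q, method="fdr_bh")
        reject[ok] = rej
    threshold = float(p_arr[reject].max()) if reject.any() else 0.0
    return reject, threshold


def predict_and_score(
    W: WeightTensor,
    F_test,
    R_test,
    drop_blocks: list[str] | None = None,
    q: float = 0.05,
) -> AccuracyMap:
    """Predict the test responses and score each voxel.

    ``drop_blocks`` removes nuisance feature blocks and the matching weight
    rows symmetrically before prediction (nuisance regressors are used in
    training only).  Accuracy is the per-voxel Pearson correlation on the
    repeat-averaged test data; one-sided p-values come from the analytic
    Gaussian null and significance from BH-FDR at level ``q``.
    """
    Fv = _as_matrix(F_test)
    Rv = _as_response(R_test)
    Wf = W.flat
    if drop_blocks:
        if not isinstance(F_test, (FeatureMatrix, DelayedFeatureMatrix)):
            raise ValueError("drop_blocks requires block provenance")
        drop_cols = np.concatenate(
            [F_test.block_columns(b) for b in drop_blocks]
        )
        keep = np.setdiff1d(np.arange(Fv.shape[1]), drop_cols)
        Fv = Fv[:, keep]
        Wf = Wf[keep]
    if Fv.shape[1] != Wf.shape[0]:
        raise ValueError(
            f"feature count {Fv.shape[1]} != weight rows {Wf.shape[0]}"
        )
    pred = Fv @ Wf
    if W.intercept is not None:
        pred = pred + W.intercept
    r = pearson_columns(pred, Rv)
    invalid = ~np.isfinite(r)
    n = Rv.shape[0]
    p = gaussian_null(r, n)
    sig, _p_thr = fdr_bh(p, q)
    sig_r = r[sig & np.isfinite(r)]
    return AccuracyMap(
        r=r,
        p=p,
        significant=sig,
        n_samples=n,
        fdr_q=q,
        threshold_r=float(sig_r.min()) if sig_r.size else float("nan"),
        invalid=invalid,
    )


def compare_models_wilcoxon(acc_a: np.ndarray, acc_b: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank test of paired per-voxel accuracies.

    Tests the alternative that model A's accuracies exceed model B's.
    Returns NaN when every pair is tied (the statistic is undefined).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired accuracies must have equal shape")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    if d.size == 0 or np.all(d == 0):
        return float("nan")
    return float(stats.wilcoxon(a[ok], b[ok], alternative="greater").pvalue)
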