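"""Novel-task encoding and decoding through the cognitive-factor space.

The tasks are split into five balanced groups.  For each group the model is
trained on the other groups only, excluding every time point during which a
target task was performed plus a 6-s window after it; at test time exactly
those time points are used.  Encoding predicts held-out responses through
the CTF; decoding inverts the delayed responses into the factor space,
scores each candidate task by the "task likelihood" (per-time-point
correlation between the decoded factor vector and the task's CTF row), and
evaluates one-vs-one classification accuracy against every other task.
Element-wise shuffle nulls quantify chance performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import features
from .design import ExperimentDesign
from .encoding import (
    AccuracyMap,
    RidgeConfig,
    WeightTensor,
    fdr_bh,
    gaussian_null,
    pearson_columns,
    ridge_fit,
)
from .metadata import TransformMatrix, rowwise_correlation
from .preprocess import ResponseMatrix

#: post-trial exclusion window, seconds
EXCLUSION_WINDOW_S = 6.0


# ---------------------------------------------------------------------------
# Task splitting and temporal exclusion
# ---------------------------------------------------------------------------


@dataclass
class TaskSplit:
    """Balanced random partition of the tasks into groups."""

    group_of_task: np.ndarray
    n_groups: int
    seed: int

    def tasks_of(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.group_of_task == group)


def split_tasks(n_tasks: int, n_groups: int = 5, seed: int = 0) -> TaskSplit:
    """Uniformly random partition with group sizes differing by at most one."""
    if n_groups > n_tasks:
        raise ValueError("more groups than tasks")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_tasks)
    group_of = np.empty(n_tasks, dtype=np.int64)
    base, rem = divmod(n_tasks, n_groups)
    start = 0
    for g in range(n_groups):
        size = base + (1 if g < rem else 0)
        group_of[perm[start : start + size]] = g
        start += size
    return TaskSplit(group_of, n_groups, seed)


def _target_window_mask(
    timeline: np.ndarray,
    run_slices: list[tuple[int, int]],
    target_tasks: np.ndarray,
    window_bins: int,
) -> np.ndarray:
    """Bins occupied by a target task or within the window after one,
    truncated at run boundaries."""
    occupied = np.isin(timeline, target_tasks)
    mask = occupied.copy()
    for r0, r1 in run_slices:
        seg = occupied[r0:r1]
        for t in np.flatnonzero(seg):
            mask[r0 + t : min(r0 + t + 1 + window_bins, r1)] = True
    return mask


def exclusion_masks(
    design: ExperimentDesign,
    target_tasks: np.ndarray,
    window_s: float = EXCLUSION_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Training and test sample masks for a target task group.

    The train mask (over the training-run timeline) is the complement of the
    target-task bins and the ``window_s`` window after each occurrence; the
    test mask (over the test block timeline) is exactly that union.
    """
    k = window_s / design.tr
    if abs(k - round(k)) > 1e-9:
        raise ValueError("window_s must be a multiple of tr")
    wb = int(round(k))
    targets = np.asarray(target_tasks)
    train_excl = _target_window_mask(
        design.timeline("train"), design.portion_slices("train"), targets, wb
    )
    train_mask = ~train_excl
    if not train_mask.any():
        raise ValueError("exclusion leaves no training samples")
    test_mask = _target_window_mask(
        design.timeline("test_block"),
        design.portion_slices("test_block"),
        targets,
        wb,
    )
    return train_mask, test_mask


def per_task_test_masks(
    design: ExperimentDesign, window_s: float = EXCLUSION_WINDOW_S
) -> dict[int, np.ndarray]:
    """Test-block mask of each task: its bins plus the post-task window."""
    wb = int(round(window_s / design.tr))
    block = design.timeline("test_block")
    slices = design.portion_slices("test_block")
    return {
        k: _target_window_mask(block, slices, np.array([k]), wb)
        for k in range(design.n_tasks)
        if np.any(block == k)
    }


# ---------------------------------------------------------------------------
# Decoder fitting
# ---------------------------------------------------------------------------


@dataclass
class DecoderWeights:
    """Ridge weights mapping delayed responses to features, ``[3V x N]``."""

    values: np.ndarray
    chosen_lambda: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("decoder weights must be finite")


def delayed_responses(
    r: ResponseMatrix, delays_s: tuple[float, ...] = features.DEFAULT_DELAYS_S
) -> features.DelayedFeatureMatrix:
    """FIR-embed the responses themselves (decoding input, ``[T x 3V]``).

    The hemodynamic response lags the feature it encodes, so the decoder
    reads the feature at time ``t`` from the responses 2-6 s *after* ``t``:
    the delay blocks here shift the responses backward in time (within
    runs, zero-padded at run ends).
    """
    fm = features.FeatureMatrix(
        values=r.values.T,
        feature_names=[f"voxel{v}" for v in range(r.n_voxels)],
        tr=r.tr,
        run_slices=list(r.run_slices),
    )
    return features.delay_embed(fm, tuple(-d for d in delays_s))


def decode_fit(
    R_delayed,
    F_target,
    config: RidgeConfig | None = None,
    lam: float | None = None,
) -> DecoderWeights:
    """Fit the decoding model ``F_hat = R_delayed W_D``.

    The fit follows the same procedure as the encoding model with the roles
    of features and responses swapped: L2-regularized regression with the
    regularization parameter chosen by blocked 10-fold cross-validation.
    """
    wt = ridge_fit(R_delayed, F_target, config=config, lam=lam)
    return DecoderWeights(values=wt.flat, chosen_lambda=wt.chosen_lambda)


# ---------------------------------------------------------------------------
# Task likelihood and one-vs-one accuracy
# ---------------------------------------------------------------------------


@dataclass
class DecodingResult:
    """Per-task one-vs-one accuracy with sign-test significance."""

    task_ids: np.ndarray
    accuracy: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    n_comparisons: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.accuracy))


def likelihood_matrix(
    decoded: np.ndarray, ctf: TransformMatrix
) -> tuple[np.ndarray, int]:
    """Per-time-point correlation of decoded factor vectors with CTF rows.

    Returns the ``[T x n_tasks]`` likelihood matrix and the number of time
    points excluded because the decoded vector was constant (undefined
    correlation).
    """
    L = rowwise_correlation(decoded, ctf.values)
    bad = ~np.isfinite(L).all(axis=1)
    return L, int(bad.sum())


def task_likelihood(
    decoded: np.ndarray,
    ctf: TransformMatrix,
    sample_masks: dict[int, np.ndarray],
) -> np.ndarray:
    """Time-averaged task likelihoods, one row per target task.

    For each target task, the likelihood of every candidate task is the mean
    over the target's test-mask time points of the per-time-point
    correlations.  Rows are ordered by sorted target task id; undefined
    time points are excluded from the mean.
    """
    L, _n_bad = likelihood_matrix(decoded, ctf)
    targets = sorted(sample_masks)
    out = np.full((len(targets), ctf.n_tasks), np.nan)
    for i, k in enumerate(targets):
        rows = L[sample_masks[k]]
        if rows.size:
            out[i] = np.nanmean(rows, axis=0)
    return out


def one_vs_one(
    likelihoods: np.ndarray,
    task_ids: np.ndarray | None = None,
    q: float = 0.05,
) -> DecodingResult:
    """Binary classification of each target task against every other task.

    The accuracy is the fraction of candidate tasks with strictly lower
    likelihood than the target's own (ties count 0.5).  A one-sided sign
    test per task (ties excluded) tests accuracy above chance, with BH-FDR
    across tasks.
    """
    L = np.asarray(likelihoods, dtype=float)
    n_targets, n_tasks = L.shape
    ids = (
        np.arange(n_targets) if task_ids is None else np.asarray(task_ids)
    )
    acc = np.full(n_targets, np.nan)
    p = np.full(n_targets, np.nan)
    for i, k in enumerate(ids):
        own = L[i, k]
        others = np.delete(L[i], k)
        others = others[np.isfinite(others)]
        if not np.isfinite(own) or others.size == 0:
            continue
        wins = int((others < own).sum())
        ties = int((others == own).sum())
        m = others.size
        acc[i] = (wins + 0.5 * ties) / m
        if m - ties > 0:
            p[i] = stats.binomtest(
                wins, m - ties, 0.5, alternative="greater"
            ).pvalue
        else:
            p[i] = 1.0
    sig, _thr = fdr_bh(p, q)
    return DecodingResult(
        task_ids=ids,
        accuracy=acc,
        p=p,
        significant=sig,
        n_comparisons=n_tasks - 1,
    )


# ---------------------------------------------------------------------------
# Novel-task pipelines (per subject)
# ---------------------------------------------------------------------------


@dataclass
class NovelEncodingResult:
    accuracy: AccuracyMap
    predictions: np.ndarray  # [B, V], NaN outside covered samples
    covered: np.ndarray  # [B] bool


@dataclass
class NovelDecodingResult:
    decoding: DecodingResult
    likelihoods: np.ndarray  # [n_targets, n_tasks]
    decoded: np.ndarray  # [B, n_terms], NaN outside covered samples
    covered: np.ndarray
    sample_masks: dict[int, np.ndarray]
    ctf: TransformMatrix
    lambdas: list[float]


def _accumulate(total, count, mask, values) -> None:
    total[mask] += values
    count[mask] += 1


def novel_encode(
    design: ExperimentDesign,
    R_train,
    R_test: ResponseMatrix,
    R_test_avg: np.ndarray,
    ctf: TransformMatrix,
    split: TaskSplit,
    config: RidgeConfig | None = None,
    window_s: float = EXCLUSION_WINDOW_S,
    q: float = 0.05,
) -> NovelEncodingResult:
    """Predict held-out-task responses through the cognitive-factor space.

    Five fits, one per task group: each trains the cognitive-factor model on
    the masked training samples of the other groups and predicts the test
    samples of the held-out group.  Predictions at duplicated time points
    are averaged across groups; accuracy and significance follow the
    standard encoding scoring.

    ``R_train`` is the preprocessed training response; ``R_test`` the
    continuous preprocessed test runs (used only for their geometry here);
    ``R_test_avg`` the repeat-averaged test response ``[V, B]``.  Test
    features are delay-embedded on the physical test runs and
    repeat-averaged exactly like the responses.
    """
    from .preprocess import average_test_timecourses

    config = config or RidgeConfig()
    f_train = features.task_onehot(design, "train")
    f_test = features.task_onehot(design, "test")
    Fd_train = features.delay_embed(features.ctf_features(f_train, ctf))
    Fd_test = features.delay_embed(features.ctf_features(f_test, ctf))
    Fd_avg = average_test_timecourses(Fd_test.values, design)
    Rtr = R_train.values.T if isinstance(R_train, ResponseMatrix) else np.asarray(R_train)
    B = design.test_block_len
    V = R_test_avg.shape[0]
    total = np.zeros((B, V))
    count = np.zeros(B, dtype=int)
    for g in range(split.n_groups):
        targets = split.tasks_of(g)
        try:
            train_mask, test_mask = exclusion_masks(design, targets, window_s)
            wt = ridge_fit(
                Fd_train.values[train_mask],
                Rtr[train_mask],
                config,
                fit_intercept=True,
            )
        except Exception as err:  # noqa: BLE001 - annotate the failing fold
            raise RuntimeError(f"novel-encoding fold {g} failed: {err}") from err
        pred = Fd_avg[test_mask] @ wt.flat + wt.intercept
        _accumulate(total, count, test_mask, pred)
    covered = count > 0
    predictions = np.full((B, V), np.nan)
    predictions[covered] = total[covered] / count[covered, None]
    r = pearson_columns(predictions[covered], R_test_avg.T[covered])
    n = int(covered.sum())
    p = gaussian_null(r, n)
    sig, _ = fdr_bh(p, q)
    sig_r = r[sig & np.isfinite(r)]
    acc = AccuracyMap(
        r=r,
        p=p,
        significant=sig,
        n_samples=n,
        fdr_q=q,
        threshold_r=float(sig_r.min()) if sig_r.size else float("nan"),
    )
    return NovelEncodingResult(acc, predictions, covered)


def novel_decode(
    design: ExperimentDesign,
    R_train: ResponseMatrix,
    R_test: ResponseMatrix,
    R_test_avg: np.ndarray,
    ctf: TransformMatrix,
    split: TaskSplit,
    config: RidgeConfig | None = None,
    window_s: float = EXCLUSION_WINDOW_S,
    q: float = 0.05,
) -> NovelDecodingResult:
    """Decode held-out-task factor vectors and classify the tasks.

    For each task group the decoder is trained on the masked training
    samples of the other groups; decoded factor vectors at the held-out test
    samples are accumulated (duplicates averaged across groups), converted
    into task likelihoods against the leave-one-subject-out CTF, and scored
    one-vs-one against every other task.
    """
    from .preprocess import average_test_timecourses

    config = config or RidgeConfig()
    f_train = features.task_onehot(design, "train")
    F_cog = features.ctf_features(f_train, ctf)
    Rd_train = delayed_responses(R_train)
    # embed the physical test runs, then average over repeats: the decoder
    # input keeps the same carry-over structure as the measurements
    Rd_test = delayed_responses(R_test)
    Rd_avg = average_test_timecourses(Rd_test.values, design)
    B = design.test_block_len
    J = ctf.n_terms
    total = np.zeros((B, J))
    count = np.zeros(B, dtype=int)
    lambdas = []
    for g in range(split.n_groups):
        targets = split.tasks_of(g)
        try:
            train_mask, test_mask = exclusion_masks(design, targets, window_s)
            dw = decode_fit(
                Rd_train.values[train_mask], F_cog.values[train_mask], config
            )
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"novel-decoding fold {g} failed: {err}") from err
        lambdas.append(dw.chosen_lambda)
        dec = Rd_avg[test_mask] @ dw.values
        _accumulate(total, count, test_mask, dec)
    covered = count > 0
    decoded = np.full((B, J), np.nan)
    decoded[covered] = total[covered] / count[covered, None]
    masks = per_task_test_masks(design, window_s)
    # restrict each task's mask to covered samples
    masks = {k: m & covered for k, m in masks.items()}
    likelihoods = task_likelihood(decoded, ctf, masks)
    result = one_vs_one(likelihoods, np.array(sorted(masks)), q)
    return NovelDecodingResult(
        decoding=result,
        likelihoods=likelihoods,
        decoded=decoded,
        covered=covered,
        sample_masks=masks,
        ctf=ctf,
        lambdas=lambdas,
    )


# ---------------------------------------------------------------------------
# Shuffle nulls
# ---------------------------------------------------------------------------


def ctf_shuffle_null(
    novel: NovelDecodingResult,
    n_rep: int = 1000,
    seed: int = 0,
    permutation=None,
    per_task: bool = False,
) -> np.ndarray:
    """Null distribution of mean decoding accuracy under CTF shuffling.

    Every element of the task-by-term CTF matrix is randomly permuted
    (element-wise, across the whole matrix), the task likelihoods are
    recomputed from the unchanged decoded factor vectors, and the mean
    one-vs-one accuracy across tasks is recorded; repeated ``n_rep`` times.

    ``permutation`` is a test hook: a callable ``(rng, size) -> index
    array`` replacing the random permutation (identity reproduces the
    unshuffled statistic).  With ``per_task=True`` the full
    ``[n_rep, n_targets]`` accuracy matrix is returned instead of the
    per-repetition means.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    flat = novel.ctf.values.ravel()
    task_ids = np.array(sorted(novel.sample_masks))
    out = np.empty((n_rep, task_ids.size))
    for i in range(n_rep):
        perm = (
            rng.permutation(flat.size)
            if permutation is None
            else permutation(rng, flat.size)
        )
        shuffled = TransformMatrix(
            flat[perm].reshape(novel.ctf.values.shape),
            list(novel.ctf.task_names),
            list(novel.ctf.term_names),
        )
        L = task_likelihood(novel.decoded, shuffled, novel.sample_masks)
        out[i] = one_vs_one(L, task_ids).accuracy
    return out if per_task else np.nanmean(out, axis=1)


def feature_shuffle_null(
    F_cog_block,
    W: WeightTensor,
    R_test_avg: np.ndarray,
    design: ExperimentDesign,
    n_rep: int = 1000,
    seed: int = 0,
    permutation=None,
) -> np.ndarray:
    """Null distribution of mean prediction accuracy under feature shuffling.

    Every element of the test cognitive-factor feature matrix is randomly
    permuted; the shuffled matrix is FIR-embedded and multiplied with the
    original weight matrix, and the mean prediction accuracy across voxels
    is recorded; repeated ``n_rep`` times.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    base = (
        F_cog_block
        if isinstance(F_cog_block, features.FeatureMatrix)
        else features.FeatureMatrix(
            values=np.asarray(F_cog_block, dtype=float),
            feature_names=[f"t{i}" for i in range(np.asarray(F_cog_block).shape[1])],
            tr=design.tr,
            run_slices=[(0, np.asarray(F_cog_block).shape[0])],
        )
    )
    flat = base.values.ravel()
    Rt = R_test_avg.T
    out = np.empty(n_rep)
    for i in range(n_rep):
        perm = (
            rng.permutation(flat.size)
            if permutation is None
            else permutation(rng, flat.size)
        )
        shuffled = features.FeatureMatrix(
            values=flat[perm].reshape(base.values.shape),
            feature_names=list(base.feature_names),
            tr=base.tr,
            run_slices=list(base.run_slices),
        )
        pred = features.delay_embed(shuffled, W.delays_s).values @ W.flat
        out[i] = float(np.nanmean(pearson_columns(pred, Rt)))
    return out
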