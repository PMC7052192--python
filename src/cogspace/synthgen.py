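"""Synthetic multi-task fMRI: designs, ground truth and BOLD simulation.

The generator emulates the study conditions the analysis assumes: multi-run
designs with 6-12 s trials, 2-s feedback displays and 6-s task-free edges;
cluster-structured ground-truth weight maps shared across a cohort in task
space but realized in subject-specific voxel spaces; term maps built as
noisy copies of the cluster-mean maps; and forward-simulated responses
through the same three-delay FIR model the encoder assumes, plus
low-frequency drift and i.i.d. Gaussian noise.

Task-space geometry is planted in a latent cognitive-factor space: task
``k`` is ``cluster_sep`` times its cluster axis plus a unit mixture of
shared private factor axes, and term ``j`` is a factor axis plus its own
noise axis (the first ``n_clusters`` term slots are noisy cluster-mean
directions).  Each
subject's voxel realization multiplies these latents by an orthonormal,
zero-row-mean random basis, so every pairwise Pearson correlation between
maps is exactly the cosine of the latents and therefore identical across
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import features
from .design import (
    EDGE_PAD_S,
    FEEDBACK_DURATION_S,
    NO_TASK,
    ExperimentDesign,
    Run,
    Trial,
)
from .preprocess import ResponseMatrix
from .repspace import MergeTree, hca

#: relative gain of the three FIR delays in the forward model
DELAY_GAINS = (1.0, 0.9, 0.6)


@dataclass
class NoiseSpec:
    """Observation noise: i.i.d. Gaussian plus slow sinusoidal drift."""

    sigma: float = 1.0
    drift_amplitude: float = 1.0
    drift_period_s: float = 480.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be > 0")


@dataclass
class GroundTruth:
    """Planted task structure and its voxel-space realization for one subject."""

    true_weights: np.ndarray  # [3, n_tasks, n_voxels]
    cluster_of_task: np.ndarray  # [n_tasks]
    term_maps: np.ndarray  # [n_terms, n_voxels]
    hierarchy: MergeTree
    task_latents: np.ndarray  # [n_tasks, L], shared across a cohort
    term_latents: np.ndarray  # [n_terms, L], shared across a cohort
    cluster_of_term: np.ndarray  # [n_terms]
    delay_gains: tuple[float, ...] = DELAY_GAINS

    @property
    def n_tasks(self) -> int:
        return self.true_weights.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.true_weights.shape[2]

    @property
    def task_maps(self) -> np.ndarray:
        """Delay-averaged true weight maps, ``[n_tasks, n_voxels]``."""
        return self.true_weights.mean(axis=0)


@dataclass
class SubjectData:
    """One subject of a synthetic cohort."""

    design: ExperimentDesign
    responses: list[ResponseMatrix]
    ground_truth: GroundTruth
    subject_id: int = 0

    @property
    def train_responses(self) -> list[ResponseMatrix]:
        return [
            rm
            for rm, run in zip(self.responses, self.design.runs)
            if not run.is_test
        ]

    @property
    def test_responses(self) -> list[ResponseMatrix]:
        return [
            rm
            for rm, run in zip(self.responses, self.design.runs)
            if run.is_test
        ]


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------


def _duration_bins(trial_range_s, tr: float) -> tuple[int, int]:
    lo, hi = trial_range_s
    lo_b = int(np.ceil(lo / tr - 1e-9))
    hi_b = int(np.floor(hi / tr + 1e-9))
    if lo_b < 1 or hi_b < lo_b:
        raise ValueError(
            f"trial range {trial_range_s} s leaves no duration that is a "
            f"multiple of tr={tr}"
        )
    return lo_b, hi_b


def _button_counts(
    trials: list[Trial],
    duration: float,
    response_tasks: frozenset[int],
    rng: np.random.Generator,
) -> np.ndarray:
    counts = np.zeros((4, int(round(duration))), dtype=float)
    for trial in trials:
        if trial.task not in response_tasks:
            continue
        for sec in range(int(trial.onset), int(trial.offset)):
            n = rng.poisson(0.4)
            if n:
                counts[rng.integers(4), sec] += n
    return counts


def make_design(
    n_tasks: int,
    n_train_runs: int,
    n_test_runs: int,
    run_duration_s: float,
    trial_range_s: tuple[float, float],
    tr: float = 2.0,
    seed: int = 0,
    *,
    feedback_every: int = 8,
    response_tasks: frozenset[int] | None = None,
    test_feedback_period: int = 3,
    test_block_s: float | None = None,
    task_names: list[str] | None = None,
) -> ExperimentDesign:
    """Generate a multi-run experiment design.

    Training runs present tasks in pseudorandom order (cycling through
    seeded permutations of the task list) with a 2-s feedback display after
    every ``feedback_every`` trials and 6-s task-free edges.  Test runs
    carry a fixed task sequence (one seeded permutation of all tasks with
    per-task durations drawn once from ``trial_range_s``) repeated as many
    times as the total retained test samples allow; each test run records
    how many trailing samples the reshape step must discard (6-s end rest,
    a trailing feedback sample on every ``test_feedback_period``-th run, and
    any remainder needed to make the retained length an exact multiple of
    the block).

    ``test_block_s`` optionally fixes the repeat-block duration by padding
    the block with task-free time after the drawn trials.
    """
    if n_tasks <= 0:
        raise ValueError("n_tasks must be positive")
    rng = np.random.default_rng(seed)
    T_run = run_duration_s / tr
    if abs(T_run - round(T_run)) > 1e-9:
        raise ValueError("run_duration_s must be divisible by tr")
    T_run = int(round(T_run))
    pad = int(round(EDGE_PAD_S / tr))
    lo_b, hi_b = _duration_bins(trial_range_s, tr)
    if response_tasks is None:
        response_tasks = frozenset(range(0, n_tasks, 4))
    names = task_names or [f"task{k:03d}" for k in range(n_tasks)]

    runs: list[Run] = []

    # -- training runs -------------------------------------------------
    usable_end = (T_run - pad) * tr
    pool: list[int] = []
    for i in range(n_train_runs):
        trials: list[Trial] = []
        feedback: list[float] = []
        cursor = pad * tr
        since_fb = 0
        while True:
            dur = int(rng.integers(lo_b, hi_b + 1)) * tr
            if cursor + dur > usable_end:
                break
            if not pool:
                pool = [int(k) for k in rng.permutation(n_tasks)]
            trials.append(Trial(pool.pop(0), cursor, dur))
            cursor += dur
            since_fb += 1
            if (
                since_fb >= feedback_every
                and cursor + FEEDBACK_DURATION_S <= usable_end
            ):
                feedback.append(cursor)
                cursor += FEEDBACK_DURATION_S
                since_fb = 0
        if not trials:
            raise ValueError(
                f"training run {i}: no trial of {trial_range_s} s fits in "
                f"{run_duration_s} s with {EDGE_PAD_S} s edge padding"
            )
        runs.append(
            Run(
                duration=run_duration_s,
                trials=trials,
                feedback_onsets=feedback,
                button_counts=_button_counts(
                    trials, run_duration_s, response_tasks, rng
                ),
            )
        )

    # -- test runs ------------------------------------------------------
    test_block = np.empty(0, dtype=np.int64)
    test_repeats = 0
    if n_test_runs > 0:
        order = rng.permutation(n_tasks)
        durs = rng.integers(lo_b, hi_b + 1, size=n_tasks)
        block = [np.full(pad, NO_TASK, dtype=np.int64)]
        for k, d in zip(order, durs):
            block.append(np.full(d, k, dtype=np.int64))
        test_block = np.concatenate(block)
        if test_block_s is not None:
            target = test_block_s / tr
            if abs(target - round(target)) > 1e-9:
                raise ValueError("test_block_s must be divisible by tr")
            target = int(round(target))
            if target < test_block.size:
                raise ValueError(
                    f"test_block_s={test_block_s} too short for the drawn "
                    f"trials ({test_block.size * tr} s)"
                )
            test_block = np.concatenate(
                [
                    test_block,
                    np.full(target - test_block.size, NO_TASK, dtype=np.int64),
                ]
            )
        B = test_block.size
        flagged = [
            (i + 1) % test_feedback_period == 0 for i in range(n_test_runs)
        ]
        base_discard = [pad + (1 if f else 0) for f in flagged]
        capacity = n_test_runs * T_run - sum(base_discard)
        if capacity < B:
            raise ValueError(
                f"test runs retain {capacity} samples, fewer than one "
                f"repeat block ({B} samples)"
            )
        test_repeats = capacity // B
        remainder = capacity - test_repeats * B
        extra = [remainder // n_test_runs] * n_test_runs
        for i in range(remainder % n_test_runs):
            extra[n_test_runs - 1 - i] += 1
        discard = [b + e for b, e in zip(base_discard, extra)]
        for i, d in enumerate(discard):
            if d >= T_run:
                raise ValueError(
                    f"test run {i}: discard ({d}) exceeds run length"
                )
        full = np.tile(test_block, test_repeats)
        start = 0
        for i in range(n_test_runs):
            content_len = T_run - discard[i]
            labels = full[start : start + content_len]
            start += content_len
            trials = []
            t = 0
            while t < labels.size:
                task = labels[t]
                t1 = t
                while t1 < labels.size and labels[t1] == task:
                    t1 += 1
                if task != NO_TASK:
                    trials.append(Trial(int(task), t * tr, (t1 - t) * tr))
                t = t1
            feedback = (
                [content_len * tr] if flagged[i] else []
            )
            runs.append(
                Run(
                    duration=run_duration_s,
                    trials=trials,
                    feedback_onsets=feedback,
                    button_counts=_button_counts(
                        trials, run_duration_s, response_tasks, rng
                    ),
                    is_test=True,
                    n_discard_end=discard[i],
                )
            )

    return ExperimentDesign(
        runs=runs,
        tr=tr,
        n_tasks=n_tasks,
        task_names=names,
        test_repeats=test_repeats,
        test_block=test_block,
    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class _Latent:
    task_latents: np.ndarray
    term_latents: np.ndarray
    cluster_of_task: np.ndarray
    cluster_of_term: np.ndarray
    hierarchy: MergeTree
    cluster_sep: float


def _latent_structure(
    n_tasks: int,
    n_clusters: int,
    n_terms: int,
    cluster_sep: float,
    term_noise: float,
    rng: np.random.Generator,
    n_factors: int | None = None,
) -> _Latent:
    """Plant task and term latents in a shared cognitive-factor space.

    The factor space has ``n_factors`` axes: one per cluster plus a pool of
    shared private axes.  Task ``k`` is ``cluster_sep`` times its cluster
    axis plus a unit-norm random mixture of the private axes — every task
    lies in the span of the factors, which is what makes novel tasks
    predictable and decodable from models trained on other tasks.  Term
    ``j`` is the factor axis ``j mod n_factors`` plus ``term_noise`` on its
    own noise axis, so the first ``n_clusters`` term slots are noisy copies
    of the cluster-mean directions and the term set as a whole spans the
    factor space.
    """
    if min(n_tasks, n_clusters, n_terms) <= 0:
        raise ValueError("dimensions must be positive")
    if n_clusters > n_tasks:
        raise ValueError("n_clusters must not exceed n_tasks")
    if n_factors is None:
        n_factors = n_clusters + max(2, n_tasks // 4)
    if n_factors <= n_clusters:
        raise ValueError("n_factors must exceed n_clusters")
    F = n_factors
    L = F + n_terms
    cluster_of_task = np.arange(n_tasks) % n_clusters
    U = np.zeros((n_tasks, L))
    U[np.arange(n_tasks), cluster_of_task] = cluster_sep
    z = rng.standard_normal((n_tasks, F - n_clusters))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    U[:, n_clusters:F] = z
    factor_of_term = np.arange(n_terms) % F
    V = np.zeros((n_terms, L))
    V[np.arange(n_terms), factor_of_term] = 1.0
    V[np.arange(n_terms), F + np.arange(n_terms)] = term_noise
    cluster_of_term = np.where(factor_of_term < n_clusters, factor_of_term, -1)
    gram = U @ U.T
    norms = np.sqrt(np.diag(gram))
    rsm_true = gram / np.outer(norms, norms)
    hierarchy = hca(np.clip(rsm_true, -1.0, 1.0))
    return _Latent(U, V, cluster_of_task, cluster_of_term, hierarchy, cluster_sep)


def _voxel_basis(L: int, n_voxels: int, rng: np.random.Generator) -> np.ndarray:
    """Random ``[L, V]`` basis with orthonormal, zero-mean rows.

    Rows are orthogonal to the constant vector, so Pearson correlations of
    any maps built from this basis equal the cosines of their latents.
    """
    if n_voxels < L + 1:
        raise ValueError(
            f"need at least {L + 1} voxels for a {L}-dim latent space"
        )
    B = rng.standard_normal((L, n_voxels))
    B -= B.mean(axis=1, keepdims=True)
    Q, _ = np.linalg.qr(B.T)  # columns orthonormal, each orthogonal to 1
    return Q.T


def _realize(
    latent: _Latent, n_voxels: int, rng: np.random.Generator
) -> GroundTruth:
    L = latent.task_latents.shape[1]
    basis = _voxel_basis(L, n_voxels, rng)
    # orthonormal rows have entries ~ 1/sqrt(V); rescale so a single task's
    # voxel weights have roughly unit variance
    basis_s = basis * np.sqrt(n_voxels / (latent.cluster_sep**2 + 1.0))
    task_maps = latent.task_latents @ basis_s
    gains = np.asarray(DELAY_GAINS)
    true_weights = gains[:, None, None] * task_maps[None]
    term_maps = latent.term_latents @ basis_s
    return GroundTruth(
        true_weights=true_weights,
        cluster_of_task=latent.cluster_of_task.copy(),
        term_maps=term_maps,
        hierarchy=latent.hierarchy,
        task_latents=latent.task_latents.copy(),
        term_latents=latent.term_latents.copy(),
        cluster_of_term=latent.cluster_of_term.copy(),
    )


def make_ground_truth(
    n_voxels: int,
    n_tasks: int,
    n_clusters: int,
    n_terms: int,
    cluster_sep: float = 3.0,
    term_noise: float = 0.3,
    n_factors: int | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Cluster-structured true weights, term maps and the planted hierarchy.

    Tasks in the same planted cluster share a cluster axis of magnitude
    ``cluster_sep`` plus a unit task-private deviation; term maps are
    cluster-mean directions plus ``term_noise`` independent deviation.  The
    planted hierarchy is the single-linkage tree of the noise-free task
    correlation structure.
    """
    rng = np.random.default_rng(seed)
    latent = _latent_structure(
        n_tasks, n_clusters, n_terms, cluster_sep, term_noise, rng, n_factors
    )
    return _realize(latent, n_voxels, rng)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------


def simulate_bold(
    design: ExperimentDesign,
    ground_truth: GroundTruth,
    noise: NoiseSpec | None = None,
) -> list[ResponseMatrix]:
    """Forward-simulate per-run voxel responses.

    The response is the sum over the three FIR delays of the one-hot task
    features shifted by that delay (within runs) times the true
    delay-specific weights, plus sinusoidal low-frequency drift and i.i.d.
    Gaussian noise.
    """
    if ground_truth.n_tasks != design.n_tasks:
        raise ValueError(
            f"ground truth has {ground_truth.n_tasks} tasks, design has "
            f"{design.n_tasks}"
        )
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    onehot = features.task_onehot(design, portion="all")
    delayed = features.delay_embed(onehot)
    W = ground_truth.true_weights.reshape(-1, ground_truth.n_voxels)
    signal = delayed.values @ W  # [T, V]
    V = ground_truth.n_voxels
    out: list[ResponseMatrix] = []
    for r0, r1 in design.portion_slices("all"):
        seg = signal[r0:r1].T.copy()  # [V, T_run]
        T_run = r1 - r0
        if noise.drift_amplitude > 0:
            t = np.arange(T_run) * design.tr
            for m in (1, 2, 3):
                period = noise.drift_period_s * m
                phase = rng.uniform(0, 2 * np.pi, size=(V, 1))
                amp = noise.drift_amplitude / m
                seg += amp * np.sin(2 * np.pi * t[None, :] / period + phase)
        if noise.sigma > 0:
            seg += noise.sigma * rng.standard_normal(seg.shape)
        out.append(ResponseMatrix(seg, design.tr))
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def make_cohort(
    n_subjects: int,
    n_tasks: int = 24,
    n_clusters: int = 6,
    n_terms: int = 60,
    n_voxels: int | list[int] = 2000,
    n_train_runs: int = 4,
    n_test_runs: int = 2,
    run_duration_s: float = 360.0,
    trial_range_s: tuple[float, float] = (6.0, 12.0),
    tr: float = 2.0,
    cluster_sep: float = 3.0,
    term_noise: float = 0.3,
    n_factors: int | None = None,
    sigma: float = 1.0,
    drift_amplitude: float = 1.0,
    drift_period_s: float = 480.0,
    seed: int = 0,
    test_block_s: float | None = None,
) -> list[SubjectData]:
    """Generate a cohort sharing task-space structure.

    All subjects share the design (same stimulus protocol), the cluster
    assignment and the latent task/term geometry; the voxel-space
    realizations and the observation noise are subject-specific.
    """
    if n_subjects < 2:
        raise ValueError(
            "a cohort needs at least two subjects (leave-one-subject-out "
            "averaging is undefined otherwise)"
        )
    rng = np.random.default_rng(seed)
    design = make_design(
        n_tasks,
        n_train_runs,
        n_test_runs,
        run_duration_s,
        trial_range_s,
        tr=tr,
        seed=int(rng.integers(2**31)),
        test_block_s=test_block_s,
    )
    latent = _latent_structure(
        n_tasks,
        n_clusters,
        n_terms,
        cluster_sep,
        term_noise,
        np.random.default_rng(rng.integers(2**31)),
        n_factors,
    )
    if isinstance(n_voxels, int):
        voxel_counts = [n_voxels] * n_subjects
    else:
        voxel_counts = list(n_voxels)
        if len(voxel_counts) != n_subjects:
            raise ValueError("n_voxels list length must equal n_subjects")
    cohort = []
    for s in range(n_subjects):
        gt = _realize(latent, voxel_counts[s], np.random.default_rng(rng.integers(2**31)))
        noise = NoiseSpec(
            sigma=sigma,
            drift_amplitude=drift_amplitude,
            drift_period_s=drift_period_s,
            seed=int(rng.integers(2**31)),
        )
        responses = simulate_bold(design, gt, noise)
        cohort.append(SubjectData(design, responses, gt, subject_id=s))
    return cohort
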