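"""End-to-end orchestration: preprocess, fit, group analyses, generalization.

These helpers tie the stage modules together for the CLI, the test-suite
and reproduction scripts.  The desk-scale default configuration exercises
every stage of the analysis at a size that runs in minutes on one CPU; the
paper-scale geometry (103 tasks, 12 + 6 runs of 556 s, tens of thousands of
voxels) is available through the same knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features, generalize, metadata, preprocess, repspace
from .encoding import (
    AccuracyMap,
    RidgeConfig,
    WeightTensor,
    compare_models_wilcoxon,
    predict_and_score,
    ridge_fit,
)
from .metadata import TermAtlas, TransformMatrix
from .preprocess import ResponseMatrix
from .synthgen import SubjectData

#: desk-scale study configuration (defaults of :func:`cogspace.synthgen.make_cohort`)
DESK_CONFIG: dict = dict(
    n_subjects=6,
    n_tasks=24,
    n_clusters=6,
    n_terms=60,
    n_voxels=2000,
    n_train_runs=4,
    n_test_runs=2,
    run_duration_s=360.0,
    trial_range_s=(6.0, 12.0),
    tr=2.0,
    cluster_sep=3.0,
    term_noise=0.3,
    n_factors=None,
    sigma=1.0,
    drift_amplitude=1.0,
    drift_period_s=480.0,
    seed=0,
)

#: paper-scale geometry (same generator, full task set and run counts)
PAPER_SCALE_CONFIG: dict = dict(
    DESK_CONFIG,
    n_tasks=103,
    n_train_runs=12,
    n_test_runs=6,
    run_duration_s=556.0,
    trial_range_s=(6.0, 8.0),
    test_block_s=824.0,
    n_voxels=50000,
)


def validate_config(config: dict) -> dict:
    """Merge a user configuration over the desk-scale defaults.

    Unknown keys raise, naming the offending key.
    """
    allowed = set(DESK_CONFIG) | {"test_block_s"}
    for key in config:
        if key not in allowed:
            raise ValueError(f"unknown configuration key: {key!r}")
    merged = dict(DESK_CONFIG)
    merged.update(config)
    return merged


# ---------------------------------------------------------------------------
# Per-subject preprocessing and fitting
# ---------------------------------------------------------------------------


@dataclass
class PreprocessedSubject:
    """Detrended, z-scored responses split into model-ready pieces."""

    R_train: ResponseMatrix  # voxel x T_train
    R_test: ResponseMatrix  # voxel x T_test (continuous physical test runs)
    R_test_avg: np.ndarray  # voxel x B (repeat-averaged)
    test_repeats: np.ndarray  # repeat x voxel x B
    valid_voxels: np.ndarray


def preprocess_subject(sd: SubjectData) -> PreprocessedSubject:
    """Median-filter detrend and per-run z-scoring, then test-run averaging."""
    train = preprocess.concat_runs(sd.train_responses)
    train = preprocess.detrend_median(train)
    train, valid_train = preprocess.zscore_voxels(train)
    test = preprocess.concat_runs(sd.test_responses)
    test = preprocess.detrend_median(test)
    test, valid_test = preprocess.zscore_voxels(test)
    per_run = [
        ResponseMatrix(test.values[:, r0:r1], test.tr)
        for r0, r1 in test.run_slices
    ]
    repeats, averaged = preprocess.reshape_test_runs(per_run, sd.design)
    return PreprocessedSubject(
        R_train=train,
        R_test=test,
        R_test_avg=averaged,
        test_repeats=repeats,
        valid_voxels=valid_train & valid_test,
    )


@dataclass
class SubjectFit:
    """A fitted voxel-wise model for one subject."""

    subject_id: int
    model: str
    weights: WeightTensor
    accuracy: AccuracyMap
    pre: PreprocessedSubject
    nuisance: list[str] = field(default_factory=list)


def _model_features(
    sd: SubjectData,
    model: str,
    portion: str,
    tree=None,
    ctf: TransformMatrix | None = None,
):
    if model == "tasktype":
        return features.task_onehot(sd.design, portion)
    if model == "hierarchical":
        if tree is None:
            raise ValueError("hierarchical model requires a merge tree")
        return features.hierarchical_features(sd.design, tree, portion)
    if model == "cogfactor":
        if ctf is None:
            raise ValueError("cogfactor model requires a CTF (term atlas fits)")
        return features.ctf_features(features.task_onehot(sd.design, portion), ctf)
    if model == "button":
        return features.button_features(sd.design, portion)
    raise ValueError(f"unknown model {model!r}")


def fit_subject(
    sd: SubjectData,
    model: str = "tasktype",
    config: RidgeConfig | None = None,
    pre: PreprocessedSubject | None = None,
    tree=None,
    ctf: TransformMatrix | None = None,
    nuisance: list[tuple[str, np.ndarray]] | None = None,
    lam: float | None = None,
) -> SubjectFit:
    """Fit one voxel-wise encoding model and score it on the averaged test data.

    ``nuisance`` optionally concatenates extra regressor blocks (name, T x k
    array over the training portion) during training; they are removed,
    together with their weights, before test-time prediction.
    """
    config = config or RidgeConfig()
    pre = pre or preprocess_subject(sd)
    f_train = _model_features(sd, model, "train", tree, ctf)
    f_test = _model_features(sd, model, "test", tree, ctf)
    nuisance_names: list[str] = []
    if nuisance:
        blocks = [(model, f_train)]
        for name, arr in nuisance:
            blocks.append(
                (
                    name,
                    features.FeatureMatrix(
                        values=arr,
                        feature_names=[f"{name}{i}" for i in range(arr.shape[1])],
                        tr=sd.design.tr,
                        run_slices=f_train.run_slices,
                    ),
                )
            )
        f_train = features.concat_features(blocks)
        nuisance_names = [name for name, _ in nuisance]
    Fd_train = features.delay_embed(f_train)
    wt = ridge_fit(Fd_train, pre.R_train, config, lam=lam, fit_intercept=True)
    # test features never contain the nuisance blocks; drop the matching
    # weight rows symmetrically instead.  Features are delay-embedded on the
    # physical test runs and repeat-averaged exactly like the responses, so
    # predictions carry the same hemodynamic carry-over across repeats.
    Fd_test = features.delay_embed(f_test)
    Fd_test_avg = preprocess.average_test_timecourses(Fd_test.values, sd.design)
    if nuisance_names:
        keep = np.setdiff1d(
            np.arange(Fd_train.values.shape[1]),
            np.concatenate(
                [Fd_train.block_columns(b) for b in nuisance_names]
            ),
        )
        flat = wt.flat[keep]
        n_delays = len(wt.delays_s)
        wt_test = WeightTensor(
            values=flat.reshape(n_delays, -1, flat.shape[1]),
            feature_names=list(f_test.feature_names),
            chosen_lambda=wt.chosen_lambda,
            delays_s=wt.delays_s,
            intercept=wt.intercept,
        )
    else:
        wt_test = wt
    acc = predict_and_score(wt_test, Fd_test_avg, pre.R_test_avg.T)
    return SubjectFit(
        subject_id=sd.subject_id,
        model=model,
        weights=wt_test,
        accuracy=acc,
        pre=pre,
        nuisance=nuisance_names,
    )


def fit_cohort(
    cohort: list[SubjectData],
    model: str = "tasktype",
    config: RidgeConfig | None = None,
    pres: list[PreprocessedSubject] | None = None,
    **kwargs,
) -> list[SubjectFit]:
    pres = pres or [preprocess_subject(sd) for sd in cohort]
    return [
        fit_subject(sd, model, config, pre, **kwargs)
        for sd, pre in zip(cohort, pres)
    ]


# ---------------------------------------------------------------------------
# Group analyses
# ---------------------------------------------------------------------------


def hierarchical_tree_loso(fits: list[SubjectFit], target: int) -> repspace.MergeTree:
    """Task dendrogram from all subjects except the target.

    The hierarchical model of a subject uses a tree fit on the other
    subjects' data only, keeping the features independent of the target.
    """
    others = [
        (f.weights, f.accuracy) for i, f in enumerate(fits) if i != target
    ]
    if not others:
        raise ValueError("need at least one other subject")
    gw = repspace.group_weights(others)
    return repspace.hca(repspace.rsm(gw))


def fit_cohort_hierarchical(
    cohort: list[SubjectData],
    tasktype_fits: list[SubjectFit],
    config: RidgeConfig | None = None,
) -> list[SubjectFit]:
    """Hierarchical-model fits with leave-one-subject-out trees."""
    out = []
    for i, sd in enumerate(cohort):
        tree = hierarchical_tree_loso(tasktype_fits, i)
        out.append(
            fit_subject(
                sd,
                "hierarchical",
                config,
                pre=tasktype_fits[i].pre,
                tree=tree,
            )
        )
    return out


def subject_ctf(sd: SubjectData, fit: SubjectFit) -> TransformMatrix:
    """CTF of one subject from its task-type fit and its own term atlas."""
    atlas = TermAtlas(
        term_names=[f"term{j:03d}" for j in range(sd.ground_truth.term_maps.shape[0])],
        maps=sd.ground_truth.term_maps,
    )
    maps, sig = metadata.subject_task_maps(fit.weights, fit.accuracy)
    return metadata.build_ctf(
        maps, atlas.restrict(sig), task_names=list(sd.design.task_names)
    )


def cohort_ctfs(
    cohort: list[SubjectData], fits: list[SubjectFit]
) -> list[TransformMatrix]:
    return [subject_ctf(sd, fit) for sd, fit in zip(cohort, fits)]


def compare_hierarchical_vs_tasktype(
    hier_fits: list[SubjectFit], task_fits: list[SubjectFit]
) -> list[float]:
    """Per-subject one-sided Wilcoxon p for hierarchical > task-type accuracy."""
    return [
        compare_models_wilcoxon(h.accuracy.r, t.accuracy.r)
        for h, t in zip(hier_fits, task_fits)
    ]


# ---------------------------------------------------------------------------
# Novel-task generalization
# ---------------------------------------------------------------------------


@dataclass
class NovelTaskOutcome:
    subject_id: int
    split: generalize.TaskSplit
    encoding: generalize.NovelEncodingResult | None
    decoding: generalize.NovelDecodingResult | None


def run_novel_tasks(
    cohort: list[SubjectData],
    fits: list[SubjectFit],
    target: int,
    n_groups: int = 5,
    split_seed: int = 0,
    config: RidgeConfig | None = None,
    do_encoding: bool = True,
    do_decoding: bool = True,
) -> NovelTaskOutcome:
    """Novel-task encoding/decoding for one target subject.

    The CTF is the leave-one-subject-out average over the other subjects'
    matrices, so the target's features never depend on its own data.
    """
    ctfs = cohort_ctfs(cohort, fits)
    ctf = metadata.loso_ctf(ctfs, target)
    sd = cohort[target]
    pre = fits[target].pre
    split = generalize.split_tasks(sd.design.n_tasks, n_groups, split_seed)
    enc = dec = None
    if do_encoding:
        enc = generalize.novel_encode(
            sd.design, pre.R_train, pre.R_test, pre.R_test_avg, ctf, split, config
        )
    if do_decoding:
        dec = generalize.novel_decode(
            sd.design, pre.R_train, pre.R_test, pre.R_test_avg, ctf, split, config
        )
    return NovelTaskOutcome(sd.subject_id, split, enc, dec)
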