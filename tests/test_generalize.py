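"""Novel-task splitting, exclusion windows, decoding and shuffle nulls."""

from __future__ import annotations

import numpy as np
import pytest

from cogspace import generalize, metadata, pipeline, synthgen
from cogspace.design import ExperimentDesign, Run, Trial
from cogspace.generalize import (
    ctf_shuffle_null,
    decode_fit,
    delayed_responses,
    exclusion_masks,
    feature_shuffle_null,
    likelihood_matrix,
    one_vs_one,
    split_tasks,
    task_likelihood,
)
from cogspace.metadata import TransformMatrix
from cogspace.preprocess import ResponseMatrix


# ---------------------------------------------------------------------------
# split_tasks
# ---------------------------------------------------------------------------


def test_split_sizes_for_full_task_set():
    split = split_tasks(103, 5, seed=0)
    sizes = sorted(np.bincount(split.group_of_task).tolist())
    assert sizes == [20, 20, 21, 21, 21]


def test_split_partitions_task_set():
    split = split_tasks(17, 4, seed=3)
    all_tasks = np.concatenate([split.tasks_of(g) for g in range(4)])
    assert sorted(all_tasks.tolist()) == list(range(17))


def test_split_singletons():
    split = split_tasks(6, 6, seed=1)
    assert sorted(np.bincount(split.group_of_task).tolist()) == [1] * 6


def test_split_more_groups_than_tasks_raises():
    with pytest.raises(ValueError):
        split_tasks(3, 5)


# ---------------------------------------------------------------------------
# exclusion masks
# ---------------------------------------------------------------------------


def _mask_design():
    # one training run: target task 1 occupies bins 10-12 (onset 20 s, 6 s)
    run = Run(
        duration=60.0,
        trials=[Trial(0, 6.0, 6.0), Trial(1, 20.0, 6.0), Trial(0, 40.0, 6.0)],
    )
    test_run = Run(
        duration=60.0,
        trials=[Trial(0, 6.0, 6.0), Trial(1, 20.0, 6.0)],
        is_test=True,
        n_discard_end=0,
    )
    return ExperimentDesign(
        runs=[run, test_run],
        tr=2.0,
        n_tasks=2,
        task_names=["a", "b"],
        test_repeats=1,
        test_block=__import__(
            "cogspace.design", fromlist=["run_timeline"]
        ).run_timeline(test_run, 2.0),
    )


def test_exclusion_window_bins():
    d = _mask_design()
    train_mask, test_mask = exclusion_masks(d, np.array([1]), window_s=6.0)
    assert np.flatnonzero(test_mask).tolist() == [10, 11, 12, 13, 14, 15]
    excluded = np.flatnonzero(~train_mask).tolist()
    assert excluded == [10, 11, 12, 13, 14, 15]


def test_exclusion_soundness_exhaustive():
    design = synthgen.make_design(8, 2, 1, 200, (6, 10), tr=2, seed=4)
    split = split_tasks(8, 4, seed=0)
    timeline = design.timeline("train")
    slices = design.portion_slices("train")
    for g in range(4):
        targets = set(split.tasks_of(g).tolist())
        train_mask, _ = exclusion_masks(design, split.tasks_of(g))
        for t in np.flatnonzero(train_mask):
            r0, _r1 = next(s for s in slices if s[0] <= t < s[1])
            # neither the bin itself nor any of the 3 bins before it (the
            # 6-s window after a target occurrence) may hold a target task
            for back in range(4):
                if t - back >= r0:
                    assert timeline[t - back] not in targets


def test_empty_training_mask_raises():
    run = Run(duration=20.0, trials=[Trial(0, 0.0, 20.0)])
    d = ExperimentDesign(runs=[run], tr=2.0, n_tasks=2, task_names=["a", "b"])
    with pytest.raises(ValueError, match="no training samples"):
        exclusion_masks(d, np.array([0]))


def test_window_truncated_at_run_boundary():
    from cogspace.design import run_timeline

    test_run = Run(
        duration=20.0,
        trials=[Trial(0, 14.0, 6.0)],
        is_test=True,
    )
    train_run = Run(duration=20.0, trials=[Trial(1, 6.0, 6.0)])
    d = ExperimentDesign(
        runs=[train_run, test_run],
        tr=2.0,
        n_tasks=2,
        task_names=["a", "b"],
        test_repeats=1,
        test_block=run_timeline(test_run, 2.0),
    )
    _train, test_mask = exclusion_masks(d, np.array([0]))
    # target occupies the final bins 7-9; the 6-s window is clipped there
    assert np.flatnonzero(test_mask).tolist() == [7, 8, 9]


def test_window_must_be_multiple_of_tr():
    d = _mask_design()
    with pytest.raises(ValueError, match="multiple"):
        exclusion_masks(d, np.array([1]), window_s=5.0)


# ---------------------------------------------------------------------------
# decode_fit
# ---------------------------------------------------------------------------


def test_decoder_inverts_noise_free_system(rng):
    T, V3, J = 40, 12, 4
    Rd = rng.standard_normal((T, V3))
    W0 = rng.standard_normal((V3, J))
    F = Rd @ W0
    dw = decode_fit(Rd, F, lam=0.0)
    np.testing.assert_allclose(Rd @ dw.values, F, atol=1e-8)


def test_delayed_responses_look_forward():
    # impulse at the first sample must appear in the backward-shifted blocks
    vals = np.zeros((2, 6))
    vals[0, 5] = 1.0
    rm = ResponseMatrix(vals, 2.0)
    d = delayed_responses(rm)
    assert d.values.shape == (6, 6)
    # block b at sample t equals response at t + (b+1)
    assert d.values[4, 0] == 1.0
    assert d.values[3, 2] == 1.0
    assert d.values[2, 4] == 1.0


def test_zero_responses_decode_to_zero(rng):
    Rd = np.zeros((20, 6))
    F = rng.standard_normal((20, 3))
    dw = decode_fit(Rd, F, lam=100.0)
    assert not dw.values.any()


# ---------------------------------------------------------------------------
# likelihood and one-vs-one
# ---------------------------------------------------------------------------


def _ctf(rng, K=5, J=8):
    return TransformMatrix(
        rng.uniform(-1, 1, (K, J)),
        [f"task{k}" for k in range(K)],
        [f"term{j}" for j in range(J)],
    )


def test_likelihood_of_exact_row_is_one(rng):
    ctf = _ctf(rng)
    L, n_bad = likelihood_matrix(ctf.values[2][None, :], ctf)
    assert n_bad == 0
    assert L[0, 2] == pytest.approx(1.0)


def test_constant_decoded_vector_excluded(rng):
    ctf = _ctf(rng)
    decoded = np.vstack([np.ones(8), ctf.values[0]])
    L, n_bad = likelihood_matrix(decoded, ctf)
    assert n_bad == 1
    assert np.isnan(L[0]).all()


def test_mask_averaging_of_identical_time_points(rng):
    ctf = _ctf(rng)
    decoded = np.tile(ctf.values[1], (4, 1))
    masks = {1: np.array([True, True, True, True])}
    L = task_likelihood(decoded, ctf, masks)
    single = task_likelihood(decoded[:1], ctf, {1: np.array([True])})
    np.testing.assert_allclose(L, single, atol=1e-12)


def test_one_vs_one_always_highest(rng):
    L = np.full((3, 3), 0.1)
    np.fill_diagonal(L, 0.9)
    res = one_vs_one(L)
    np.testing.assert_array_equal(res.accuracy, 1.0)
    assert res.n_comparisons == 2


def test_one_vs_one_all_ties_give_half():
    L = np.zeros((4, 4))
    res = one_vs_one(L)
    np.testing.assert_array_equal(res.accuracy, 0.5)


def test_one_vs_one_comparison_count_for_full_task_set(rng):
    L = rng.standard_normal((103, 103))
    res = one_vs_one(L)
    assert res.n_comparisons == 102


# ---------------------------------------------------------------------------
# end-to-end novel-task decoding on a small cohort
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def novel_outcome(cohort_small, fits_small):
    return pipeline.run_novel_tasks(
        cohort_small, fits_small, target=0, split_seed=1
    )


def test_novel_decoding_covers_all_tasks(novel_outcome, cohort_small):
    dec = novel_outcome.decoding
    assert dec.decoding.accuracy.shape == (cohort_small[0].design.n_tasks,)
    assert np.isfinite(dec.decoding.accuracy).all()
    assert len(dec.lambdas) == novel_outcome.split.n_groups
    # decoded values defined exactly on covered samples
    assert np.isfinite(dec.decoded[dec.covered]).all()
    assert np.isnan(dec.decoded[~dec.covered]).all()


def test_novel_decoding_beats_chance(novel_outcome):
    assert novel_outcome.decoding.decoding.mean_accuracy > 0.6


def test_novel_encoding_significant_voxels(novel_outcome):
    acc = novel_outcome.encoding.accuracy
    assert np.nanmean(acc.r) > 0.3
    assert acc.significant.mean() > 0.5


# ---------------------------------------------------------------------------
# shuffle nulls
# ---------------------------------------------------------------------------


def test_identity_shuffle_reproduces_statistic(novel_outcome):
    identity = lambda _rng, size: np.arange(size)  # noqa: E731
    null = ctf_shuffle_null(
        novel_outcome.decoding, n_rep=3, seed=0, permutation=identity
    )
    expected = novel_outcome.decoding.decoding.mean_accuracy
    np.testing.assert_allclose(null, expected, atol=1e-12)


def test_ctf_shuffle_null_centers_at_chance(novel_outcome):
    null = ctf_shuffle_null(novel_outcome.decoding, n_rep=60, seed=5)
    se = null.std(ddof=1) / np.sqrt(null.size)
    assert abs(null.mean() - 0.5) < 4 * se + 0.01


def test_feature_shuffle_null_destroys_prediction(cohort_small, fits_small):
    sd, fit = cohort_small[0], fits_small[0]
    ctfs = pipeline.cohort_ctfs(cohort_small, fits_small)
    ctf = metadata.loso_ctf(ctfs, 0)
    from cogspace import features

    f_block = features.ctf_features(
        features.task_onehot(sd.design, "test_block"), ctf
    )
    cog_fit = pipeline.fit_subject(sd, "cogfactor", pre=fit.pre, ctf=ctf)
    null = feature_shuffle_null(
        f_block, cog_fit.weights, fit.pre.R_test_avg, sd.design, n_rep=20, seed=2
    )
    real = float(np.nanmean(cog_fit.accuracy.r))
    assert abs(null.mean()) < 0.1
    assert real > null.mean() + 5 * null.std(ddof=1)
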