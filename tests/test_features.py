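"""Feature-matrix construction and FIR delay embedding."""

from __future__ import annotations

import numpy as np
import pytest

from cogspace import features, synthgen
from cogspace.design import ExperimentDesign, Run, Trial
from cogspace.features import FeatureMatrix
from cogspace.metadata import TransformMatrix
from cogspace.repspace import MergeTree


def _fm(values, tr=2.0, run_slices=None, **kw):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        values=values,
        feature_names=[f"f{i}" for i in range(values.shape[1])],
        tr=tr,
        run_slices=run_slices or [(0, values.shape[0])],
        **kw,
    )


@pytest.fixture(scope="module")
def design():
    return synthgen.make_design(5, 2, 1, 160, (4, 8), tr=2, seed=1)


# ---------------------------------------------------------------------------
# task_onehot
# ---------------------------------------------------------------------------


def test_onehot_row_sums_and_columns(design):
    f = features.task_onehot(design, "train")
    assert f.n_features == design.n_tasks
    sums = f.values.sum(axis=1)
    assert set(np.unique(sums)) <= {0.0, 1.0}
    # edge padding bins are all-zero rows
    for r0, _r1 in f.run_slices:
        assert np.all(f.values[r0 : r0 + 3] == 0)


def test_onehot_empty_run_is_zero_block():
    design = ExperimentDesign(
        runs=[Run(duration=20.0, trials=[])],
        tr=2.0,
        n_tasks=3,
        task_names=list("abc"),
    )
    f = features.task_onehot(design, "train")
    assert f.values.shape == (10, 3)
    assert not f.values.any()


# ---------------------------------------------------------------------------
# delay_embed
# ---------------------------------------------------------------------------


def test_delayed_impulse_positions():
    f = _fm(np.array([[1.0], [0], [0], [0], [0]]))
    d = features.delay_embed(f)
    expected = np.zeros((5, 3))
    expected[1, 0] = expected[2, 1] = expected[3, 2] = 1.0
    np.testing.assert_array_equal(d.values, expected)


def test_delay_embed_triples_columns():
    f = _fm(np.zeros((10, 7)))
    assert features.delay_embed(f).n_features == 21


def test_delay_embed_does_not_bleed_across_runs():
    values = np.zeros((8, 1))
    values[3, 0] = 1.0  # last sample of run 1
    f = _fm(values, run_slices=[(0, 4), (4, 8)])
    d = features.delay_embed(f)
    assert not d.values[4:].any()


def test_negative_delays_shift_backward():
    values = np.zeros((5, 1))
    values[4, 0] = 1.0
    f = _fm(values)
    d = features.delay_embed(f, (-2.0, -4.0))
    assert d.values[3, 0] == 1.0 and d.values[2, 1] == 1.0
    assert d.values.sum() == 2.0


def test_delay_not_divisible_by_tr_raises():
    f = _fm(np.zeros((5, 1)), tr=4.0)
    with pytest.raises(ValueError, match="divide"):
        features.delay_embed(f)


def test_delay_embed_is_linear(rng):
    F = _fm(rng.standard_normal((12, 3)), run_slices=[(0, 5), (5, 12)])
    G = _fm(rng.standard_normal((12, 3)), run_slices=[(0, 5), (5, 12)])
    combo = _fm(2.0 * F.values - 3.0 * G.values, run_slices=[(0, 5), (5, 12)])
    np.testing.assert_allclose(
        features.delay_embed(combo).values,
        2.0 * features.delay_embed(F).values
        - 3.0 * features.delay_embed(G).values,
        atol=1e-12,
    )


# ---------------------------------------------------------------------------
# hierarchical_features
# ---------------------------------------------------------------------------


def _chain_tree(n):
    merges = []
    prev = 0
    for m in range(n - 1):
        merges.append((prev, m + 1, 0.1 * (m + 1)))
        prev = n + m
    return MergeTree(merges, n)


def test_hierarchical_column_count_and_root(design):
    tree = _chain_tree(design.n_tasks)
    h = features.hierarchical_features(design, tree, "train")
    onehot = features.task_onehot(design, "train")
    assert h.n_features == design.n_tasks - 1
    np.testing.assert_array_equal(
        h.values[:, -1], onehot.values.max(axis=1)
    )  # root = any-task indicator


def test_hierarchical_two_leaf_tree():
    design = ExperimentDesign(
        runs=[
            Run(
                duration=24.0,
                trials=[Trial(0, 6.0, 4.0), Trial(1, 12.0, 4.0)],
            )
        ],
        tr=2.0,
        n_tasks=2,
        task_names=["a", "b"],
    )
    tree = MergeTree([(0, 1, 0.5)], 2)
    h = features.hierarchical_features(design, tree, "train")
    onehot = features.task_onehot(design, "train")
    assert h.n_features == 1
    np.testing.assert_array_equal(h.values[:, 0], onehot.values.sum(axis=1))


def test_hierarchical_node_equals_clipped_child_sum(design):
    tree = _chain_tree(design.n_tasks)
    h = features.hierarchical_features(design, tree, "train")
    onehot = features.task_onehot(design, "train")
    sets = tree.leaf_sets()
    for j, leaves in enumerate(sets):
        manual = np.clip(onehot.values[:, sorted(leaves)].sum(axis=1), 0, 1)
        np.testing.assert_array_equal(h.values[:, j], manual)


def test_hierarchical_leaf_mismatch_raises(design):
    with pytest.raises(ValueError, match="leaves"):
        features.hierarchical_features(design, _chain_tree(4), "train")


# ---------------------------------------------------------------------------
# ctf_features
# ---------------------------------------------------------------------------


def test_ctf_identity_roundtrip(design):
    f = features.task_onehot(design, "train")
    ctf = TransformMatrix(
        np.eye(design.n_tasks),
        list(design.task_names),
        [f"t{i}" for i in range(design.n_tasks)],
    )
    out = features.ctf_features(f, ctf)
    np.testing.assert_array_equal(out.values, f.values)


def test_ctf_row_lookup(design, rng):
    f = features.task_onehot(design, "train")
    C = rng.uniform(-1, 1, size=(design.n_tasks, 7))
    ctf = TransformMatrix(C, list(design.task_names), [f"t{i}" for i in range(7)])
    out = features.ctf_features(f, ctf)
    timeline = design.timeline("train")
    for t, task in enumerate(timeline):
        if task >= 0:
            np.testing.assert_array_equal(out.values[t], C[task])
        else:
            assert not out.values[t].any()


def test_ctf_dimension_mismatch(design):
    ctf = TransformMatrix(np.eye(3), list("abc"), list("xyz"))
    with pytest.raises(ValueError, match="dimension"):
        features.ctf_features(features.task_onehot(design, "train"), ctf)


# ---------------------------------------------------------------------------
# button_features
# ---------------------------------------------------------------------------


def test_button_features_aggregate_counts():
    counts = np.zeros((4, 20))
    counts[1, 4] = 2
    counts[1, 5] = 1  # same TR bin as second 4 at tr=2
    counts[3, 18] = 5
    design = ExperimentDesign(
        runs=[Run(duration=20.0, trials=[], button_counts=counts)],
        tr=2.0,
        n_tasks=1,
        task_names=["a"],
    )
    f = features.button_features(design, "train")
    assert f.values.shape == (10, 4)
    assert f.values[2, 1] == 3.0  # seconds 4-5 fall into bin 2
    assert f.values[9, 3] == 5.0
    assert f.values.sum() == 8.0


def test_button_features_zero_without_presses():
    design = ExperimentDesign(
        runs=[Run(duration=12.0, trials=[])],
        tr=2.0,
        n_tasks=1,
        task_names=["a"],
    )
    f = features.button_features(design, "train")
    assert f.values.shape == (6, 4)
    assert not f.values.any()


# ---------------------------------------------------------------------------
# concat / drop blocks
# ---------------------------------------------------------------------------


def test_concat_and_drop_round_trip(rng):
    A = _fm(rng.standard_normal((9, 2)))
    B = _fm(rng.standard_normal((9, 3)))
    cat = features.concat_features([("A", A), ("B", B)])
    assert cat.values.shape == (9, 5)
    assert cat.blocks == [("A", 2), ("B", 3)]
    np.testing.assert_array_equal(cat.block_columns("B"), [2, 3, 4])
    back = features.without_blocks(cat, ["B"])
    np.testing.assert_array_equal(back.values, A.values)
    assert back.feature_names == A.feature_names


def test_concat_single_matrix_is_identity(rng):
    A = _fm(rng.standard_normal((5, 2)))
    cat = features.concat_features([("A", A)])
    np.testing.assert_array_equal(cat.values, A.values)


def test_concat_time_mismatch_raises(rng):
    A = _fm(rng.standard_normal((5, 2)))
    B = _fm(rng.standard_normal((6, 2)))
    with pytest.raises(ValueError, match="T="):
        features.concat_features([("A", A), ("B", B)])


def test_delayed_block_columns_span_all_delays(rng):
    A = _fm(rng.standard_normal((10, 2)))
    B = _fm(rng.standard_normal((10, 3)))
    cat = features.concat_features([("A", A), ("B", B)])
    d = features.delay_embed(cat)
    cols = d.block_columns("B")
    np.testing.assert_array_equal(cols, [2, 3, 4, 7, 8, 9, 12, 13, 14])
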