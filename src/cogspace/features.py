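"""Model feature matrices and their hemodynamic delay embeddings.

Every encoding/decoding model is a ``[T x N]`` feature matrix sharing the
response time grid.  The finite-impulse-response embedding duplicates the
columns at temporal delays of 2, 4 and 6 s (``[T x 3N]``), shifting within
each run and zero-padding at run starts so that no feature bleeds across a
run boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import NO_TASK, ExperimentDesign

#: hemodynamic delays applied to every feature column, seconds
DEFAULT_DELAYS_S = (2.0, 4.0, 6.0)


@dataclass
class FeatureMatrix:
    """Time-by-feature matrix on the response grid.

    ``blocks`` records column provenance as ``(name, n_columns)`` pairs in
    column order, so that nuisance blocks concatenated for training can be
    removed symmetrically (features and weights) at test time.
    """

    values: np.ndarray
    feature_names: list[str]
    tr: float
    run_slices: list[tuple[int, int]]
    blocks: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (time x feature)")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match column count")
        T = self.values.shape[0]
        edges = sorted(self.run_slices)
        if not edges or edges[0][0] != 0 or edges[-1][1] != T:
            raise ValueError("run_slices must partition [0, T)")
        for (a0, a1), (b0, _b1) in zip(edges, edges[1:]):
            if a1 != b0:
                raise ValueError("run_slices must be contiguous")
        if self.blocks is not None and sum(n for _, n in self.blocks) != self.values.shape[1]:
            raise ValueError("block sizes must sum to the column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block_columns(self, name: str) -> np.ndarray:
        """Column indices belonging to the named block."""
        if self.blocks is None:
            raise ValueError("feature matrix has no block provenance")
        start = 0
        for bname, n in self.blocks:
            if bname == name:
                return np.arange(start, start + n)
            start += n
        raise KeyError(f"no block named {name!r}")


@dataclass
class DelayedFeatureMatrix(FeatureMatrix):
    """FIR-embedded features: one column block per delay, ``[T x d*N]``.

    Column block ``b`` at sample ``t`` equals the parent column at sample
    ``t - delays_s[b]/tr`` within the same run, and zero where that index
    precedes the run start.
    """

    delays_s: tuple[float, ...] = DEFAULT_DELAYS_S
    parent_names: list[str] = field(default_factory=list)
    parent_blocks: list[tuple[str, int]] | None = None

    @property
    def n_delays(self) -> int:
        return len(self.delays_s)

    @property
    def n_parent_features(self) -> int:
        return len(self.parent_names)

    def block_columns(self, name: str) -> np.ndarray:
        """Indices of the named parent block within every delay block."""
        if self.parent_blocks is None:
            raise ValueError("delayed matrix has no block provenance")
        start = 0
        cols = None
        for bname, n in self.parent_blocks:
            if bname == name:
                cols = np.arange(start, start + n)
                break
            start += n
        if cols is None:
            raise KeyError(f"no block named {name!r}")
        N = self.n_parent_features
        return np.concatenate([cols + d * N for d in range(self.n_delays)])


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------


def task_onehot(design: ExperimentDesign, portion: str = "train") -> FeatureMatrix:
    """One-hot task indicators: entry ``(t, k)`` is 1 iff task ``k`` occupies
    bin ``t``.  Feedback and rest bins are all-zero rows."""
    timeline = design.timeline(portion)
    T = timeline.size
    values = np.zeros((T, design.n_tasks))
    active = timeline != NO_TASK
    values[np.flatnonzero(active), timeline[active]] = 1.0
    return FeatureMatrix(
        values=values,
        feature_names=list(design.task_names),
        tr=design.tr,
        run_slices=design.portion_slices(portion),
        blocks=[("task", design.n_tasks)],
    )


def delay_embed(
    f: FeatureMatrix, delays_s: tuple[float, ...] = DEFAULT_DELAYS_S
) -> DelayedFeatureMatrix:
    """Concatenate copies of ``f`` shifted by each hemodynamic delay.

    Shifting is per run; samples shifted in from beyond a run boundary are
    zero-padded so the output keeps the parent's ``T``.  Positive delays
    shift content forward in time (encoding: the response lags the feature);
    negative delays shift backward (decoding: the feature at ``t`` is read
    from responses after ``t``).
    """
    shifts = []
    for d in delays_s:
        k = d / f.tr
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"tr={f.tr} s does not divide delay {d} s")
        shifts.append(int(round(k)))
    T, N = f.values.shape
    out = np.zeros((T, len(shifts) * N))
    for b, k in enumerate(shifts):
        dst = out[:, b * N : (b + 1) * N]
        for r0, r1 in f.run_slices:
            if abs(k) >= r1 - r0:
                continue
            if k >= 0:
                dst[r0 + k : r1] = f.values[r0 : r1 - k]
            else:
                dst[r0 : r1 + k] = f.values[r0 - k : r1]
    names = [
        f"{name}@{d:g}s" for d in delays_s for name in f.feature_names
    ]
    return DelayedFeatureMatrix(
        values=out,
        feature_names=names,
        tr=f.tr,
        run_slices=list(f.run_slices),
        blocks=None,
        delays_s=tuple(delays_s),
        parent_names=list(f.feature_names),
        parent_blocks=list(f.blocks) if f.blocks is not None else None,
    )


def hierarchical_features(
    design: ExperimentDesign, merge_tree, portion: str = "train"
) -> FeatureMatrix:
    """Binary indicators of the non-terminal nodes of a task dendrogram.

    Column ``j`` is 1 at bin ``t`` iff the task occupying ``t`` is a
    descendant leaf of internal node ``j`` (merge order).  A tree over ``n``
    tasks yields ``n - 1`` columns.
    """
    if merge_tree.n_leaves != design.n_tasks:
        raise ValueError(
            f"tree has {merge_tree.n_leaves} leaves but design has "
            f"{design.n_tasks} tasks"
        )
    onehot = task_onehot(design, portion)
    leaf_sets = merge_tree.leaf_sets()
    values = np.zeros((onehot.n_samples, len(leaf_sets)))
    for j, leaves in enumerate(leaf_sets):
        values[:, j] = onehot.values[:, sorted(leaves)].sum(axis=1)
    np.clip(values, 0.0, 1.0, out=values)
    return FeatureMatrix(
        values=values,
        feature_names=[f"node{j}" for j in range(len(leaf_sets))],
        tr=design.tr,
        run_slices=onehot.run_slices,
        blocks=[("hierarchy", len(leaf_sets))],
    )


def ctf_features(f_task: FeatureMatrix, ctf) -> FeatureMatrix:
    """Project one-hot task features into the latent cognitive-factor space.

    ``values = f_task.values @ ctf.values`` (time x term): each task-active
    bin becomes that task's row of the cognitive transform function.
    """
    C = np.asarray(ctf.values, dtype=float)
    if C.shape[0] != f_task.n_features:
        raise ValueError(
            f"CTF task dimension {C.shape[0]} != feature count "
            f"{f_task.n_features}"
        )
    return FeatureMatrix(
        values=f_task.values @ C,
        feature_names=list(ctf.term_names),
        tr=f_task.tr,
        run_slices=list(f_task.run_slices),
        blocks=[("cogfactor", C.shape[1])],
    )


def button_features(design: ExperimentDesign, portion: str = "train") -> FeatureMatrix:
    """Per-bin button-press counts for the four buttons.

    Per-second counts are summed within each TR bin so the button regressors
    share the response time base.
    """
    runs = {"train": design.train_runs, "test": design.test_runs, "all": design.runs}[
        portion
    ]
    tr_int = design.tr
    per_run = []
    for run in runs:
        T = run.n_samples(tr_int)
        out = np.zeros((T, 4))
        if run.button_counts is not None:
            counts = np.asarray(run.button_counts, dtype=float)
            sec_of_bin = (np.arange(counts.shape[1]) / tr_int).astype(int)
            for t in range(T):
                out[t] = counts[:, sec_of_bin == t].sum(axis=1)
        per_run.append(out)
    values = (
        np.concatenate(per_run, axis=0) if per_run else np.zeros((0, 4))
    )
    return FeatureMatrix(
        values=values,
        feature_names=[f"button{i + 1}" for i in range(4)],
        tr=design.tr,
        run_slices=design.portion_slices(portion),
        blocks=[("button", 4)],
    )


def concat_features(named: list[tuple[str, FeatureMatrix]]) -> FeatureMatrix:
    """Column-wise concatenation with block provenance.

    All inputs must share ``T``, TR and run boundaries.  The result records
    one block per input so nuisance blocks can later be dropped.
    """
    if not named:
        raise ValueError("nothing to concatenate")
    first = named[0][1]
    for name, fm in named[1:]:
        if fm.n_samples != first.n_samples:
            raise ValueError(
                f"block {name!r}: T={fm.n_samples} != {first.n_samples}"
            )
        if fm.tr != first.tr or list(fm.run_slices) != list(first.run_slices):
            raise ValueError(f"block {name!r}: time grid mismatch")
    return FeatureMatrix(
        values=np.concatenate([fm.values for _, fm in named], axis=1),
        feature_names=[n for _, fm in named for n in fm.feature_names],
        tr=first.tr,
        run_slices=list(first.run_slices),
        blocks=[(name, fm.n_features) for name, fm in named],
    )


def without_blocks(f: FeatureMatrix, drop: list[str]) -> FeatureMatrix:
    """Remove the named blocks, keeping the remaining columns in order."""
    if f.blocks is None:
        raise ValueError("feature matrix has no block provenance")
    keep_cols, keep_blocks, keep_names, start = [], [], [], 0
    for bname, n in f.blocks:
        if bname not in drop:
            keep_cols.extend(range(start, start + n))
            keep_blocks.append((bname, n))
            keep_names.extend(f.feature_names[start : start + n])
        start += n
    if not keep_cols:
        raise ValueError("dropping all blocks leaves no features")
    return replace(
        f,
        values=f.values[:, keep_cols],
        feature_names=keep_names,
        blocks=keep_blocks,
    )
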