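"""Metadata-based reverse inference and the cognitive transform function.

A term atlas holds one meta-analytic reverse-inference map per cognitive
term, registered to a subject's voxel space.  Correlating a weight map with
every term map ranks the cognitive factors behind it; doing so for every
task's delay-averaged weight map yields the cognitive transform function
(CTF), the task-by-term correlation matrix that maps binary task labels
into the continuous latent factor space.  For generalization analyses the
CTF of a target subject is the element-wise mean of the other subjects'
matrices, so it never uses the target's own data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TermAtlas:
    """Term-by-voxel reverse-inference maps in one voxel space."""

    term_names: list[str]
    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be term x voxel")
        if len(self.term_names) != self.maps.shape[0]:
            raise ValueError("term_names length must match map count")
        if self.maps.shape[0] < 1:
            raise ValueError("need at least one term")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("term maps must be finite")
        if np.any(self.maps.std(axis=1) == 0):
            raise ValueError("term maps must be non-constant")

    @property
    def n_terms(self) -> int:
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]

    def restrict(self, voxel_idx: np.ndarray) -> "TermAtlas":
        """Atlas restricted to a voxel subset (e.g. predictive voxels)."""
        return TermAtlas(list(self.term_names), self.maps[:, voxel_idx])


@dataclass
class TransformMatrix:
    """The CTF: task-by-term correlations."""

    values: np.ndarray
    task_names: list[str]
    term_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("CTF must be task x term")
        if self.values.shape != (len(self.task_names), len(self.term_names)):
            raise ValueError("CTF shape must match task and term name counts")
        finite = self.values[np.isfinite(self.values)]
        if np.any(np.abs(finite) > 1 + 1e-9):
            raise ValueError("CTF entries must lie in [-1, 1]")

    @property
    def n_tasks(self) -> int:
        return self.values.shape[0]

    @property
    def n_terms(self) -> int:
        return self.values.shape[1]


def rowwise_correlation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``A`` with every row of ``B``.

    Rows are centered over the shared voxel axis; zero-variance rows give
    NaN.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[-1] != B.shape[-1]:
        raise ValueError(
            f"voxel spaces differ: {A.shape[-1]} vs {B.shape[-1]}"
        )
    Ac = A - A.mean(axis=-1, keepdims=True)
    Bc = B - B.mean(axis=-1, keepdims=True)
    na = np.linalg.norm(Ac, axis=-1)
    nb = np.linalg.norm(Bc, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ Bc.T) / np.outer(na, nb)
    r[na == 0, :] = np.nan
    r[:, nb == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def rank_terms(
    weight_map: np.ndarray, atlas: TermAtlas, top_k: int = 10
) -> list[tuple[str, float]]:
    """Rank atlas terms by their correlation with a weight map.

    Terms with higher correlation are taken to contribute more to the map;
    the top ``top_k`` are returned as ``(term, r)`` pairs in descending
    order.
    """
    w = np.asarray(weight_map, dtype=float).reshape(1, -1)
    r = rowwise_correlation(w, atlas.maps)[0]
    order = np.argsort(-r)
    return [(atlas.term_names[i], float(r[i])) for i in order[:top_k]]


def build_ctf(
    task_maps: np.ndarray,
    atlas: TermAtlas,
    task_names: list[str] | None = None,
) -> TransformMatrix:
    """Correlate every task's weight map with every term map.

    ``task_maps`` holds one delay-averaged weight map per row, in the same
    voxel space as the atlas.  Row ``k`` of the result is task ``k``'s
    715-dimensional (in general, ``n_terms``-dimensional) cognitive factor
    vector.
    """
    task_maps = np.asarray(task_maps, dtype=float)
    if task_maps.ndim != 2:
        raise ValueError("task_maps must be task x voxel")
    values = rowwise_correlation(task_maps, atlas.maps)
    names = task_names or [f"task{k:03d}" for k in range(task_maps.shape[0])]
    return TransformMatrix(values, names, list(atlas.term_names))


def loso_ctf(ctfs: list[TransformMatrix], target: int) -> TransformMatrix:
    """Leave-one-subject-out CTF: mean over all subjects except ``target``.

    The result is independent of the target subject's own data.
    """
    if len(ctfs) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    if not 0 <= target < len(ctfs):
        raise ValueError(f"target {target} out of range")
    others = [c for i, c in enumerate(ctfs) if i != target]
    shape = others[0].values.shape
    for c in others:
        if c.values.shape != shape:
            raise ValueError("all CTFs must share shape")
    mean = np.mean([c.values for c in others], axis=0)
    return TransformMatrix(
        mean, list(others[0].task_names), list(others[0].term_names)
    )


def subject_task_maps(weights, accuracy) -> tuple[np.ndarray, np.ndarray]:
    """Delay-averaged task weight maps over a subject's predictive voxels.

    Returns the ``[n_tasks, n_significant]`` maps and the significant-voxel
    indices (use them to restrict the atlas to the same voxel subset).
    """
    sig = np.flatnonzero(np.asarray(accuracy.significant, dtype=bool))
    if sig.size == 0:
        raise ValueError("subject has no significant voxels")
    return weights.delay_averaged[:, sig], sig
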