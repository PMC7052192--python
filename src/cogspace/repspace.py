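"""Representational similarity, hierarchical clustering and group PCA.

The representational similarity matrix (RSM) holds Pearson correlations
between the voxel-wise weight patterns of every pair of tasks.  Tasks are
agglomerated with single linkage on the dissimilarity ``1 - r`` ("minimum
distance" linkage), and the group weight matrix is decomposed with PCA to map
the task space onto a small number of cortical components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class RSM:
    """Task-by-task correlation matrix of weight (or activity) patterns."""

    values: np.ndarray
    task_names: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RSM must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("RSM must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("RSM entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_tasks(self) -> int:
        return self.values.shape[0]


@dataclass
class MergeTree:
    """Agglomeration history: ordered merges ``(node_a, node_b, height)``.

    Leaves are numbered ``0 .. n_leaves-1``; merge ``i`` creates internal
    node ``n_leaves + i``.  With single linkage the heights are
    non-decreasing over merges.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int
    leaf_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError(
                f"expected {self.n_leaves - 1} merges, got {len(self.merges)}"
            )

    @property
    def n_internal(self) -> int:
        return len(self.merges)

    def leaf_sets(self) -> list[frozenset[int]]:
        """Descendant-leaf set of each internal node, in merge order."""
        sets: dict[int, frozenset[int]] = {
            i: frozenset([i]) for i in range(self.n_leaves)
        }
        out = []
        for m, (a, b, _h) in enumerate(self.merges):
            s = sets[a] | sets[b]
            sets[self.n_leaves + m] = s
            out.append(s)
        return out

    def cut(self, k: int) -> np.ndarray:
        """Partition the leaves into ``k`` clusters.

        Removes the ``k - 1`` highest merges (the last ones, since heights
        are non-decreasing) and labels the resulting subtrees ``0 .. k-1``
        in order of their lowest leaf index.
        """
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k must be in [1, n_leaves]")
        parent = np.arange(self.n_leaves)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        node_rep = {i: i for i in range(self.n_leaves)}
        for m, (a, b, _h) in enumerate(self.merges[: self.n_leaves - k]):
            ra, rb = find(node_rep[a]), find(node_rep[b])
            parent[rb] = ra
            node_rep[self.n_leaves + m] = ra
        roots = np.array([find(i) for i in range(self.n_leaves)])
        labels = np.zeros(self.n_leaves, dtype=np.int64)
        seen: dict[int, int] = {}
        for i, r in enumerate(roots):
            if r not in seen:
                seen[r] = len(seen)
            labels[i] = seen[r]
        return labels

    def heights(self) -> np.ndarray:
        return np.array([h for _a, _b, h in self.merges])

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        names = self.leaf_names or [f"task{i}" for i in range(self.n_leaves)]
        height = {i: 0.0 for i in range(self.n_leaves)}
        text = {i: names[i] for i in range(self.n_leaves)}
        for m, (a, b, h) in enumerate(self.merges):
            node = self.n_leaves + m
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
            height[node] = h
        root = self.n_leaves + self.n_internal - 1 if self.merges else 0
        return text[root] + ";"


@dataclass
class PcaResult:
    """Group PCA of the task-by-voxel weight matrix.

    ``task_loadings[k, c]`` is task ``k``'s coordinate on component ``c``
    (scaled by the singular value); ``voxel_scores[v, c]`` is the unit-norm
    cortical axis of component ``c``.
    """

    task_loadings: np.ndarray
    voxel_scores: np.ndarray
    explained_variance_fraction: np.ndarray
    task_names: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.task_loadings.shape[1]

    def meaningful_components(self, threshold: float = 0.05) -> np.ndarray:
        """Indices of components explaining more than ``threshold`` variance."""
        return np.flatnonzero(self.explained_variance_fraction > threshold)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def group_weights(fits: list[tuple]) -> np.ndarray:
    """Concatenate per-subject delay-averaged weights over predictive voxels.

    Parameters
    ----------
    fits
        One ``(WeightTensor, AccuracyMap)`` pair per subject.  For each
        subject only voxels with FDR-significant prediction accuracy are
        kept; the three delay slices are averaged; subjects are concatenated
        along the voxel axis.

    Returns
    -------
    ndarray of shape ``[n_tasks, total_significant_voxels]``
    """
    if not fits:
        raise ValueError("at least one subject fit is required")
    parts = []
    for s, (weights, acc) in enumerate(fits):
        sig = np.asarray(acc.significant, dtype=bool)
        if not sig.any():
            raise ValueError(f"subject {s}: no significant voxels to pool")
        parts.append(weights.delay_averaged[:, sig])
    return np.concatenate(parts, axis=1)


def rsm(task_by_voxel: np.ndarray, task_names: list[str] | None = None) -> RSM:
    """Pearson correlation between the voxel patterns of every task pair."""
    M = np.asarray(task_by_voxel, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a task x voxel matrix with >= 2 voxels")
    sd = M.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance task rows: {bad.tolist()}")
    r = np.corrcoef(M)
    return RSM(np.clip(r, -1.0, 1.0), task_names)


def hca(similarity: RSM | np.ndarray) -> MergeTree:
    """Single-linkage agglomeration on the dissimilarity ``1 - r``.

    At every step the pair of clusters with the smallest inter-cluster
    minimum distance is merged; distance ties are broken by the lowest
    (node_a, node_b) id pair, which for leaves is the lowest task index.
    """
    if isinstance(similarity, RSM):
        names = similarity.task_names
        R = similarity.values
    else:
        names = None
        R = np.asarray(similarity, dtype=float)
    n = R.shape[0]
    if n < 2:
        raise ValueError("need at least two tasks")
    size = 2 * n - 1
    D = np.full((size, size), np.inf)
    D[:n, :n] = 1.0 - R
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    for m in range(n - 1):
        best: tuple[float, int, int] | None = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                key = (D[a, b], a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best  # type: ignore[misc]
        new = n + m
        merges.append((a, b, float(d)))
        for c in active:
            if c not in (a, b):
                nd = min(D[a, c], D[b, c])
                D[new, c] = D[c, new] = nd
        active = [c for c in active if c not in (a, b)] + [new]
    return MergeTree(merges, n, names)


def cut_clusters(tree: MergeTree, k: int) -> np.ndarray:
    """Task-to-cluster labels from the ``k`` subtrees below the top merges."""
    return tree.cut(k)


def group_pca(task_by_voxel: np.ndarray, task_names: list[str] | None = None) -> PcaResult:
    """PCA of the task-centered group weight matrix.

    Tasks are the observations: the mean weight map over tasks is removed and
    the centered matrix is decomposed by SVD.  No variance scaling is applied
    (weights share units).  Component signs are pinned so that the
    largest-magnitude task loading of each component is positive.
    """
    M = np.asarray(task_by_voxel, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need >= 2 tasks and >= 2 voxels")
    Mc = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("weight matrix has rank 0 after centering")
    loadings = U * s
    for c in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, c]))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1
            Vt[c] *= -1
    return PcaResult(
        task_loadings=loadings,
        voxel_scores=Vt.T,
        explained_variance_fraction=s**2 / total,
        task_names=task_names,
    )


def cluster_loading_test(
    pca: PcaResult,
    cluster_of_task: np.ndarray,
    top_m: int = 4,
    q: float = 0.05,
    low_power_size: int = 5,
) -> pd.DataFrame:
    """Two-sided sign tests of cluster-mean loadings against zero.

    For each (cluster, component) pair among the top ``top_m`` components,
    the member tasks' loadings are sign-tested against zero and the p-values
    are Benjamini-Hochberg corrected across all pairs.  Clusters smaller than
    ``low_power_size`` are flagged as low-power.
    """
    cluster_of_task = np.asarray(cluster_of_task)
    clusters = np.unique(cluster_of_task)
    top_m = min(top_m, pca.n_components)
    rows = []
    for c in clusters:
        members = np.flatnonzero(cluster_of_task == c)
        if members.size == 0:
            raise ValueError(f"cluster {c} has no tasks")
        for comp in range(top_m):
            x = pca.task_loadings[members, comp]
            n_pos = int((x > 0).sum())
            n_neg = int((x < 0).sum())
            if n_pos + n_neg == 0:
                p = 1.0
            else:
                p = stats.binomtest(
                    n_pos, n_pos + n_neg, 0.5, alternative="two-sided"
                ).pvalue
            rows.append(
                dict(
                    cluster=int(c),
                    component=comp,
                    mean_loading=float(x.mean()),
                    n_pos=n_pos,
                    n_neg=n_neg,
                    p=float(p),
                    low_power=members.size < low_power_size,
                )
            )
    table = pd.DataFrame(rows)
    reject, _, _, _ = multipletests(table["p"].to_numpy(), alpha=q, method="fdr_bh")
    table["significant"] = reject
    return table


def _normalize_channels(X: np.ndarray, pct: tuple[float, float]) -> np.ndarray:
    lo = np.percentile(X, pct[0], axis=0)
    hi = np.percentile(X, pct[1], axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.clip((X - lo) / span, 0.0, 1.0)


@dataclass
class RgbEmbedding:
    """Tasks and voxels colored by the top three components."""

    task_rgb: np.ndarray
    task_xy: np.ndarray
    voxel_rgb: np.ndarray


def rgb_embed(pca: PcaResult, pct: tuple[float, float] = (1.0, 99.0)) -> RgbEmbedding:
    """Map the top three components to RGB and the top two to 2-D positions.

    Each color channel is affinely mapped by its 1st-99th percentile range to
    ``[0, 1]`` and clipped; task colors use task loadings, voxel colors use
    voxel scores.
    """
    if pca.n_components < 3:
        raise ValueError("need at least three components for RGB embedding")
    return RgbEmbedding(
        task_rgb=_normalize_channels(pca.task_loadings[:, :3], pct),
        task_xy=pca.task_loadings[:, :2].copy(),
        voxel_rgb=_normalize_channels(pca.voxel_scores[:, :3], pct),
    )
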