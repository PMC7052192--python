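"""Temporal detrending, voxel normalization and test-run reshaping.

Preprocessing is scoped per run: low-frequency drift is removed with a
running median (240-s window), each voxel is z-scored within the run, and the
test runs are reshaped into repeats of the fixed task block and averaged to
raise the signal-to-noise ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .design import ExperimentDesign

logger = logging.getLogger(__name__)

#: running-median window for drift removal, seconds
DETREND_WINDOW_S = 240.0


@dataclass
class ResponseMatrix:
    """Voxel-by-time responses, possibly concatenated across runs."""

    values: np.ndarray
    tr: float
    run_slices: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("responses must be 2-D (voxel x time)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("responses must be finite")
        if not self.run_slices:
            self.run_slices = [(0, self.values.shape[1])]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def concat_runs(runs: list[ResponseMatrix]) -> ResponseMatrix:
    """Concatenate per-run response matrices along time."""
    if not runs:
        raise ValueError("no runs to concatenate")
    V = runs[0].n_voxels
    tr = runs[0].tr
    for r in runs:
        if r.n_voxels != V or r.tr != tr:
            raise ValueError("runs must share voxel count and TR")
    slices, start = [], 0
    for r in runs:
        slices.append((start, start + r.n_samples))
        start += r.n_samples
    return ResponseMatrix(
        np.concatenate([r.values for r in runs], axis=1), tr, slices
    )


def _odd_window(window_s: float, tr: float, run_len: int) -> int:
    w = int(round(window_s / tr))
    if w > run_len:
        logger.warning(
            "median window (%d samples) exceeds run length (%d); "
            "falling back to run-length window",
            w,
            run_len,
        )
        w = run_len
    if w % 2 == 0:
        w += 1 if w < run_len else -1
    return max(w, 3)


def detrend_median(
    r: ResponseMatrix, window_s: float = DETREND_WINDOW_S
) -> ResponseMatrix:
    """Subtract a per-voxel running median computed within each run.

    Window edges are handled by reflection; the window in samples is
    ``round(window_s / tr)`` forced odd (121 samples at TR = 2 s).
    """
    out = np.empty_like(r.values)
    for r0, r1 in r.run_slices:
        seg = r.values[:, r0:r1]
        w = _odd_window(window_s, r.tr, r1 - r0)
        baseline = median_filter(seg, size=(1, w), mode="reflect")
        out[:, r0:r1] = seg - baseline
    return ResponseMatrix(out, r.tr, list(r.run_slices))


def zscore_voxels(
    r: ResponseMatrix, eps: float = 1e-12
) -> tuple[ResponseMatrix, np.ndarray]:
    """Z-score each voxel within each run.

    Returns the normalized responses and a boolean mask of voxels with
    positive variance in every run; zero-variance voxels are set to zero and
    flagged for exclusion from modeling.
    """
    out = np.empty_like(r.values)
    valid = np.ones(r.n_voxels, dtype=bool)
    for r0, r1 in r.run_slices:
        seg = r.values[:, r0:r1]
        mu = seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1, keepdims=True)
        ok = sd[:, 0] > eps
        valid &= ok
        sd[~ok] = 1.0
        out[:, r0:r1] = (seg - mu) / sd
    out[~valid] = 0.0
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("excluded %d zero-variance voxels", n_bad)
    return ResponseMatrix(out, r.tr, list(r.run_slices)), valid


def reshape_test_runs(
    test_runs: list[ResponseMatrix], design: ExperimentDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Reshape the test runs into repeats of the fixed task block.

    For each test run, the trailing ``n_discard_end`` samples (end-of-run
    rest and, where present, the trailing feedback sample) are dropped; the
    retained samples are concatenated and split into ``design.test_repeats``
    equal-length repeats, which are then averaged.

    Returns
    -------
    repeats : ndarray ``[n_repeats, n_voxels, block_len]``
    averaged : ndarray ``[n_voxels, block_len]``
    """
    design_tests = design.test_runs
    if len(test_runs) != len(design_tests):
        raise ValueError(
            f"{len(test_runs)} response runs but design has "
            f"{len(design_tests)} test runs"
        )
    if design.test_repeats < 1:
        raise ValueError("design has no test repeats")
    kept = []
    for rm, drun in zip(test_runs, design_tests):
        n = rm.n_samples
        if drun.n_samples(design.tr) != n:
            raise ValueError("response run length does not match design")
        kept.append(rm.values[:, : n - drun.n_discard_end])
    data = np.concatenate(kept, axis=1)
    R = design.test_repeats
    B = design.test_block_len
    if data.shape[1] != R * B:
        raise ValueError(
            f"retained test samples ({data.shape[1]}) != repeats ({R}) x "
            f"block length ({B})"
        )
    repeats = np.stack([data[:, i * B : (i + 1) * B] for i in range(R)])
    return repeats, repeats.mean(axis=0)


def average_test_timecourses(
    values: np.ndarray, design: ExperimentDesign
) -> np.ndarray:
    """Average any time-major test-run series over the repeat blocks.

    ``values`` is ``[T_test, C]`` over the concatenated physical test runs
    (responses, features, or predictions); the same per-run end discards and
    repeat splitting as :func:`reshape_test_runs` are applied.  Averaging a
    linear model's inputs this way equals averaging its outputs, so
    predictions can be compared to the repeat-averaged measurements while
    keeping the hemodynamic carry-over between consecutive repeats that the
    physical runs contain.
    """
    runs = []
    start = 0
    for drun in design.test_runs:
        n = drun.n_samples(design.tr)
        runs.append(ResponseMatrix(values[start : start + n].T, design.tr))
        start += n
    if start != values.shape[0]:
        raise ValueError(
            f"series length {values.shape[0]} does not match the "
            f"{start} test samples of the design"
        )
    _repeats, avg = reshape_test_runs(runs, design)
    return avg.T
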