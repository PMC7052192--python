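"""Experiment designs: runs of timed task trials with feedback and button events.

The temporal grid is set by the repetition time (TR).  Time bin ``t`` covers
``[t*tr, (t+1)*tr)`` seconds within its run, and a trial occupies every bin
whose start lies in ``[onset, onset + duration)``.  Onsets and durations are
kept in seconds; all conversions to sample indices happen here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: duration of the post-trial feedback display, seconds
FEEDBACK_DURATION_S = 2.0
#: task-free imaging at the start and end of every run, seconds
EDGE_PAD_S = 6.0
#: timeline value marking bins with no task
NO_TASK = -1

_EPS = 1e-9


@dataclass(frozen=True)
class Trial:
    """A single task presentation."""

    task: int
    onset: float
    duration: float

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class Run:
    """One continuous acquisition: trials, feedback events and button presses.

    Parameters
    ----------
    duration
        Run length in seconds; must be an integer multiple of the TR.
    trials
        Ordered, non-overlapping task presentations.
    feedback_onsets
        Onsets (s) of the 2-s feedback displays.
    button_counts
        ``[4, int(duration)]`` per-second press counts for the four buttons.
    is_test
        Whether this run belongs to the test portion of the experiment.
    n_discard_end
        Samples dropped from the end of this run when the test portion is
        reshaped into repeats (end-of-run rest plus, for some runs, a trailing
        feedback sample).
    """

    duration: float
    trials: list[Trial] = field(default_factory=list)
    feedback_onsets: list[float] = field(default_factory=list)
    button_counts: np.ndarray | None = None
    is_test: bool = False
    n_discard_end: int = 0

    def n_samples(self, tr: float) -> int:
        return int(round(self.duration / tr))


def _bin_range(onset: float, duration: float, tr: float) -> tuple[int, int]:
    """Half-open bin range occupied by an event of given onset/duration."""
    b0 = int(np.ceil(onset / tr - _EPS))
    b1 = int(np.ceil((onset + duration) / tr - _EPS))
    return b0, b1


def run_timeline(run: Run, tr: float) -> np.ndarray:
    """Per-sample task id for one run (``NO_TASK`` for task-free bins)."""
    out = np.full(run.n_samples(tr), NO_TASK, dtype=np.int64)
    for trial in run.trials:
        b0, b1 = _bin_range(trial.onset, trial.duration, tr)
        out[b0:b1] = trial.task
    return out


@dataclass
class ExperimentDesign:
    """A full multi-run experiment for one cohort.

    Training runs present tasks in pseudorandom order; test runs repeat a
    fixed task sequence (the *test block*) so that, after dropping each test
    run's ``n_discard_end`` trailing samples, the concatenated test timeline
    is exactly ``test_repeats`` copies of ``test_block``.
    """

    runs: list[Run]
    tr: float
    n_tasks: int
    task_names: list[str]
    test_repeats: int = 0
    test_block: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.n_tasks <= 0:
            raise ValueError("n_tasks must be positive")
        if len(self.task_names) != self.n_tasks:
            raise ValueError("task_names length must equal n_tasks")
        for i, run in enumerate(self.runs):
            n = run.duration / self.tr
            if abs(n - round(n)) > _EPS:
                raise ValueError(
                    f"run {i}: duration {run.duration} s is not a multiple "
                    f"of tr={self.tr} s"
                )
            prev_end = -_EPS
            for trial in run.trials:
                if trial.task < 0 or trial.task >= self.n_tasks:
                    raise ValueError(
                        f"run {i}: task id {trial.task} out of range"
                    )
                if trial.onset < prev_end - _EPS:
                    raise ValueError(
                        f"run {i}: trials overlap or are unordered at "
                        f"onset {trial.onset}"
                    )
                if trial.offset > run.duration + _EPS:
                    raise ValueError(
                        f"run {i}: trial at {trial.onset} exceeds run end"
                    )
                prev_end = trial.offset

    # -- run subsets ---------------------------------------------------
    @property
    def train_runs(self) -> list[Run]:
        return [r for r in self.runs if not r.is_test]

    @property
    def test_runs(self) -> list[Run]:
        return [r for r in self.runs if r.is_test]

    # -- sample geometry -----------------------------------------------
    def run_sample_slices(self, runs: list[Run] | None = None) -> list[tuple[int, int]]:
        """(start, stop) sample indices of each run in the concatenated grid."""
        if runs is None:
            runs = self.runs
        slices, start = [], 0
        for run in runs:
            stop = start + run.n_samples(self.tr)
            slices.append((start, stop))
            start = stop
        return slices

    @property
    def n_train_samples(self) -> int:
        return sum(r.n_samples(self.tr) for r in self.train_runs)

    @property
    def n_test_samples(self) -> int:
        return sum(r.n_samples(self.tr) for r in self.test_runs)

    @property
    def test_block_len(self) -> int:
        return int(self.test_block.size)

    def timeline(self, portion: str = "train") -> np.ndarray:
        """Concatenated per-sample task ids for a portion of the design.

        ``portion`` is one of ``'train'``, ``'test'``, ``'all'`` (physical
        runs) or ``'test_block'`` (one repeat of the fixed test sequence).
        """
        if portion == "test_block":
            return self.test_block.copy()
        runs = {
            "train": self.train_runs,
            "test": self.test_runs,
            "all": self.runs,
        }[portion]
        if not runs:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([run_timeline(r, self.tr) for r in runs])

    def portion_slices(self, portion: str = "train") -> list[tuple[int, int]]:
        """Run-boundary slices matching :meth:`timeline` for a portion."""
        if portion == "test_block":
            return [(0, self.test_block_len)]
        runs = {
            "train": self.train_runs,
            "test": self.test_runs,
            "all": self.runs,
        }[portion]
        return self.run_sample_slices(runs)
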