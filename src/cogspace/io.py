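"""Serialization: event tables, array containers, trees and manifests.

Event tables are written in the BIDS events dialect (tab-separated, columns
``onset``, ``duration``, ``trial_type``); arrays go to NumPy ``.npz``
containers with the TR recorded; dendrograms are exported as Newick.
Optional NIfTI ingestion (4-D volume plus mask to voxel-by-time) is
available when nibabel is installed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExperimentDesign, Run, Trial
from .metadata import TermAtlas, TransformMatrix
from .preprocess import ResponseMatrix
from .repspace import MergeTree
from .synthgen import GroundTruth, SubjectData


# ---------------------------------------------------------------------------
# Designs and event tables
# ---------------------------------------------------------------------------


def events_table(design: ExperimentDesign) -> pd.DataFrame:
    """All trials and feedback events as a BIDS-style events table."""
    rows = []
    for i, run in enumerate(design.runs):
        for t in run.trials:
            rows.append(
                dict(
                    run=i,
                    onset=t.onset,
                    duration=t.duration,
                    trial_type=design.task_names[t.task],
                )
            )
        for onset in run.feedback_onsets:
            rows.append(
                dict(run=i, onset=onset, duration=2.0, trial_type="feedback")
            )
    df = pd.DataFrame(rows, columns=["run", "onset", "duration", "trial_type"])
    return df.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)


def design_to_dict(design: ExperimentDesign) -> dict:
    return dict(
        tr=design.tr,
        n_tasks=design.n_tasks,
        task_names=list(design.task_names),
        test_repeats=design.test_repeats,
        test_block=design.test_block.tolist(),
        runs=[
            dict(
                duration=run.duration,
                is_test=run.is_test,
                n_discard_end=run.n_discard_end,
                feedback_onsets=list(run.feedback_onsets),
                trials=[[t.task, t.onset, t.duration] for t in run.trials],
                button_counts=(
                    run.button_counts.tolist()
                    if run.button_counts is not None
                    else None
                ),
            )
            for run in design.runs
        ],
    )


def design_from_dict(d: dict) -> ExperimentDesign:
    runs = [
        Run(
            duration=r["duration"],
            trials=[Trial(int(a), float(b), float(c)) for a, b, c in r["trials"]],
            feedback_onsets=list(r["feedback_onsets"]),
            button_counts=(
                np.asarray(r["button_counts"], dtype=float)
                if r["button_counts"] is not None
                else None
            ),
            is_test=r["is_test"],
            n_discard_end=int(r["n_discard_end"]),
        )
        for r in d["runs"]
    ]
    return ExperimentDesign(
        runs=runs,
        tr=d["tr"],
        n_tasks=d["n_tasks"],
        task_names=list(d["task_names"]),
        test_repeats=int(d["test_repeats"]),
        test_block=np.asarray(d["test_block"], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


def array_digest(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def save_dataset(root: str | Path, cohort: list[SubjectData], config: dict) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    design = cohort[0].design
    (root / "design.json").write_text(json.dumps(design_to_dict(design)))
    events_table(design).to_csv(root / "events.tsv", sep="\t", index=False)
    digests = {}
    for sd in cohort:
        sub = root / f"sub-{sd.subject_id:02d}"
        sub.mkdir(exist_ok=True)
        resp = {f"run{i:02d}": rm.values for i, rm in enumerate(sd.responses)}
        np.savez_compressed(sub / "responses.npz", tr=design.tr, **resp)
        gt = sd.ground_truth
        np.savez_compressed(
            sub / "ground_truth.npz",
            true_weights=gt.true_weights,
            cluster_of_task=gt.cluster_of_task,
            term_maps=gt.term_maps,
            cluster_of_term=gt.cluster_of_term,
            task_latents=gt.task_latents,
            term_latents=gt.term_latents,
            hierarchy_merges=np.array(
                [[a, b, h] for a, b, h in gt.hierarchy.merges]
            ),
        )
        digests[f"sub-{sd.subject_id:02d}"] = array_digest(
            *[rm.values for rm in sd.responses]
        )
    manifest = dict(config=config, n_subjects=len(cohort), digests=digests)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(root: str | Path) -> tuple[list[SubjectData], dict]:
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    design = design_from_dict(json.loads((root / "design.json").read_text()))
    cohort = []
    for s in range(manifest["n_subjects"]):
        sub = root / f"sub-{s:02d}"
        with np.load(sub / "responses.npz") as z:
            tr = float(z["tr"])
            responses = [
                ResponseMatrix(z[k], tr)
                for k in sorted(z.files)
                if k.startswith("run")
            ]
        with np.load(sub / "ground_truth.npz") as z:
            merges = [
                (int(a), int(b), float(h)) for a, b, h in z["hierarchy_merges"]
            ]
            gt = GroundTruth(
                true_weights=z["true_weights"],
                cluster_of_task=z["cluster_of_task"],
                term_maps=z["term_maps"],
                hierarchy=MergeTree(merges, design.n_tasks),
                task_latents=z["task_latents"],
                term_latents=z["term_latents"],
                cluster_of_term=z["cluster_of_term"],
            )
        cohort.append(SubjectData(design, responses, gt, subject_id=s))
    return cohort, manifest


# ---------------------------------------------------------------------------
# Analysis artifacts
# ---------------------------------------------------------------------------


def save_accuracy_table(path: str | Path, acc) -> None:
    pd.DataFrame(
        dict(r=acc.r, p=acc.p, significant=acc.significant.astype(int))
    ).to_csv(path, sep="\t", index_label="voxel")


def save_ctf(path: str | Path, ctf: TransformMatrix) -> None:
    pd.DataFrame(
        ctf.values, index=ctf.task_names, columns=ctf.term_names
    ).to_csv(path, sep="\t", index_label="task")


def load_atlas_table(path: str | Path) -> TermAtlas:
    """Term atlas from a tab-separated term-by-voxel table (rows = terms)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TermAtlas(term_names=[str(t) for t in df.index], maps=df.to_numpy())


def save_newick(path: str | Path, tree: MergeTree) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def nifti_to_response(
    img_path: str | Path, mask_path: str | Path, tr: float
) -> ResponseMatrix:
    """Voxel-by-time responses from a 4-D NIfTI volume and a binary mask."""
    try:
        import nibabel as nib
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("NIfTI ingestion requires nibabel") from err
    img = np.asarray(nib.load(str(img_path)).dataobj)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    if img.ndim != 4:
        raise ValueError("expected a 4-D volume")
    return ResponseMatrix(img[mask], tr)
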