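"""Cohort serialization: HDF5 and per-subject CSV + JSON sidecar dialects.

HDF5 layout: one group per subject holding dataset ``data`` (n_rois x
n_samples) with attrs ``class``, ``fs``; root attrs carry ``roi_labels``.
CSV layout: one ``<subject>.csv`` per subject (rows = samples, columns =
ROIs) plus ``<subject>.json`` with ``subject_id``, ``class_label``, ``fs``,
``roi_labels``.  CSV columns may arrive in any order; they are mapped back
into canonical order via the header labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import CohortDataset, SubjectRecording


class SchemaError(ValueError):
    """Malformed or incomplete cohort metadata."""


def write_cohort_h5(cohort: CohortDataset, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["roi_labels"] = list(cohort.roi_labels)
        for rec in cohort.subjects:
            g = f.create_group(rec.subject_id)
            g.create_dataset("data", data=rec.data)
            g.attrs["class"] = rec.class_label
            g.attrs["fs"] = rec.fs
    return path


def read_cohort_h5(path) -> CohortDataset:
    path = Path(path)
    subjects = []
    with h5py.File(path, "r") as f:
        if "roi_labels" not in f.attrs:
            raise SchemaError("cohort file missing root attribute 'roi_labels'")
        roi_labels = tuple(
            s.decode() if isinstance(s, bytes) else str(s)
            for s in f.attrs["roi_labels"]
        )
        for sid in sorted(f.keys()):
            g = f[sid]
            for attr in ("class", "fs"):
                if attr not in g.attrs:
                    raise SchemaError(f"subject {sid!r} missing attribute {attr!r}")
            subjects.append(
                SubjectRecording(
                    subject_id=sid,
                    class_label=str(g.attrs["class"]),
                    fs=float(g.attrs["fs"]),
                    data=np.asarray(g["data"]),
                    roi_labels=roi_labels,
                )
            )
    return CohortDataset(subjects=subjects, roi_labels=roi_labels)


def write_cohort_csv(cohort: CohortDataset, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in cohort.subjects:
        df = pd.DataFrame(rec.data.T, columns=list(rec.roi_labels))
        df.to_csv(directory / f"{rec.subject_id}.csv", index=False, float_format="%.17g")
        meta = {
            "subject_id": rec.subject_id,
            "class_label": rec.class_label,
            "fs": rec.fs,
            "roi_labels": list(rec.roi_labels),
        }
        (directory / f"{rec.subject_id}.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_cohort_csv(directory) -> CohortDataset:
    directory = Path(directory)
    sidecars = sorted(directory.glob("*.json"))
    if not sidecars:
        raise SchemaError(f"no subject sidecar JSON files in {directory}")
    subjects = []
    roi_labels = None
    for sc in sidecars:
        meta = json.loads(sc.read_text())
        for key in ("subject_id", "class_label", "fs", "roi_labels"):
            if key not in meta:
                raise SchemaError(f"sidecar {sc.name} missing field {key!r}")
        labels = tuple(meta["roi_labels"])
        if roi_labels is None:
            roi_labels = labels
        elif labels != roi_labels:
            raise SchemaError("inconsistent roi_labels across sidecars")
        csv_path = directory / f"{meta['subject_id']}.csv"
        if not csv_path.exists():
            raise SchemaError(f"missing data CSV for subject {meta['subject_id']!r}")
        df = pd.read_csv(csv_path)
        if set(df.columns) != set(roi_labels):
            raise SchemaError(
                f"CSV columns of {csv_path.name} do not match roi_labels"
            )
        data = df[list(roi_labels)].to_numpy().T  # reorder into canonical order
        subjects.append(
            SubjectRecording(
                subject_id=meta["subject_id"],
                class_label=meta["class_label"],
                fs=float(meta["fs"]),
                data=data,
                roi_labels=roi_labels,
            )
        )
    return CohortDataset(subjects=subjects, roi_labels=roi_labels)


def write_cohort(cohort: CohortDataset, path) -> Path:
    """Dispatch on suffix: ``.h5``/``.hdf5`` files vs a CSV directory."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return write_cohort_h5(cohort, path)
    return write_cohort_csv(cohort, path)


def read_cohort(path) -> CohortDataset:
    path = Path(path)
    if path.is_dir():
        return read_cohort_csv(path)
    return read_cohort_h5(path)
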