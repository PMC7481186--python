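"""Readers and writers for the pipeline's on-disk formats.

Epochs and beta stacks travel as HDF5 (or NPZ) containers with named
datasets; RDMs as full square CSV matrices with a label header; the
stimulus manifest as CSV.  Round-trips are lossless at the tolerances
stated on each function.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .core import (
    RDM,
    SensorEpochs,
    StimulusItem,
    StimulusSet,
    ValidationError,
)

TRIAL_COLUMNS = ("stimulus_id", "category", "run", "repeat")
MANIFEST_COLUMNS = ("id", "category", "yoke_id", "filename", "tilt_deg")


# ---------------------------------------------------------------------------
# Epoch containers
# ---------------------------------------------------------------------------

def write_epochs(epochs: SensorEpochs, path: str | Path) -> None:
    """Write epochs to ``path`` (.h5/.hdf5 or .npz, chosen by extension)."""
    path = Path(path)
    trials = epochs.trials
    cols = {
        "stimulus_id": trials["stimulus_id"].to_numpy(dtype="U64"),
        "category": (
            trials["category"].to_numpy(dtype="U64")
            if "category" in trials
            else np.full(len(trials), "", dtype="U64")
        ),
        "run": trials["run"].to_numpy(dtype=np.int64),
        "repeat": trials["repeat"].to_numpy(dtype=np.int64),
    }
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=epochs.data)
            f.create_dataset("times_ms", data=epochs.times_ms)
            grp = f.create_group("trials")
            for name, arr in cols.items():
                if arr.dtype.kind in "UO":
                    arr = arr.astype(h5py.string_dtype())
                grp.create_dataset(name, data=arr)
            f.attrs["sample_rate_hz"] = epochs.sample_rate_hz
            f.attrs["feature_space"] = epochs.feature_space
            f.attrs["subject"] = epochs.subject or ""
    elif path.suffix == ".npz":
        np.savez(
            path,
            data=epochs.data,
            times_ms=epochs.times_ms,
            sample_rate_hz=np.array(epochs.sample_rate_hz),
            feature_space=np.array(epochs.feature_space),
            subject=np.array(epochs.subject or ""),
            **{f"trials_{k}": v for k, v in cols.items()},
        )
    else:
        raise ValidationError(f"path: unsupported epoch container suffix {path.suffix!r}")


def read_epochs(path: str | Path) -> SensorEpochs:
    """Read an epoch container written by :func:`write_epochs`.

    Structural problems (e.g. a trial table shorter than the data) raise a
    :class:`ValidationError` naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"])
            times = np.asarray(f["times_ms"])
            trials = pd.DataFrame(
                {
                    name: (
                        np.char.decode(np.asarray(f["trials"][name]).astype("S"), "utf-8")
                        if name in ("stimulus_id", "category")
                        else np.asarray(f["trials"][name])
                    )
                    for name in TRIAL_COLUMNS
                }
            )
            rate = float(f.attrs["sample_rate_hz"])
            space = str(f.attrs.get("feature_space", "sensors"))
            subject = str(f.attrs.get("subject", "")) or None
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            data = f["data"]
            times = f["times_ms"]
            trials = pd.DataFrame(
                {name: f[f"trials_{name}"] for name in TRIAL_COLUMNS}
            )
            rate = float(f["sample_rate_hz"])
            space = str(f["feature_space"])
            subject = str(f["subject"]) or None
    else:
        raise ValidationError(f"path: unsupported epoch container suffix {path.suffix!r}")
    if trials["category"].eq("").all():
        trials = trials.drop(columns=["category"])
    return SensorEpochs(data, times, trials, rate, space, subject)


# ---------------------------------------------------------------------------
# RDM CSV
# ---------------------------------------------------------------------------

def write_rdm(rdm: RDM, path: str | Path) -> None:
    """Write the full square matrix as CSV (labels as header and index)."""
    df = pd.DataFrame(rdm.matrix, index=rdm.labels, columns=rdm.labels)
    df.to_csv(path, float_format="%.17g")
    # stash the metric tag next to the matrix without breaking plain-CSV readers
    with open(path, "a") as fh:
        fh.write(f"# metric: {rdm.metric}\n")


def read_rdm(path: str | Path) -> RDM:
    """Read an RDM CSV.  Round-trips from :func:`write_rdm` are exact to 1e-12.

    Off-diagonal asymmetries up to 1e-8 are averaged away; anything larger
    is an error, as is a non-square matrix or duplicate labels.
    """
    metric = "custom"
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("# metric:"):
            metric = line.split(":", 1)[1].strip()
        else:
            body.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValidationError("labels: row and column labels differ (non-square?)")
    if len(set(labels)) != len(labels):
        raise ValidationError("labels: duplicate labels")
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValidationError("matrix: not square")
    asym = np.max(np.abs(mat - mat.T)) if mat.size else 0.0
    if asym > 1e-8:
        raise ValidationError(f"matrix: asymmetric by {asym:.3g} (> 1e-8)")
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return RDM(mat, labels, metric)


# ---------------------------------------------------------------------------
# Stimulus manifest
# ---------------------------------------------------------------------------

def write_stimulus_manifest(stimuli: StimulusSet, path: str | Path) -> None:
    rows = [
        {
            "id": it.id,
            "category": it.category,
            "yoke_id": it.yoke_id or "",
            "filename": it.filename or "",
            "tilt_deg": it.tilt_deg,
        }
        for it in stimuli.items
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)


def load_stimulus_manifest(
    path: str | Path, image_dir: str | Path | None = None
) -> StimulusSet:
    """Load and validate a stimulus manifest CSV.

    When ``image_dir`` is given, every listed file must exist and decode;
    non-square or non-400x400 images trigger a warning (the canonical
    stimuli are 400x400 crops) but are accepted.
    """
    df = pd.read_csv(path, dtype={"id": str, "category": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest: missing columns {missing}")
    items = []
    for _, row in df.iterrows():
        yoke = row["yoke_id"]
        yoke = None if (pd.isna(yoke) or yoke == "") else str(yoke)
        fname = row["filename"]
        fname = None if (pd.isna(fname) or fname == "") else str(fname)
        items.append(
            StimulusItem(str(row["id"]), str(row["category"]), yoke, fname,
                         float(row["tilt_deg"]))
        )
    stimuli = StimulusSet(items)  # validates yoking, counts, categories
    if image_dir is not None:
        for it in stimuli.items:
            if it.filename is None:
                raise ValidationError(f"manifest: no filename for {it.id!r}")
            p = os.path.join(image_dir, it.filename)
            with Image.open(p) as img:
                w, h = img.size
            if (w, h) != (400, 400):
                warnings.warn(
                    f"image {it.filename!r} is {w}x{h}, expected 400x400",
                    stacklevel=2,
                )
    return stimuli


def load_image(image_dir: str | Path, item: StimulusItem) -> np.ndarray:
    """Decode one stimulus image as a float RGB array in [0, 1]."""
    with Image.open(os.path.join(image_dir, item.filename)) as img:
        return np.asarray(img.convert("RGB"), dtype=float) / 255.0
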