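"""NIfTI / TSV / JSON plumbing shared by the CLI and the pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from crossmorph.preprocess import GMStack
from crossmorph.synthetic import GroundTruth


def save_volume(path, volume: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))


def save_labels(path, labels: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_species_dataset(
    outdir, stack: GMStack, truth: GroundTruth | None = None, name: str = "species"
) -> Path:
    """Persist a GM stack as per-subject NIfTI volumes plus metadata TSV.

    Layout: ``<outdir>/<name>/sub-XXXX_gm.nii.gz``, ``participants.tsv``,
    ``mask.nii.gz`` and, when ground truth is given, ``truth_labels.nii.gz``
    and ``truth.json``.
    """
    root = Path(outdir) / name
    root.mkdir(parents=True, exist_ok=True)
    ids = (
        stack.covariates["subject_id"].tolist()
        if len(stack.covariates)
        else [f"S{i:04d}" for i in range(stack.n_subjects)]
    )
    for i, sid in enumerate(ids):
        save_volume(root / f"sub-{sid}_gm.nii.gz", stack.unmask(stack.data[:, i]), stack.affine)
    save_labels(root / "mask.nii.gz", stack.mask.astype(np.int16), stack.affine)
    if len(stack.covariates):
        stack.covariates.to_csv(root / "participants.tsv", sep="\t", index=False)
    if truth is not None:
        save_labels(root / "truth_labels.nii.gz", truth.label_volume, stack.affine)
        payload = {"parcel_age_slopes": np.asarray(truth.parcel_age_slopes).tolist()}
        if truth.parcel_expansion_factors is not None:
            payload["parcel_expansion_factors"] = np.asarray(
                truth.parcel_expansion_factors
            ).tolist()
        (root / "truth.json").write_text(json.dumps(payload, indent=2))
    return root


def load_species_dataset(root) -> tuple[GMStack, np.ndarray | None]:
    """Rebuild a :class:`GMStack` from a directory written by
    :func:`write_species_dataset`.  Returns (stack, truth labels or None)."""
    root = Path(root)
    covariates = pd.read_csv(root / "participants.tsv", sep="\t")
    mask, affine = load_volume(root / "mask.nii.gz")
    mask = mask > 0
    cols = []
    for sid in covariates["subject_id"]:
        vol, _ = load_volume(root / f"sub-{sid}_gm.nii.gz")
        cols.append(vol[mask])
    data = np.clip(np.column_stack(cols), 0.0, None)
    stack = GMStack(data=data, mask=mask, affine=affine, covariates=covariates)
    truth_path = root / "truth_labels.nii.gz"
    truth = None
    if truth_path.exists():
        truth, _ = load_volume(truth_path)
        truth = truth.astype(np.int32)
    return stack, truth


def write_json(path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
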