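"""Readers and writers for volumes, annotations, and result tables."""

from __future__ import annotations

import json
import logging
import re
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .boundaries import AnnotationSet, RaterAnnotation
from .pipeline import AnticipationMap, Searchlight
from .synthetic import SyntheticVolume

logger = logging.getLogger(__name__)

__all__ = [
    "BoldDataset",
    "read_bold_dataset",
    "write_synthetic_dataset",
    "read_annotations",
    "write_annotations",
    "write_map",
    "read_map",
    "write_searchlight_table",
]

_BOLD_RE = re.compile(r"sub-(?P<sub>[^_]+)_view-(?P<view>\d+)_bold\.nii(\.gz)?$")


@dataclass
class BoldDataset:
    """In-memory multi-subject, multi-viewing BOLD collection.

    ``bold[subject][viewing]`` is a 4D (x, y, z, T) array with each voxel's
    timecourse z-scored per viewing.  ``validity[subject]`` marks voxels
    with nonzero variance in every viewing (constant voxels z-score to all
    zeros and are flagged invalid for searchlight inclusion).
    """

    subjects: list
    bold: list
    mask: np.ndarray
    affine: np.ndarray
    tr: float
    validity: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.bold)

    @property
    def n_viewings(self) -> int:
        return len(self.bold[0])


def _zscore_volume(vol: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each voxel timecourse; returns (zscored, nonzero-variance mask)."""
    vol = np.asarray(vol, dtype=np.float32)
    mu = vol.mean(axis=-1, keepdims=True)
    sd = vol.std(axis=-1, keepdims=True)
    out = vol - mu
    np.divide(out, sd, out=out, where=sd > 0)
    return out, (sd[..., 0] > 0)


def read_bold_dataset(
    root: str | Path,
    mask_path: str | Path | None = None,
    tr: float = 1.5,
) -> BoldDataset:
    """Load ``sub-*_view-*_bold.nii[.gz]`` volumes under ``root``.

    Subjects missing any viewing are dropped with a warning; shape or affine
    mismatches raise with the offending file named.  Voxel timecourses are
    z-scored per viewing at load.
    """
    root = Path(root)
    found: dict[str, dict[int, Path]] = {}
    for path in sorted(root.glob("sub-*_view-*_bold.nii*")):
        m = _BOLD_RE.search(path.name)
        if not m:
            continue
        found.setdefault(m["sub"], {})[int(m["view"])] = path
    if not found:
        raise FileNotFoundError(f"no sub-*_view-*_bold.nii[.gz] files under {root}")

    n_views = max(max(v) for v in found.values())
    ref_shape = ref_affine = None
    subjects, bold, validity = [], [], []
    for sub in sorted(found):
        views = found[sub]
        if set(views) != set(range(1, n_views + 1)):
            logger.warning("subject %s missing viewings %s; dropped",
                           sub, sorted(set(range(1, n_views + 1)) - set(views)))
            continue
        vols, valid = [], None
        for v in range(1, n_views + 1):
            img = nib.load(str(views[v]))
            data = np.asarray(img.get_fdata(), dtype=np.float32)
            if ref_shape is None:
                ref_shape, ref_affine = data.shape, img.affine
            elif data.shape != ref_shape or not np.allclose(img.affine, ref_affine):
                raise ValueError(f"shape/affine mismatch in {views[v]}")
            z, ok = _zscore_volume(data)
            vols.append(z)
            valid = ok if valid is None else (valid & ok)
        subjects.append(sub)
        bold.append(vols)
        validity.append(valid)
    if not bold:
        raise ValueError(f"no complete subjects under {root}")

    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.get_fdata()) > 0
        affine = mask_img.affine
        if mask.shape != ref_shape[:3]:
            raise ValueError(f"mask shape {mask.shape} != data shape {ref_shape[:3]}")
    else:
        mask = np.ones(ref_shape[:3], dtype=bool)
        affine = ref_affine
    return BoldDataset(subjects, bold, mask, affine, tr, validity)


def write_synthetic_dataset(vol: SyntheticVolume, out_dir: str | Path) -> None:
    """Write a synthetic dataset as NIfTIs plus ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s, viewings in enumerate(vol.bold):
        for v, data in enumerate(viewings):
            img = nib.Nifti1Image(np.asarray(data, np.float32), vol.affine)
            nib.save(img, str(out / f"sub-{s + 1:02d}_view-{v + 1}_bold.nii.gz"))
    nib.save(
        nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine),
        str(out / "mask.nii.gz"),
    )
    nib.save(
        nib.Nifti1Image(vol.anticipation_field.astype(np.float32), vol.affine),
        str(out / "anticipation_field.nii.gz"),
    )
    truth = {
        "n_events": vol.truth.n_events,
        "tr": vol.truth.tr,
        "noise_sd": vol.truth.noise_sd,
        "boundaries_by_viewing": [
            [int(b) for b in bnd] for bnd in vol.truth.boundaries_by_viewing
        ],
        "shift_seconds": [float(s) for s in vol.truth.shift_seconds],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))


def read_annotations(path: str | Path, clip_duration_s: float = 90.0) -> AnnotationSet:
    """Read a ``rater,time_s,label`` CSV into an AnnotationSet."""
    df = pd.read_csv(path)
    required = {"rater", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotations CSV needs columns {sorted(required)}")
    raters = []
    for rater_id, grp in df.groupby("rater", sort=True):
        grp = grp.sort_values("time_s")
        labels = (
            grp["label"].astype(str).tolist() if "label" in grp else []
        )
        raters.append(
            RaterAnnotation(str(rater_id), grp["time_s"].to_numpy(float), labels)
        )
    return AnnotationSet(raters, clip_duration_s)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    rows = []
    for r in ann.raters:
        labels = r.labels if r.labels else [""] * len(r.times_s)
        for t, lab in zip(r.times_s, labels):
            rows.append({"rater": r.rater_id, "time_s": float(t), "label": lab})
    pd.DataFrame(rows, columns=["rater", "time_s", "label"]).to_csv(path, index=False)


def _git_revision() -> str:
    try:
        return subprocess.run(
            ["git", "rev-parse", "HEAD"],
            capture_output=True, text=True, timeout=5, check=True,
        ).stdout.strip()
    except Exception:  # noqa: BLE001 - best effort only
        return "unknown"


def write_map(
    values: np.ndarray | AnticipationMap,
    affine: np.ndarray,
    path: str | Path,
    config_hash: str | None = None,
) -> None:
    """Write a float32 NIfTI map (NaN outside coverage) with a JSON sidecar."""
    if isinstance(values, AnticipationMap):
        values = values.values
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(values, np.float32), affine), str(path))
    sidecar = {
        "config_hash": config_hash or "unknown",
        "git_revision": _git_revision(),
    }
    stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    (path.parent / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def write_searchlight_table(
    searchlights: Sequence[Searchlight],
    values: np.ndarray,
    path: str | Path,
) -> None:
    rows = [
        {
            "center_x": sl.center[0],
            "center_y": sl.center[1],
            "center_z": sl.center[2],
            "n_voxels": sl.n_voxels,
            "n_subjects": sl.n_valid_subjects if sl.valid_subjects is not None else -1,
            "anticipation_s": float(v),
        }
        for sl, v in zip(searchlights, values)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
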