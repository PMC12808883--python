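"""NIfTI + JSON sidecar interchange for CEST, relaxometry and ROI data.

Layout convention: an image series is a NIfTI volume whose last axis is
the series dimension (saturation offset, flip angle or echo), with a JSON
sidecar of the same stem describing it.  CEST sidecars carry
``offsets_hz`` in acquisition order, ``s0_offsets_ppm``, ``ref_freq_mhz``
and the saturation module (``b1_uT``, ``tsat_ms``, ``tr_ms``); the two S0
reference images live in a companion ``*_s0.nii`` volume.  ROI labels are
integer NIfTI images with a sidecar naming each label.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .pipeline import RawCestSeries

__all__ = [
    "save_cest_series",
    "load_cest_series",
    "save_map",
    "load_map",
    "save_roi_labels",
    "load_roi_labels",
]

_EYE = np.eye(4)


def _to_nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), _EYE)


def save_cest_series(path_stem: str | Path, raw: RawCestSeries, seq_meta: dict | None = None) -> None:
    """Write ``<stem>.nii`` (H, W, n_offsets), ``<stem>_s0.nii`` and ``<stem>.json``."""
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_to_nifti(np.moveaxis(raw.stack, 0, -1)), str(stem) + ".nii")
    nib.save(_to_nifti(np.moveaxis(raw.s0_images, 0, -1)), str(stem) + "_s0.nii")
    sidecar = {
        "offsets_hz": list(raw.offsets_hz),
        "s0_offsets_ppm": [15.0, -15.0],
        "ref_freq_mhz": raw.ref_freq_mhz,
    }
    if seq_meta:
        sidecar.update(seq_meta)
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=1))
    if raw.mask is not None:
        nib.save(_to_nifti(raw.mask.astype(float)), str(stem) + "_mask.nii")


def load_cest_series(path_stem: str | Path) -> RawCestSeries:
    """Load a CEST series written by :func:`save_cest_series`."""
    stem = Path(path_stem)
    sidecar = json.loads(Path(str(stem) + ".json").read_text())
    stack = np.moveaxis(np.asarray(nib.load(str(stem) + ".nii").dataobj), -1, 0)
    s0 = np.moveaxis(np.asarray(nib.load(str(stem) + "_s0.nii").dataobj), -1, 0)
    mask_path = Path(str(stem) + "_mask.nii")
    mask = np.asarray(nib.load(mask_path).dataobj) > 0.5 if mask_path.exists() else None
    return RawCestSeries(
        stack=stack,
        s0_images=s0,
        offsets_hz=tuple(sidecar["offsets_hz"]),
        ref_freq_mhz=sidecar.get("ref_freq_mhz", 400.2),
        mask=mask,
    )


def save_map(path: str | Path, data: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(_to_nifti(data), str(path))


def load_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_roi_labels(path_stem: str | Path, rois: dict[str, np.ndarray]) -> None:
    """Write ROI masks as one integer label image plus a JSON label table."""
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    names = sorted(rois)
    label_img = np.zeros(next(iter(rois.values())).shape, dtype=float)
    table = {}
    for i, name in enumerate(names, start=1):
        label_img[rois[name].astype(bool)] = i
        table[str(i)] = name
    nib.save(_to_nifti(label_img), str(stem) + ".nii")
    Path(str(stem) + ".json").write_text(json.dumps({"labels": table}, indent=1))


def load_roi_labels(path_stem: str | Path) -> dict[str, np.ndarray]:
    stem = Path(path_stem)
    img = np.asarray(nib.load(str(stem) + ".nii").dataobj)
    table = json.loads(Path(str(stem) + ".json").read_text())["labels"]
    return {name: np.isclose(img, float(i)) for i, name in table.items()}
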