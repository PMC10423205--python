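"""Reading and writing phantom/patient bundles.

A bundle directory holds the aligned volumes as NIfTI (t1_pre, t1_post,
mask, optionally the true rr field) plus a JSON sidecar with the patient
record, the acquisition protocol and the generator seed.  The affine
carries the voxel spacing; orientation is RAS.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import VoxelGeometry
from .relaxometry import LiverMask, T1Volume
from .scoring import PatientRecord
from .synthetic import VfaProtocol

_VOLUME_FILES = {
    "t1_pre": "t1_pre.nii.gz",
    "t1_post": "t1_post.nii.gz",
    "mask": "mask.nii.gz",
    "rr_truth": "rr_truth.nii.gz",
}
_SIDECAR = "bundle.json"


def _save_nifti(path: Path, values: np.ndarray, geometry: VoxelGeometry) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), geometry.affine())
    img.header.set_zooms(geometry.spacing)
    nib.save(img, str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, VoxelGeometry]:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return values, VoxelGeometry(values.shape, zooms)


def write_phantom_bundle(directory, t1_pre: T1Volume, t1_post: T1Volume,
                         mask: LiverMask, rr_truth: np.ndarray | None = None,
                         patient: PatientRecord | None = None,
                         protocol: VfaProtocol | None = None,
                         seed: int | None = None) -> Path:
    """Write a phantom bundle (NIfTI volumes + JSON sidecar) to a directory."""
    for vol in (t1_post, mask):
        t1_pre.geometry.check_same(vol.geometry)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    _save_nifti(directory / _VOLUME_FILES["t1_pre"], t1_pre.values, t1_pre.geometry)
    _save_nifti(directory / _VOLUME_FILES["t1_post"], t1_post.values, t1_post.geometry)
    _save_nifti(directory / _VOLUME_FILES["mask"], mask.values.astype(np.float64), mask.geometry)
    if rr_truth is not None:
        _save_nifti(directory / _VOLUME_FILES["rr_truth"], rr_truth, t1_pre.geometry)

    sidecar = {
        "patient": dataclasses.asdict(patient) if patient is not None else None,
        "protocol": {
            "flip_angles_deg": list(protocol.flip_angles),
            "tr_ms": protocol.tr,
            "te_ms": list(protocol.te),
            "delay_min": protocol.delay_post_contrast_min,
        } if protocol is not None else None,
        "seed": seed,
    }
    (directory / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return directory


def read_phantom_bundle(directory) -> dict:
    """Read a bundle written by :func:`write_phantom_bundle`.

    Returns a dict with keys t1_pre, t1_post, mask, rr_truth (or None),
    patient (PatientRecord or None), protocol (VfaProtocol or None), seed.
    Raises if a required volume is missing.
    """
    directory = Path(directory)
    for key in ("t1_pre", "t1_post", "mask"):
        if not (directory / _VOLUME_FILES[key]).exists():
            raise FileNotFoundError(
                f"bundle incomplete: missing {_VOLUME_FILES[key]} in {directory}"
            )

    pre_values, geom = _load_nifti(directory / _VOLUME_FILES["t1_pre"])
    post_values, _ = _load_nifti(directory / _VOLUME_FILES["t1_post"])
    mask_values, _ = _load_nifti(directory / _VOLUME_FILES["mask"])
    rr_truth = None
    if (directory / _VOLUME_FILES["rr_truth"]).exists():
        rr_truth, _ = _load_nifti(directory / _VOLUME_FILES["rr_truth"])

    patient = protocol = seed = None
    sidecar_path = directory / _SIDECAR
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar.get("patient"):
            patient = PatientRecord(**sidecar["patient"])
        if sidecar.get("protocol"):
            p = sidecar["protocol"]
            protocol = VfaProtocol(
                flip_angles=tuple(p["flip_angles_deg"]),
                tr=p["tr_ms"],
                te=tuple(p["te_ms"]),
                delay_post_contrast_min=p["delay_min"],
            )
        seed = sidecar.get("seed")

    return {
        "t1_pre": T1Volume(pre_values, geom, phase="native"),
        "t1_post": T1Volume(post_values, geom, phase="hepatobiliary"),
        "mask": LiverMask(mask_values > 0.5, geom),
        "rr_truth": rr_truth,
        "patient": patient,
        "protocol": protocol,
        "seed": seed,
    }
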