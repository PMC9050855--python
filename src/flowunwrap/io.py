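"""Readers and writers for velocity fields and masks (HDF5 and NIfTI).

The canonical on-disk layout is a single HDF5 file holding the velocity array
(``velocity``, float32 cm/s, axes ``[x, y, z, frame, direction]``), optional
masks (uint8, congruent or 3D for a vessel segmentation), and the acquisition
metadata as root attributes (``venc_cms``, ``spacing_mm``,
``frame_interval_ms``).  NIfTI interchange writes one 4D image per velocity
direction plus a small YAML sidecar for the metadata a NIfTI header cannot
carry (venc, frame interval).

Scanner-like phase-integer data (values in [-4096, 4096) mapping linearly to
[-venc, +venc)) can be imported with :func:`phase_to_velocity`.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .core import VelocityField, check_mask_congruent, check_vessel_congruent

__all__ = [
    "read_field",
    "write_field",
    "read_mask",
    "write_mask",
    "read_vessel",
    "phase_to_velocity",
    "array_digest",
]

_ATTRS = ("venc_cms", "spacing_mm", "frame_interval_ms")
_DIR_SUFFIXES = ("vx", "vy", "vz")


def array_digest(arr: np.ndarray) -> str:
    """Content digest of an array (shape- and dtype-sensitive)."""
    h = hashlib.sha256()
    h.update(str(arr.shape).encode() + str(arr.dtype).encode())
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# HDF5


def write_field(
    path, field: VelocityField, vessel: np.ndarray | None = None, masks: dict | None = None
) -> None:
    """Write a velocity field (and optional masks) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=field.values.astype(np.float32))
        f.attrs["venc_cms"] = float(field.venc)
        f.attrs["spacing_mm"] = np.asarray(field.voxel_spacing, dtype=float)
        f.attrs["frame_interval_ms"] = float(field.frame_interval)
        if vessel is not None:
            f.create_dataset("vessel", data=check_vessel_congruent(field, vessel).astype(np.uint8))
        for name, mask in (masks or {}).items():
            f.create_dataset(name, data=check_mask_congruent(field, mask).astype(np.uint8))


def read_field(path, fmt: str | None = None) -> VelocityField:
    """Read a velocity field from HDF5 (or a NIfTI triple, see below).

    ``fmt`` is inferred from the extension when omitted: ``.h5``/``.hdf5`` →
    HDF5; anything ending in ``.nii``/``.nii.gz`` → NIfTI (``path`` is then
    the path of any one of the three per-direction files, or their common
    prefix).
    """
    p = str(path)
    if fmt is None:
        if p.endswith((".nii", ".nii.gz")) or Path(p + "_vx.nii").exists():
            fmt = "nifti"
        else:
            fmt = "hdf5"
    if fmt == "hdf5":
        return _read_field_h5(path)
    if fmt == "nifti":
        return read_field_nifti(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_field_h5(path) -> VelocityField:
    with h5py.File(path, "r") as f:
        if "velocity" not in f:
            raise KeyError(f"{path}: missing 'velocity' dataset")
        for attr in _ATTRS:
            if attr not in f.attrs:
                raise KeyError(f"{path}: missing required attribute '{attr}'")
        return VelocityField(
            values=f["velocity"][()].astype(np.float64),
            venc=float(f.attrs["venc_cms"]),
            voxel_spacing=tuple(np.asarray(f.attrs["spacing_mm"], dtype=float)),
            frame_interval=float(f.attrs["frame_interval_ms"]),
        )


def read_vessel(path) -> np.ndarray | None:
    """The vessel segmentation stored alongside a field, if any."""
    with h5py.File(path, "r") as f:
        return f["vessel"][()].astype(bool) if "vessel" in f else None


def write_mask(path, mask: np.ndarray, name: str = "mask") -> None:
    """Write a binary mask (any shape) as uint8 HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset(name, data=np.asarray(mask).astype(np.uint8))


def read_mask(path, name: str = "mask") -> np.ndarray:
    with h5py.File(path, "r") as f:
        if name not in f:
            raise KeyError(f"{path}: missing '{name}' dataset")
        return f[name][()].astype(bool)


# ---------------------------------------------------------------------------
# NIfTI


def _nifti_names(prefix: str) -> list[Path]:
    prefix = str(prefix)
    for ext in (".nii.gz", ".nii"):
        if prefix.endswith(ext):
            prefix = prefix[: -len(ext)]
            for d in _DIR_SUFFIXES:
                if prefix.endswith("_" + d):
                    prefix = prefix[: -(len(d) + 1)]
                    break
            break
    candidates = [Path(f"{prefix}_{d}.nii") for d in _DIR_SUFFIXES]
    if not candidates[0].exists():
        gz = [Path(f"{prefix}_{d}.nii.gz") for d in _DIR_SUFFIXES]
        if gz[0].exists():
            candidates = gz
    return candidates


def write_field_nifti(prefix, field: VelocityField) -> list[Path]:
    """Write one 4D NIfTI per velocity direction plus a YAML metadata sidecar."""
    prefix = str(prefix)
    affine = np.diag(list(field.voxel_spacing) + [1.0])
    paths = []
    for d, suffix in enumerate(_DIR_SUFFIXES):
        img = nib.Nifti1Image(field.values[..., d].astype(np.float32), affine)
        img.header.set_zooms(field.voxel_spacing + (field.frame_interval / 1000.0,))
        p = Path(f"{prefix}_{suffix}.nii")
        nib.save(img, p)
        paths.append(p)
    meta = {"venc_cms": float(field.venc), "frame_interval_ms": float(field.frame_interval)}
    Path(f"{prefix}.yaml").write_text(yaml.safe_dump(meta))
    return paths


def read_field_nifti(prefix) -> VelocityField:
    """Read the three per-direction 4D NIfTI files written by
    :func:`write_field_nifti` (``prefix`` may be the bare prefix or any of the
    three file paths)."""
    paths = _nifti_names(prefix)
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing per-direction NIfTI file(s): {missing}")
    imgs = [nib.load(p) for p in paths]
    shapes = {img.shape for img in imgs}
    if len(shapes) != 1:
        raise ValueError(f"direction files disagree on shape: {sorted(shapes)}")
    stem = str(paths[0])
    stem = stem[: stem.rindex("_vx")]
    sidecar = Path(stem + ".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar} (venc is required)")
    meta = yaml.safe_load(sidecar.read_text())
    if "venc_cms" not in meta:
        raise KeyError(f"{sidecar}: missing required key 'venc_cms'")
    spacing = tuple(float(z) for z in imgs[0].header.get_zooms()[:3])
    values = np.stack([np.asarray(img.dataobj, dtype=np.float64) for img in imgs], axis=-1)
    return VelocityField(
        values=values,
        venc=float(meta["venc_cms"]),
        voxel_spacing=spacing,
        frame_interval=float(meta.get("frame_interval_ms", 40.0)),
    )


# ---------------------------------------------------------------------------
# scanner-like phase integers


def phase_to_velocity(phase: np.ndarray, venc: float, full_scale: int = 4096) -> np.ndarray:
    """Map phase integers in [-full_scale, full_scale) to velocities in
    [-venc, +venc) cm/s."""
    phase = np.asarray(phase)
    if phase.min() < -full_scale or phase.max() >= full_scale:
        raise ValueError(f"phase values outside [-{full_scale}, {full_scale})")
    return phase.astype(np.float64) * (venc / full_scale)
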