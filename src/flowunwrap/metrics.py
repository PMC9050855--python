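"""Detection-quality metrics: Dice overlap, Hausdorff distance, voxel counts.

All metrics can be restricted to a static 3D vessel segmentation (broadcast
over frames and directions), since only aliased voxels inside the vessel are
clinically meaningful — background voxels are noise.

Dice uses the stabilized form ``(2|X ∩ Y| + 1e-5) / (|X| + |Y| + 1e-5)`` so
that two empty masks (e.g. a diastolic frame with no aliasing, correctly
detected as such) score 1 instead of 0/0.  The Hausdorff distance is the
symmetric max of directed min Euclidean distances between the two voxel point
sets, in physical mm (voxel-center coordinates scaled by the spacing); it is
undefined — an explicit error, never silently 0 — when either mask is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["DICE_EPS", "dice", "hausdorff", "count_aliased", "restrict_mask", "EmptyMaskError"]

DICE_EPS = 1e-5


class EmptyMaskError(ValueError):
    """Raised when a distance is requested between point sets one of which is empty."""


def restrict_mask(mask: np.ndarray, restrict: np.ndarray | None) -> np.ndarray:
    """Apply a 3D vessel restriction to a mask of any trailing shape."""
    mask = np.asarray(mask, dtype=bool)
    if restrict is None:
        return mask
    restrict = np.asarray(restrict, dtype=bool)
    if restrict.shape != mask.shape[:3]:
        raise ValueError(
            f"restriction shape {restrict.shape} does not match mask grid {mask.shape[:3]}"
        )
    extra = mask.ndim - 3
    return mask & restrict[(...,) + (None,) * extra]


def dice(
    detected: np.ndarray,
    truth: np.ndarray,
    restrict: np.ndarray | None = None,
) -> float:
    """Stabilized Dice overlap between two congruent binary masks."""
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detected.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {detected.shape} vs {truth.shape}")
    x = restrict_mask(detected, restrict)
    y = restrict_mask(truth, restrict)
    inter = np.count_nonzero(x & y)
    return float((2.0 * inter + DICE_EPS) / (x.sum() + y.sum() + DICE_EPS))


def _points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Voxel-center coordinates (mm) of the set voxels of a 3D mask."""
    return np.argwhere(mask).astype(float) * np.asarray(spacing, dtype=float)


def _hausdorff_points(px: np.ndarray, py: np.ndarray, method: str) -> float:
    if len(px) == 0 or len(py) == 0:
        raise EmptyMaskError("Hausdorff distance is undefined for an empty mask")
    if method == "brute":
        # O(|X||Y|) double max-min, the reference formulation
        d = np.sqrt(((px[:, None, :] - py[None, :, :]) ** 2).sum(-1))
        return float(max(d.min(axis=0).max(), d.min(axis=1).max()))
    if method == "kdtree":
        dxy = cKDTree(px).query(py, workers=-1)[0].max()
        dyx = cKDTree(py).query(px, workers=-1)[0].max()
        return float(max(dxy, dyx))
    raise ValueError(f"unknown method {method!r}")


def hausdorff(
    detected: np.ndarray,
    truth: np.ndarray,
    voxel_spacing=(1.0, 1.0, 1.0),
    restrict: np.ndarray | None = None,
    method: str = "kdtree",
    per_volume: bool = False,
):
    """Symmetric Hausdorff distance between two masks, in mm.

    For 5-axis masks ``[x, y, z, frame, direction]`` the distance is computed
    per (frame, direction) volume on the spacing-scaled voxel-center
    coordinates, skipping volumes where both masks are empty; the reported
    dataset value is the maximum over volumes (also returned per volume with
    ``per_volume=True``).  A volume where exactly one mask is empty — or a
    fully empty mask — raises :class:`EmptyMaskError`.

    ``method="brute"`` is the O(|X||Y|) reference; ``method="kdtree"`` is the
    accelerated path and returns identical values.
    """
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detected.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {detected.shape} vs {truth.shape}")
    x = restrict_mask(detected, restrict)
    y = restrict_mask(truth, restrict)
    spacing = np.asarray(voxel_spacing, dtype=float)
    if x.ndim == 3:
        d = _hausdorff_points(_points_mm(x, spacing), _points_mm(y, spacing), method)
        return (d, {(0, 0): d}) if per_volume else d
    if x.ndim != 5:
        raise ValueError("masks must be 3D volumes or 5-axis [x,y,z,frame,direction]")
    per: dict[tuple[int, int], float] = {}
    for t in range(x.shape[3]):
        for c in range(x.shape[4]):
            xv, yv = x[:, :, :, t, c], y[:, :, :, t, c]
            if not xv.any() and not yv.any():
                continue
            per[(t, c)] = _hausdorff_points(
                _points_mm(xv, spacing), _points_mm(yv, spacing), method
            )
    if not per:
        raise EmptyMaskError("Hausdorff distance is undefined: both masks are empty")
    overall = max(per.values())
    return (overall, per) if per_volume else overall


def count_aliased(mask: np.ndarray, restrict: np.ndarray | None = None) -> int:
    """Number of set voxels (inside the vessel if given), over all frames/directions."""
    return int(np.count_nonzero(restrict_mask(np.asarray(mask, dtype=bool), restrict)))
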