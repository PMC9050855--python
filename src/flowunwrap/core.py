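"""Core containers for 4D-flow velocity data.

The central object is :class:`VelocityField`: a five-axis array of velocities
indexed ``[x, y, z, frame, direction]`` in cm/s together with the acquisition
metadata every downstream stage needs — the velocity-encoding sensitivity
(venc), the voxel spacing and the cardiac frame interval.  Binary masks
(aliased-voxel masks, vessel segmentations) are plain boolean numpy arrays;
helper functions validate their congruence with a field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VelocityField",
    "as_wrap_mask",
    "as_vessel_mask",
    "check_mask_congruent",
    "check_vessel_congruent",
]

#: Axis layout of VelocityField.values
AXES = ("x", "y", "z", "frame", "direction")
N_DIRECTIONS = 3  # Vx, Vy, Vz


@dataclass
class VelocityField:
    """A 4D-flow velocity data set.

    Parameters
    ----------
    values
        Real array of shape ``(nx, ny, nz, n_frames, 3)`` holding the three
        velocity components in cm/s.
    venc
        Velocity-encoding sensitivity in cm/s.  Velocities are representable
        on the half-open interval ``[-venc, +venc)``; anything outside wraps.
    voxel_spacing
        Voxel edge lengths ``(dx, dy, dz)`` in mm.
    frame_interval
        Temporal resolution (time between cardiac frames) in ms.
    """

    values: np.ndarray
    venc: float
    voxel_spacing: tuple[float, float, float] = (2.4, 2.4, 2.4)
    frame_interval: float = 40.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 5 or self.values.shape[-1] != N_DIRECTIONS:
            raise ValueError(
                f"velocity array must have shape (nx, ny, nz, n_frames, 3), "
                f"got {self.values.shape}"
            )
        if self.values.shape[3] < 1:
            raise ValueError("velocity field needs at least one cardiac frame")
        if not np.isfinite(self.venc) or self.venc <= 0:
            raise ValueError(f"venc must be positive and finite, got {self.venc}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive lengths (mm), got {self.voxel_spacing}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ms)")

    # -- convenience -------------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def copy(self) -> "VelocityField":
        return replace(self, values=self.values.copy())

    def with_values(self, values: np.ndarray, venc: float | None = None) -> "VelocityField":
        """A new field sharing this field's metadata (optionally a new venc)."""
        return replace(self, values=values, venc=self.venc if venc is None else venc)

    def volume(self, frame: int, direction: int) -> np.ndarray:
        """The 3D ``[x, y, z]`` volume of one frame and one velocity direction."""
        return self.values[:, :, :, frame, direction]


def as_wrap_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce to a boolean aliased-voxel mask of shape ``(nx, ny, nz, t, 3)``."""
    mask = np.asarray(mask)
    if mask.ndim != 5 or mask.shape[-1] != N_DIRECTIONS:
        raise ValueError(f"wrap mask must have shape (nx, ny, nz, n_frames, 3), got {mask.shape}")
    return mask.astype(bool, copy=False)


def as_vessel_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce to a boolean 3D vessel segmentation; must be nonempty."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"vessel mask must be 3D (nx, ny, nz), got shape {mask.shape}")
    mask = mask.astype(bool, copy=False)
    if not mask.any():
        raise ValueError("vessel mask is empty")
    return mask


def check_mask_congruent(field: VelocityField, mask: np.ndarray) -> np.ndarray:
    mask = as_wrap_mask(mask)
    if mask.shape != field.shape:
        raise ValueError(f"mask shape {mask.shape} does not match field shape {field.shape}")
    return mask


def check_vessel_congruent(field_or_shape, vessel: np.ndarray) -> np.ndarray:
    vessel = as_vessel_mask(vessel)
    shape = (
        field_or_shape.grid_shape
        if isinstance(field_or_shape, VelocityField)
        else tuple(field_or_shape)[:3]
    )
    if vessel.shape != tuple(shape):
        raise ValueError(f"vessel mask shape {vessel.shape} does not match grid {tuple(shape)}")
    return vessel
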