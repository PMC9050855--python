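"""Synthetic pulsatile-flow phantoms with known true velocities.

Real aortic 4D-flow scans are not redistributable, so every stage of the
toolkit is exercised on phantoms generated here: a vessel (straight tube or a
U-bend "candy-cane" emulating ascending aorta → arch → descending aorta)
carrying pulsatile Poiseuille flow, embedded in static background tissue.
Peak velocity, venc, spatial/temporal resolution and the magnitude SNR are all
controlled by :class:`PhantomSpec`, and the same spec + seed always
regenerates a bit-identical data set.

The noise model is the standard phase-contrast relation: the velocity-noise
standard deviation per component is ``sigma_v = sqrt(2) * venc / (pi * SNR)``,
i.e. proportional to the selected venc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .core import VelocityField

__all__ = ["PhantomSpec", "generate_waveform", "generate_phantom", "velocity_noise_sd"]

#: diastolic plateau level of the waveform, relative to the systolic peak
_DIASTOLE_LEVEL = 0.08

#: tilt of the U-bend plane about z (deg), so arch flow has x and y components
_UBEND_TILT_DEG = 20.0


@dataclass
class PhantomSpec:
    """Full parameterization of the synthetic 4D-flow generator.

    Defaults mirror a typical adult thoracic-aorta protocol: ~2.4 mm voxels,
    ~40 ms temporal resolution, normal peak aortic velocity of 150 cm/s and a
    venc prescribed slightly above it.
    """

    grid_shape: tuple[int, int, int] = (64, 48, 16)
    voxel_spacing: tuple[float, float, float] = (2.4, 2.4, 2.6)
    n_frames: int = 14
    frame_interval: float = 40.0  # ms
    vessel: Literal["ubend", "straight"] = "ubend"
    vessel_radius: float = 12.0  # mm
    bend_radius: float | None = None  # mm; U-bend limb half-separation (auto if None)
    systole_fraction: float = 0.35
    peak_velocity: float = 150.0  # cm/s
    venc: float = 170.0  # cm/s
    snr: float = 15.0  # magnitude SNR; np.inf disables noise
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.grid_shape) != 3 or any(n < 4 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 integers >= 4, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive (mm)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ms)")
        if self.peak_velocity <= 0 or self.venc <= 0:
            raise ValueError("peak_velocity and venc must be positive (cm/s)")
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must lie in (0, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be positive (use numpy.inf for noise-free)")
        if self.vessel not in ("ubend", "straight"):
            raise ValueError(f"unknown vessel geometry {self.vessel!r}")
        # tube must span at least 2 voxels of radius in every in-plane direction
        min_voxels = min(self.vessel_radius / s for s in self.voxel_spacing)
        if min_voxels < 2.0:
            raise ValueError(
                f"vessel_radius {self.vessel_radius} mm is under 2 voxels "
                f"for spacing {self.voxel_spacing} mm"
            )


def velocity_noise_sd(venc: float, snr: float) -> float:
    """Velocity-noise SD (cm/s) per component: sqrt(2)*venc/(pi*SNR)."""
    if np.isinf(snr):
        return 0.0
    return float(np.sqrt(2.0) * venc / (np.pi * snr))


def generate_waveform(
    n_frames: int, frame_interval: float, systole_fraction: float = 0.35
) -> np.ndarray:
    """Per-frame cardiac scale factors in [0, 1] with max exactly 1.

    A raised-cosine systolic pulse occupying the first ``systole_fraction`` of
    the cycle on top of a low diastolic plateau.  Frames are sampled at frame
    centers, and the sampled waveform is renormalized so its maximum is 1.

    Parameters
    ----------
    n_frames
        Number of cardiac frames (>= 2).
    frame_interval
        Frame duration in ms (sets the cycle length ``n_frames * frame_interval``;
        the shape depends only on the phase, so it is accepted for interface
        symmetry and validation).
    systole_fraction
        Fraction of the cycle occupied by the systolic pulse, in (0, 1).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive (ms)")
    if not 0.0 < systole_fraction < 1.0:
        raise ValueError("systole_fraction must lie in (0, 1)")
    # frame-center phases in [0, 1)
    phase = (np.arange(n_frames) + 0.5) / n_frames
    w = np.full(n_frames, _DIASTOLE_LEVEL, dtype=float)
    in_sys = phase < systole_fraction
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[in_sys] / systole_fraction))
    w[in_sys] = _DIASTOLE_LEVEL + (1.0 - _DIASTOLE_LEVEL) * pulse
    return w / w.max()


def _centerline(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Finely sampled centerline points (mm) and unit tangents for the vessel."""
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_spacing
    step = 0.5 * min(spec.voxel_spacing)
    cy = 0.5 * (ny - 1) * dy
    if spec.vessel_radius > cy:
        raise ValueError("vessel_radius exceeds the grid half-extent in y")
    if spec.vessel == "straight":
        if spec.vessel_radius > 0.5 * (nx - 1) * dx:
            raise ValueError("vessel_radius exceeds the grid half-extent in x")
        cx = 0.5 * (nx - 1) * dx
        z = np.arange(-dz, nz * dz + dz, step)  # overshoot ends so caps are flat
        pts = np.column_stack([np.full_like(z, cx), np.full_like(z, cy), z])
        tan = np.tile([0.0, 0.0, 1.0], (len(z), 1))
        return pts, tan
    # U-bend ("candy cane"): up the ascending limb, over the arch, down the
    # descending limb.  The bend plane is tilted about z so the arch velocity
    # has both x and y components — all three directions are exercised.
    cx = 0.5 * (nx - 1) * dx
    tilt = np.deg2rad(_UBEND_TILT_DEG)
    e_xi = np.array([np.cos(tilt), np.sin(tilt), 0.0])  # in-plane horizontal axis
    R = spec.vessel_radius
    rb = spec.bend_radius
    if rb is None:
        rb = min(
            (cx - R - dx) / np.cos(tilt),
            (cy - R - dy) / max(np.sin(tilt), 1e-9),
        )
    z_top = (nz - 1) * dz - R - dz  # arch apex center height
    if rb <= 0 or z_top <= 0:
        raise ValueError("U-bend geometry does not fit the grid; enlarge grid or shrink radius")
    center = np.array([cx, cy, 0.0])
    segs_p, segs_t = [], []
    z_lo = -dz
    z1 = np.arange(z_lo, z_top, step)
    asc = center - rb * e_xi + np.outer(z1, [0.0, 0.0, 1.0])
    segs_p.append(asc)
    segs_t.append(np.tile([0.0, 0.0, 1.0], (len(z1), 1)))
    theta = np.arange(np.pi, 0.0, -step / rb)
    arc = center + rb * np.cos(theta)[:, None] * e_xi
    arc[:, 2] = z_top + rb * np.sin(theta)
    segs_p.append(arc)
    # tangent (sinθ)·e_xi - (cosθ)·ẑ for θ decreasing from π to 0
    segs_t.append(np.sin(theta)[:, None] * e_xi - np.outer(np.cos(theta), [0.0, 0.0, 1.0]))
    z2 = np.arange(z_top, z_lo, -step)
    dsc = center + rb * e_xi + np.outer(z2, [0.0, 0.0, 1.0])
    segs_p.append(dsc)
    segs_t.append(np.tile([0.0, 0.0, -1.0], (len(z2), 1)))
    pts, tans = np.concatenate(segs_p), np.concatenate(segs_t)
    hi = (np.array([nx, ny, nz]) - 1) * np.array([dx, dy, dz])
    margin = np.array([R, R, 0.0])  # z limbs may overshoot the faces by design
    if (pts[:, :2] - margin[:2] < 0).any() or (pts[:, :2] + margin[:2] > hi[:2]).any():
        raise ValueError("U-bend exceeds the grid in x/y; shrink bend_radius or vessel_radius")
    return pts, tans


def generate_phantom(spec: PhantomSpec) -> tuple[VelocityField, np.ndarray, np.ndarray]:
    """Generate a pulsatile-flow phantom.

    Returns
    -------
    field : VelocityField
        Velocities in cm/s, shape ``grid_shape + (n_frames, 3)``.  Inside the
        vessel the through-axis velocity follows a parabolic (Poiseuille)
        profile scaled by the cardiac waveform and decomposed along the local
        vessel axis; outside it is zero.  Zero-mean Gaussian noise with
        SD ``sqrt(2)*venc/(pi*snr)`` is added independently per
        voxel/frame/direction (none if ``snr`` is inf).
    vessel : ndarray of bool, shape grid_shape
        Static vessel segmentation (distance to centerline <= vessel_radius).
    waveform : ndarray, shape (n_frames,)
        The per-frame scale factors used.
    """
    pts, tans = _centerline(spec)
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_spacing
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    zs = np.arange(nz) * dz
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    dist, idx = cKDTree(pts).query(coords, workers=-1)
    dist = dist.reshape(spec.grid_shape)
    vessel = dist <= spec.vessel_radius

    # parabolic profile along the local tangent, zero outside the vessel
    profile = np.where(vessel, 1.0 - (dist / spec.vessel_radius) ** 2, 0.0)
    tangent = tans[idx].reshape(spec.grid_shape + (3,))
    tangent[~vessel] = 0.0

    waveform = generate_waveform(spec.n_frames, spec.frame_interval, spec.systole_fraction)
    base = spec.peak_velocity * profile[..., None] * tangent  # (x, y, z, 3)
    values = base[:, :, :, None, :] * waveform[None, None, None, :, None]

    sigma = velocity_noise_sd(spec.venc, spec.snr)
    if sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, sigma, size=values.shape)

    field = VelocityField(
        values=values,
        venc=spec.venc,
        voxel_spacing=spec.voxel_spacing,
        frame_interval=spec.frame_interval,
    )
    return field, vessel, waveform
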