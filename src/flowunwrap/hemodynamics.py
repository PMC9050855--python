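"""Flow quantification through analysis planes and Bland–Altman agreement.

A 2D analysis plane (e.g. at the ascending aorta, arch, or descending aorta)
is intersected with the velocity field; per cardiac frame the volumetric flow
rate is the sum over the in-plane region of interest of the through-plane
velocity component times the pixel area.  Net flow is the integral of that
series over the cardiac cycle (periodic rectangle rule, so a constant series
integrates exactly), peak flow its maximum, and peak velocity the maximum
voxelwise speed (vector magnitude) inside the ROI over the cycle.

For paired scans acquired at two vencs, :func:`dual_venc_truth` derives the
in-vivo aliasing ground truth: a voxel is aliased in the low-venc scan when
its velocity differs from the high-venc (non-aliased) scan by more than the
low venc — for a single wrap the two readings differ by exactly ``2*venc_low``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import VelocityField, check_vessel_congruent

__all__ = [
    "AnalysisPlane",
    "FlowReport",
    "AgreementReport",
    "plane_flow",
    "dual_venc_truth",
    "bland_altman",
]


@dataclass(frozen=True)
class AnalysisPlane:
    """A 2D flow-quantification plane.

    ``origin_mm`` is a point on the plane, ``normal`` its (unit) normal.  The
    in-plane ROI is resampled from the vessel segmentation passed to
    :func:`plane_flow`; alternatively a circular ROI of ``roi_radius_mm``
    about the origin can be used.
    """

    origin_mm: tuple[float, float, float]
    normal: tuple[float, float, float]
    roi_radius_mm: float | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", tuple(n / norm))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane direction vectors."""
        n = np.asarray(self.normal)
        e = np.zeros(3)
        e[np.argmin(np.abs(n))] = 1.0
        u = np.cross(n, e)
        u /= np.linalg.norm(u)
        return u, np.cross(n, u)


@dataclass
class FlowReport:
    """Per-plane flow quantification results."""

    net_flow_ml: float
    peak_flow_ml_s: float
    peak_velocity_m_s: float
    series_ml_s: np.ndarray
    frame_interval_ms: float

    def to_dict(self) -> dict:
        return {
            "net_flow_ml": self.net_flow_ml,
            "peak_flow_ml_s": self.peak_flow_ml_s,
            "peak_velocity_m_s": self.peak_velocity_m_s,
            "series_ml_s": [float(q) for q in self.series_ml_s],
            "frame_interval_ms": self.frame_interval_ms,
        }


@dataclass
class AgreementReport:
    """Bland–Altman agreement between a test and a reference series."""

    bias: float
    loa: float  # 1.96 * SD of differences (ddof=1)
    loa_percent: float  # 100 * loa / mean(reference); nan if mean(reference)=0
    n: int

    @property
    def percent_defined(self) -> bool:
        return not np.isnan(self.loa_percent)

    def to_dict(self) -> dict:
        return {"bias": self.bias, "loa": self.loa, "loa_percent": self.loa_percent, "n": self.n}


def plane_flow(
    field: VelocityField,
    plane: AnalysisPlane,
    vessel: np.ndarray | None = None,
) -> FlowReport:
    """Quantify flow through an analysis plane.

    The plane is rasterized at the field's finest voxel pitch; each in-plane
    pixel samples the nearest voxel (no interpolation).  The ROI is the set of
    pixels that fall inside ``vessel`` (or within ``plane.roi_radius_mm`` of
    the origin when no vessel mask is given).
    """
    if vessel is None and plane.roi_radius_mm is None:
        raise ValueError("give a vessel mask or set roi_radius_mm on the plane")
    if vessel is not None:
        vessel = check_vessel_congruent(field, vessel)
    spacing = np.asarray(field.voxel_spacing)
    shape = np.asarray(field.grid_shape)
    h = float(spacing.min())  # in-plane pixel pitch, mm
    u, w = plane.basis()
    origin = np.asarray(plane.origin_mm)

    half_diag = 0.5 * float(np.linalg.norm((shape - 1) * spacing)) + h
    s = np.arange(-half_diag, half_diag + h, h)
    su, tw = np.meshgrid(s, s, indexing="ij")
    pts = origin + su[..., None] * u + tw[..., None] * w  # (ns, nt, 3)

    idx = np.rint(pts / spacing).astype(int)
    valid = np.all((idx >= 0) & (idx < shape), axis=-1)
    if plane.roi_radius_mm is not None:
        valid &= su**2 + tw**2 <= plane.roi_radius_mm**2
    ii, jj, kk = idx[..., 0][valid], idx[..., 1][valid], idx[..., 2][valid]
    if vessel is not None:
        inside = vessel[ii, jj, kk]
        ii, jj, kk = ii[inside], jj[inside], kk[inside]
    if ii.size == 0:
        raise ValueError("degenerate ROI: the plane does not intersect the vessel")

    vox = field.values[ii, jj, kk]  # (npix, n_frames, 3)
    n = np.asarray(plane.normal)
    vn = vox @ n  # through-plane component, cm/s
    # cm/s * mm^2 = 10 mm^3/s = 0.01 ml/s
    series = vn.sum(axis=0) * h * h * 0.01
    dt_s = field.frame_interval / 1000.0
    net = float(series.sum() * dt_s)
    peak_flow = float(series.max())
    speed = np.linalg.norm(vox, axis=-1)
    peak_velocity = float(speed.max() / 100.0)  # cm/s -> m/s
    return FlowReport(net, peak_flow, peak_velocity, series, field.frame_interval)


def dual_venc_truth(low: VelocityField, high: VelocityField) -> np.ndarray:
    """Aliasing ground truth from a dual-venc scan pair.

    Voxels (per direction and frame) whose velocities differ by more than the
    low venc between the high-venc (non-aliased) and low-venc scans are
    flagged as aliased in the low-venc scan.
    """
    if low.shape != high.shape:
        raise ValueError(f"fields are not congruent: {low.shape} vs {high.shape}")
    if low.venc >= high.venc:
        raise ValueError(
            f"low venc ({low.venc}) must be below the reference venc ({high.venc})"
        )
    return np.abs(high.values - low.values) > low.venc


def bland_altman(reference, test) -> AgreementReport:
    """Bland–Altman agreement of a test series against a reference series.

    bias = mean(test - reference); LOA = 1.96 * SD(test - reference) with the
    n-1 denominator; LOA percent = 100 * LOA / mean(reference) (nan, flagged,
    when the reference mean is zero).
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape or reference.ndim != 1:
        raise ValueError("reference and test must be 1D series of equal length")
    if reference.size < 2:
        raise ValueError("need at least 2 paired values")
    diff = test - reference
    bias = float(diff.mean())
    loa = float(1.96 * diff.std(ddof=1))
    ref_mean = reference.mean()
    loa_percent = float(100.0 * loa / ref_mean) if ref_mean != 0 else float("nan")
    return AgreementReport(bias=bias, loa=loa, loa_percent=loa_percent, n=reference.size)
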