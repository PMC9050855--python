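"""Venc-induced velocity-wrap simulation and mask-driven correction.

Phase-contrast MRI encodes velocity in signal phase, so a true velocity
``V_T`` outside the representable half-open interval ``[-venc, +venc)`` folds
back modularly: the acquired value is ``V_A = V_T - 2*venc*k`` with the
integer wrap count ``k = floor((V_T + venc) / (2*venc))``.  For a single
positive wrap (``venc < V_T < 3*venc``) this reduces to the familiar
``V_A = V_T - 2*venc``; the modular form extends it symmetrically to negative
velocities and multiple wraps.

:func:`wrap_velocity` applies this fold at a reduced, simulated venc and
returns the exact ground-truth mask of every voxel it changed — the labeled
training/evaluation data used throughout the toolkit.
:func:`unwrap_with_mask` is the mask-driven single-wrap correction: a masked
voxel with a negative aliased value is shifted up by ``2*venc`` and vice
versa.  That sign rule inverts the wrap exactly for ``|V_T| < 2*venc``; a
binary mask carries no wrap count, so magnitudes beyond that (multi-wrap or
``|V_T|`` in ``(2*venc, 3*venc)``, where the aliased value keeps the sign of
the true one) are out of its reach by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import VelocityField, check_mask_congruent

__all__ = ["WrapSpec", "wrap_velocity", "unwrap_with_mask", "draw_venc_fractions"]

logger = logging.getLogger(__name__)

#: venc-reduction range used for training-style simulated aliasing
VENC_FRACTION_RANGE = (0.40, 0.70)


@dataclass(frozen=True)
class WrapSpec:
    """Reduced velocity sensitivity used to simulate aliasing.

    Exactly one of ``venc_sim`` (cm/s) or ``venc_fraction`` (fraction of the
    original venc) is given; the other is derived against the field at hand.
    """

    venc_sim: float | None = None
    venc_fraction: float | None = None

    def resolve(self, original_venc: float) -> float:
        if (self.venc_sim is None) == (self.venc_fraction is None):
            raise ValueError("give exactly one of venc_sim or venc_fraction")
        v = self.venc_sim if self.venc_sim is not None else self.venc_fraction * original_venc
        if not 0.0 < v < original_venc:
            raise ValueError(
                f"simulated venc {v:.6g} cm/s must lie in (0, original venc "
                f"{original_venc:.6g}); nothing can wrap otherwise"
            )
        return float(v)


def wrap_counts(values: np.ndarray, venc: float) -> np.ndarray:
    """Integer wrap count k such that ``values - 2*venc*k`` lies in [-venc, venc)."""
    return np.floor((values + venc) / (2.0 * venc)).astype(np.int64)


def wrap_velocity(
    field: VelocityField, spec: WrapSpec | float
) -> tuple[VelocityField, np.ndarray]:
    """Simulate velocity aliasing at a reduced venc, with exact ground truth.

    Parameters
    ----------
    field
        The (assumed non-aliased) velocity field; not modified.
    spec
        A :class:`WrapSpec`, or directly the simulated venc in cm/s.

    Returns
    -------
    aliased : VelocityField
        The wrapped field; carries ``venc = venc_sim`` and values in
        ``[-venc_sim, +venc_sim)``.  Applied to the entire data set, all
        frames and all three velocity directions.
    truth : ndarray of bool
        Ground-truth aliased-voxel mask — exactly the voxels whose wrapped
        value differs from the true value.
    """
    if not isinstance(spec, WrapSpec):
        spec = WrapSpec(venc_sim=float(spec))
    venc_sim = spec.resolve(field.venc)
    k = wrap_counts(field.values, venc_sim)
    truth = k != 0
    # subtracting the (exact) multiple of 2*venc leaves unwrapped voxels
    # bit-identical and wrapped voxels folded into [-venc_sim, venc_sim)
    aliased_values = field.values - (2.0 * venc_sim) * k
    aliased = field.with_values(aliased_values, venc=venc_sim)
    logger.info(
        "wrap_velocity: venc %.4g -> %.4g cm/s, %d aliased voxels",
        field.venc, venc_sim, int(truth.sum()),
    )
    return aliased, truth


def unwrap_with_mask(
    aliased: VelocityField, mask: np.ndarray, venc: float | None = None
) -> VelocityField:
    """Correct the masked voxels by one wrap, direction inferred from sign.

    A masked voxel with aliased value < 0 is shifted up by ``2*venc``; one
    with value > 0 is shifted down.  A masked voxel exactly at 0 carries no
    sign information; it is corrected upward and the occurrence logged.
    Unmasked voxels are returned unchanged.
    """
    mask = check_mask_congruent(aliased, mask)
    if venc is None:
        venc = aliased.venc
    elif venc != aliased.venc:
        raise ValueError(
            f"venc {venc} does not match the aliased field's venc {aliased.venc}"
        )
    values = aliased.values.copy()
    n_zero = int(np.count_nonzero(mask & (values == 0.0)))
    if n_zero:
        logger.warning(
            "unwrap_with_mask: %d masked voxels have aliased value exactly 0; "
            "correcting them upward (+2*venc)", n_zero,
        )
    shift = np.where(values < 0.0, 2.0 * venc, np.where(values > 0.0, -2.0 * venc, 2.0 * venc))
    values[mask] += shift[mask]
    return aliased.with_values(values)


def draw_venc_fractions(
    n: int,
    rng: np.random.Generator | int,
    low: float = VENC_FRACTION_RANGE[0],
    high: float = VENC_FRACTION_RANGE[1],
) -> np.ndarray:
    """Seeded uniform draws of venc fractions on [low, high] (default [0.40, 0.70])."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not 0.0 < low <= high < 1.0:
        raise ValueError("need 0 < low <= high < 1")
    return rng.uniform(low, high, size=n)
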