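"""Conventional spatio-temporal phase-unwrapping baseline.

The classical fully-automatic approach to velocity anti-aliasing exploits the
fact that a wrap introduces a jump of nearly ``2*venc`` between neighboring
samples, while true blood-flow velocity varies smoothly: nearest-neighbor
difference arrays are formed along x, y and time for each slice and velocity
direction ( ``[X, Y, time]`` sub-arrays — no through-slice differences), and
voxel pairs whose difference exceeds the venc are flagged.

Disambiguating *which* voxel of a flagged pair is wrapped uses two rules:

* trusted references — the first cardiac frame and the field borders are
  assumed unaliased (diastolic frames and background tissue rarely alias), so
  passes sweep outward from them, each voxel compared against its
  already-resolved neighbor;
* sign consistency — a flagged voxel is corrected by ``-sign(V) * 2 * venc``
  only when that shift reduces the jump (``sign(V) == sign(ΔV)``); flagged
  voxels failing the check (including an exact 0) are left unchanged.

A sequential sweep can chain a single mistaken correction through smooth data
(each newly corrupted voxel becomes the next reference), so every pass is
followed by a validation step: a voxel whose correction *increased* its count
of inconsistent neighbor pairs is reverted — genuine wrap regions are
corrected coherently within one pass and stay consistent, chained mistakes do
not.  A reverted correction may validate in a later iteration once its
context has been resolved.

Passes run temporal-first, then x, then y, and the schedule iterates until an
iteration makes no net correction or ``max_iterations`` is reached.  Under
severe aliasing (very low venc) the systolic upstroke between frames
approaches the venc itself, jumps fall below threshold, and the algorithm
under-detects — the classical failure mode of this family of methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import VelocityField

__all__ = ["JumpParams", "conventional_unwrap"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JumpParams:
    """Parameters of the spatio-temporal jump algorithm.

    ``jump_threshold_factor`` scales the flagging threshold
    (``threshold = factor * venc``); 1.0 is the classical "jumps larger than
    venc" rule.  ``neighborhood`` documents the adjacency the passes use.
    """

    jump_threshold_factor: float = 1.0
    max_iterations: int = 10
    neighborhood: tuple[str, ...] = ("time", "x", "y")

    def __post_init__(self) -> None:
        if not 0.0 < self.jump_threshold_factor <= 2.0:
            raise ValueError("jump_threshold_factor must lie in (0, 2]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if any(a not in ("time", "x", "y") for a in self.neighborhood):
            raise ValueError(f"unknown neighborhood axes in {self.neighborhood}")


_AXIS = {"x": 0, "y": 1, "time": 3}


def _sweep(values: np.ndarray, axis: int, thr: float, venc: float, forward: bool) -> int:
    """One sequential pass along ``axis``; corrects in place, returns #corrections."""
    n = values.shape[axis]
    idxs = range(1, n) if forward else range(n - 2, -1, -1)
    step = -1 if forward else 1
    changed = 0
    for i in idxs:
        cur = np.take(values, i, axis=axis)
        ref = np.take(values, i + step, axis=axis)
        sl = [slice(None)] * values.ndim
        sl[axis] = i
        d = cur - ref
        # only values inside [-venc, venc] can be wrapped observations; a value
        # already beyond venc is a trusted (true or corrected) velocity
        flag = (
            (np.abs(d) > thr)
            & (np.sign(cur) == np.sign(d))
            & (cur != 0.0)
            & (np.abs(cur) <= venc)
        )
        if flag.any():
            cur[flag] -= np.sign(cur[flag]) * 2.0 * venc
            values[tuple(sl)] = cur  # np.take copies; write the resolved values back
            changed += int(flag.sum())
    return changed


def _inconsistent_pairs(values: np.ndarray, thr: float) -> np.ndarray:
    """Per-voxel count of neighbor pairs (x, y, time) with |difference| > thr."""
    count = np.zeros(values.shape, dtype=np.int8)
    for ax in (0, 1, 3):
        jump = np.abs(np.diff(values, axis=ax)) > thr
        lo = [slice(None)] * values.ndim
        hi = [slice(None)] * values.ndim
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        count[tuple(lo)] += jump
        count[tuple(hi)] += jump
    return count


def conventional_unwrap(
    aliased: VelocityField, params: JumpParams | None = None
) -> tuple[VelocityField, np.ndarray]:
    """Detect and correct aliased voxels by spatio-temporal jump analysis.

    Parameters
    ----------
    aliased
        Velocity field to correct (needs >= 2 cardiac frames).  Not modified.
    params
        Algorithm parameters; defaults to :class:`JumpParams()`.

    Returns
    -------
    corrected : VelocityField
        The corrected field (same venc metadata as the input).
    detected : ndarray of bool
        Mask of all voxels the algorithm modified.
    """
    if params is None:
        params = JumpParams()
    if aliased.n_frames < 2:
        raise ValueError("conventional unwrapping needs >= 2 frames (temporal differences)")
    venc = aliased.venc
    thr = params.jump_threshold_factor * venc
    values = aliased.values.astype(float, copy=True)

    converged = False
    for it in range(params.max_iterations):
        changed = 0
        for name in params.neighborhood:
            ax = _AXIS[name]
            before = values.copy()
            cnt_before = _inconsistent_pairs(before, thr)
            n_pass = _sweep(values, ax, thr, venc, forward=True)
            if name != "time":  # frame 0 is the trusted temporal reference
                n_pass += _sweep(values, ax, thr, venc, forward=False)
            if n_pass:
                # validate: a genuine wrap correction leaves the voxel consistent
                # with its (simultaneously corrected) region, while a jump
                # chained into smooth data raises its neighborhood inconsistency;
                # revert the latter (it may validate in a later iteration once
                # its context has been corrected)
                cnt_after = _inconsistent_pairs(values, thr)
                bad = (values != before) & (cnt_after > cnt_before)
                if bad.any():
                    values[bad] = before[bad]
                    n_pass -= int(bad.sum())
            changed += n_pass
        logger.info("conventional_unwrap: iteration %d net corrections %d", it + 1, changed)
        if changed == 0:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"conventional_unwrap did not converge in {params.max_iterations} "
            "iterations; returning the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    # a voxel counts as detected when it ended up net-shifted by a wrap
    # (transient corrections repaired within the iteration leave only
    # float-rounding residue, far below venc)
    detected = np.abs(values - aliased.values) > venc
    return aliased.with_values(values), detected
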