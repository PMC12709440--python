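"""Cortical and perinuclear dynein.

Dynein motors occupy a fixed random subset of membrane and nucleus beads
(chosen once per seed at initialization).  An unoccupied anchor binds the
nearest microtubule point within its capture radius at rate ``k_on``
(attachment is discretized to the nearest bead; bead spacing is half the
capture radius).  A bound motor walks toward the minus end at ``v_motor``
and pulls through a zero-rest-length linear spring; it detaches at rate
``k_off``, when the spring load exceeds ``f_stall``, or when the plus end
shrinks past its attachment point.  Because all MT minus ends are anchored
at the centrosome, the net effect is a pulling force on the centrosome
toward the cortex and the nuclear envelope.

Reference implementations; the engine runs the identical rules inside the
compiled chunk kernel.
"""

from __future__ import annotations

import numpy as np

from .params import Params
from .state import CellState

__all__ = ["motor_attach", "motor_step_and_pull", "anchor_positions"]


def anchor_positions(state: CellState) -> np.ndarray:
    """Current (A, 2) positions of all motor anchors."""
    mo = state.motors
    pos = np.empty((mo.n_anchors, 2))
    memsel = mo.anchor_loop == 0
    pos[memsel] = state.membrane.pos[mo.anchor_bead[memsel]]
    pos[~memsel] = state.nucleus.pos[mo.anchor_bead[~memsel]]
    return pos


def motor_attach(state: CellState, params: Params,
                 rng: np.random.Generator | None = None,
                 u: np.ndarray | None = None) -> int:
    """Bind unoccupied anchors to nearby microtubules (in place).

    Each unoccupied anchor binds, with probability ``1 - exp(-k_on dt)``,
    the nearest MT bead within ``r_capture``; ``arc_pos`` is set to that
    bead's arc-length position.  One uniform variate is consumed per anchor
    per step (pass ``u`` to replay a recorded stream).  Returns the number
    of new attachments.
    """
    mo = state.motors
    if mo.n_anchors == 0 or state.mts.N == 0:
        return 0
    d = params.dynein
    p_on = 1.0 - np.exp(-d.k_on * params.dt)
    apos = anchor_positions(state)
    if u is None:
        u = rng.random(mo.n_anchors)
    n_new = 0
    for a in range(mo.n_anchors):
        if mo.bound[a]:
            continue
        best_d2, best_m, best_b = d.r_capture ** 2, -1, -1
        for m in range(state.mts.N):
            nb = int(state.mts.n_beads[m])
            dd = state.mts.pos[m, :nb] - apos[a]
            d2 = dd[:, 0] ** 2 + dd[:, 1] ** 2
            b = int(np.argmin(d2))
            if d2[b] < best_d2:
                best_d2, best_m, best_b = float(d2[b]), m, b
        if best_m >= 0 and u[a] < p_on:
            mo.bound[a] = True
            mo.mt_index[a] = best_m
            mo.arc_pos[a] = best_b * params.sigma_mt
            n_new += 1
    return n_new


def motor_step_and_pull(state: CellState, params: Params,
                        rng: np.random.Generator | None = None,
                        u: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Walk bound motors minus-end-ward and apply their spring forces.

    Returns ``(f_mem, f_nuc, f_mt)`` force arrays; attachment bookkeeping
    (arc positions, detachments) is updated in place.  Spring forces are
    applied to the anchor bead and, with lever-rule weights, to the two MT
    beads bracketing the attachment point; minus-end components are
    delivered to the centrosome by the engine's anchoring constraint.
    """
    mo = state.motors
    d = params.dynein
    sigma = params.sigma_mt
    p_off = 1.0 - np.exp(-d.k_off * params.dt)
    f_mem = np.zeros_like(state.membrane.pos)
    f_nuc = np.zeros_like(state.nucleus.pos)
    f_mt = np.zeros_like(state.mts.pos)
    apos = anchor_positions(state)
    if u is None:
        u = rng.random(mo.n_anchors)
    for a in range(mo.n_anchors):
        if not mo.bound[a]:
            continue
        m = int(mo.mt_index[a])
        if m < 0 or m >= state.mts.N:
            mo.bound[a] = False  # dangling index: drop the attachment
            mo.mt_index[a] = -1
            continue
        L = float(state.mts.lengths(sigma)[m])
        arc = mo.arc_pos[a] - d.v_motor * params.dt
        mo.arc_pos[a] = arc
        if arc <= 0.0:
            # reached the minus end: end dissociation (prevents a standing
            # anchor-to-centrosome spring from dragging the cortex into the
            # dense aster core)
            mo.bound[a] = False
            mo.mt_index[a] = -1
            mo.arc_pos[a] = 0.0
            continue
        if arc > L:
            mo.bound[a] = False  # tip shrank past the motor
            mo.mt_index[a] = -1
            continue
        if u[a] < p_off:
            mo.bound[a] = False
            mo.mt_index[a] = -1
            continue
        nb = int(state.mts.n_beads[m])
        if nb < 2:
            j, frac = 0, 0.0
            pt = state.mts.pos[m, 0]
        else:
            j = min(int(arc / sigma), nb - 2)
            frac = min(arc / sigma - j, 1.0)
            pt = (1 - frac) * state.mts.pos[m, j] + frac * state.mts.pos[m, j + 1]
        fvec = d.k_motor * (pt - apos[a])
        if np.hypot(fvec[0], fvec[1]) > d.f_stall:
            mo.bound[a] = False  # stall-force detachment, no force applied
            mo.mt_index[a] = -1
            continue
        if mo.anchor_loop[a] == 0:
            f_mem[mo.anchor_bead[a]] += fvec
        else:
            f_nuc[mo.anchor_bead[a]] += fvec
        if nb < 2:
            f_mt[m, 0] -= fvec
        else:
            f_mt[m, j] -= (1 - frac) * fvec
            f_mt[m, j + 1] -= frac * fvec
    return f_mem, f_nuc, f_mt
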