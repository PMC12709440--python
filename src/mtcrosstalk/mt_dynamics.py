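"""Microtubule dynamic instability and plus-end bead bookkeeping.

A microtubule is a bead chain anchored at the centrosome that alternates
stochastically between a growth state (plus end advances at ``vg``) and a
shrink state (retracts at ``vs``); growth switches to shrinkage at the
catastrophe rate ``fc`` and back at the rescue rate ``fr``.  In the bounded
regime ``vg*fr < vs*fc`` the free-filament length distribution is
exponential with mean ``vg*vs / (fc*vs - fr*vg)``; the engine derives
``fc`` from a target mean length (see
:func:`mtcrosstalk.params.derive_catastrophe_rate`).

Beads are added/removed at the plus end in ``sigma_mt`` quanta, with a
sub-bead accumulator ``partial_tip``; a filament that shrinks to zero
length immediately re-nucleates in the growth state along a fresh uniformly
random direction, so the number of filaments is conserved.

These per-filament functions are the readable reference path; the engine
applies the identical update rules inside the compiled chunk kernel.
"""

from __future__ import annotations

import numpy as np

from .mechanics import bend_forces, stretch_forces
from .params import Params
from .state import GROW, SHRINK, Microtubule

__all__ = [
    "update_dynamic_state", "advance_tip", "mt_internal_forces",
    "switch_probabilities", "simulate_free_lengths",
]


def switch_probabilities(params: Params) -> tuple[float, float]:
    """Per-step catastrophe and rescue probabilities ``1 - exp(-rate*dt)``."""
    fc = params.catastrophe_rate()
    return (1.0 - np.exp(-fc * params.dt),
            1.0 - np.exp(-params.fr * params.dt))


def update_dynamic_state(mt: Microtubule, params: Params,
                         rng: np.random.Generator) -> Microtubule:
    """Stochastic growth/shrink switching for one step (in place)."""
    p_cat, p_res = switch_probabilities(params)
    u = rng.random()
    if mt.state == GROW:
        if u < p_cat:
            mt.state = SHRINK
    else:
        if u < p_res:
            mt.state = GROW
    return mt

def advance_tip(mt: Microtubule, params: Params,
                rng: np.random.Generator | None = None,
                u_renuc: float | None = None,
                blocked=None) -> Microtubule:
    """Advance the plus end by one step (in place).

    Growth appends beads along the terminal tangent whenever the sub-bead
    accumulator fills; shrinkage removes beads when it empties.  A filament
    that loses its last length re-nucleates at the minus end: state GROW,
    zero length, fresh uniformly random direction (drawn from ``rng``).
    Lengths are capped at ``mt_length_cap_factor * lmt_target`` by a forced
    catastrophe (padded-storage bound; the exponential tail beyond 4 mean
    lengths carries ~2% of the mass).

    ``blocked``, when given, maps ``(candidate, tip)`` to the position to
    use for the new bead (possibly deflected along a surface, i.e. tip
    gliding) or None, in which case the addition is deferred with the
    accumulator held at the threshold (head-on contact-stalled
    polymerization).
    """
    sigma = params.sigma_mt
    if mt.state == GROW:
        mt.partial_tip += params.vg * params.dt
        cap = params.mt_length_cap_factor * params.lmt_target
        if mt.length(sigma) > cap:
            mt.state = SHRINK
            return mt
        while mt.partial_tip >= sigma:
            t = mt.tangent()
            new = mt.beads[-1] + sigma * t
            if blocked is not None:
                new = blocked(new, mt.beads[-1])
                if new is None:
                    mt.partial_tip = sigma
                    break
            mt.beads = np.vstack([mt.beads, new])
            mt.partial_tip -= sigma
    else:
        mt.partial_tip -= params.vs * params.dt
        while mt.partial_tip < 0.0:
            if len(mt.beads) > 1:
                mt.beads = mt.beads[:-1]
                mt.partial_tip += sigma
            else:
                if u_renuc is not None:
                    theta = 2.0 * np.pi * u_renuc
                elif rng is not None:
                    theta = 2.0 * np.pi * rng.random()
                else:
                    theta = 0.0
                mt.direction = np.array([np.cos(theta), np.sin(theta)])
                mt.state = GROW
                mt.partial_tip = 0.0
                break
    return mt


def mt_internal_forces(mt: Microtubule, params: Params) -> np.ndarray:
    """Stretching + bending forces along the chain, ``(n_beads, 2)``.

    The minus-end (bead 0) component is the force the filament delivers to
    the centrosome through its anchoring constraint.
    """
    f = stretch_forces(mt.beads, params.ks_mt, params.sigma_mt, closed=False)
    if len(mt.beads) >= 3:
        f = f + bend_forces(mt.beads, params.kappa_mt, params.sigma_mt,
                            0.0, closed=False)
    return f


def simulate_free_lengths(params: Params, t_total: float, dt: float,
                          n_mt: int, seed: int,
                          record_every: int = 10) -> np.ndarray:
    """Free (unconstrained, uncapped) two-state length dynamics.

    Vectorized simulation of ``n_mt`` independent filaments with the same
    switching and speed rules as the engine but lengths tracked as scalars
    (no beads, no walls, no length cap).  Used for the mean-length law and
    for length-distribution checks.

    Returns the flattened array of lengths sampled every ``record_every``
    steps after a burn-in of 20% of the run.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    fc = params.catastrophe_rate()
    p_cat = 1.0 - np.exp(-fc * dt)
    p_res = 1.0 - np.exp(-params.fr * dt)
    n_steps = int(round(t_total / dt))
    L = np.zeros(n_mt)
    growing = np.ones(n_mt, dtype=bool)
    burn = int(0.2 * n_steps)
    out = []
    for s in range(n_steps):
        u = rng.random(n_mt)
        switch_g = growing & (u < p_cat)
        switch_s = ~growing & (u < p_res)
        growing = growing ^ switch_g ^ switch_s
        L = np.where(growing, L + params.vg * dt, L - params.vs * dt)
        renuc = L < 0.0
        if np.any(renuc):
            L[renuc] = 0.0
            growing[renuc] = True
        if s >= burn and s % record_every == 0:
            out.append(L.copy())
    return np.concatenate(out)
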