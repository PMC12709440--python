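"""Passive forces and the overdamped time-stepper.

All filaments and boundaries are bead-spring objects: Hookean stretching
along bonds, a discrete worm-like-chain bending energy at vertices, and a
purely repulsive truncated-shifted Lennard-Jones (WCA) potential for steric
exclusion.  Beads follow overdamped first-order dynamics

    x(t + dt) = x(t) + dt * (F / gamma + v_active)

with no thermal noise: stochasticity enters the model only through
microtubule dynamic instability and motor kinetics.

These are the readable vectorized reference implementations; the engine's
inner loop uses compiled kernels (:mod:`mtcrosstalk._kernels`) that are
cross-checked against these functions in the test suite.
"""

from __future__ import annotations

import numpy as np

from .params import Params
from .state import CellState

__all__ = [
    "WCA_CUTOFF_FACTOR", "stretch_forces", "bend_forces", "wca_pair_force",
    "wca_pair_energy", "stretch_energy", "bend_energy", "all_steric_forces",
    "step_positions", "elastic_energy", "TimestepError",
]

#: WCA cutoff in units of sigma: 2^(1/6)
WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)


class TimestepError(RuntimeError):
    """A bead moved more than half a bead diameter in one step."""


# --------------------------------------------------------------------------
# stretching
# --------------------------------------------------------------------------

def stretch_forces(pos: np.ndarray, ks: float, rest_bond: float,
                   closed: bool = True) -> np.ndarray:
    """Hookean bond forces ``-ks (|r| - rest)`` along each bond.

    Equal and opposite on bond partners; zero-length bonds contribute a
    capped (zero-direction) force and are effectively skipped.
    """
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    f = np.zeros_like(pos)
    if n < 2:
        return f
    if closed:
        bonds = np.roll(pos, -1, axis=0) - pos         # i -> i+1 (mod n)
    else:
        bonds = pos[1:] - pos[:-1]
    r = np.hypot(bonds[:, 0], bonds[:, 1])
    safe = np.where(r > 1e-12, r, 1.0)
    coef = np.where(r > 1e-12, ks * (r - rest_bond) / safe, 0.0)
    fb = coef[:, None] * bonds                          # pulls i toward i+1
    if closed:
        f += fb
        f -= np.roll(fb, 1, axis=0)
    else:
        f[:-1] += fb
        f[1:] -= fb
    return f


def stretch_energy(pos: np.ndarray, ks: float, rest_bond: float,
                   closed: bool = True) -> float:
    pos = np.asarray(pos, dtype=float)
    if closed:
        bonds = np.roll(pos, -1, axis=0) - pos
    else:
        bonds = pos[1:] - pos[:-1]
    r = np.hypot(bonds[:, 0], bonds[:, 1])
    return float(0.5 * ks * np.sum((r - rest_bond) ** 2))


# --------------------------------------------------------------------------
# bending
# --------------------------------------------------------------------------

def _turning_angles(pos: np.ndarray, closed: bool):
    """Signed turning angle at each vertex plus the bond vectors (a, b)."""
    if closed:
        a = pos - np.roll(pos, 1, axis=0)     # incoming bond at vertex i
        b = np.roll(pos, -1, axis=0) - pos    # outgoing bond
    else:
        a = pos[1:-1] - pos[:-2]
        b = pos[2:] - pos[1:-1]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    return np.arctan2(cross, dot), a, b


def bend_energy(pos: np.ndarray, kappa: float, rest_bond: float,
                rest_angle: float = 0.0, closed: bool = True) -> float:
    """Discrete worm-like-chain energy ``kappa/(2 l0) sum (theta - theta0)^2``."""
    theta, _, _ = _turning_angles(np.asarray(pos, dtype=float), closed)
    return float(kappa / (2.0 * rest_bond) * np.sum((theta - rest_angle) ** 2))


def bend_forces(pos: np.ndarray, kappa: float, rest_bond: float,
                rest_angle: float = 0.0, closed: bool = True) -> np.ndarray:
    """Force = -grad of the discrete worm-like-chain bending energy.

    For a ring every vertex carries the energy with ``rest_angle`` equal to
    the exterior angle of the regular polygon; for an open chain only
    interior vertices contribute and the ends are free (``rest_angle = 0``
    for microtubules).
    """
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    f = np.zeros_like(pos)
    if n < 3:
        return f
    theta, a, b = _turning_angles(pos, closed)
    la2 = a[:, 0] ** 2 + a[:, 1] ** 2
    lb2 = b[:, 0] ** 2 + b[:, 1] ** 2
    # grad of the signed angle: perpendicular kicks on the three beads
    ga = np.column_stack([-a[:, 1], a[:, 0]]) / la2[:, None]   # d theta / d r_{i-1}
    gb = np.column_stack([-b[:, 1], b[:, 0]]) / lb2[:, None]   # d theta / d r_{i+1}
    w = (kappa / rest_bond) * (theta - rest_angle)
    fa = -w[:, None] * ga
    fb = -w[:, None] * gb
    fi = w[:, None] * (ga + gb)
    if closed:
        f += fi
        f += np.roll(fa, -1, axis=0)   # vertex i pushes bead i-1
        f += np.roll(fb, 1, axis=0)    # vertex i pushes bead i+1
    else:
        f[1:-1] += fi
        f[:-2] += fa
        f[2:] += fb
    return f


def area_pressure_forces(pos: np.ndarray, k_area: float,
                         area0: float) -> np.ndarray:
    """Pressure forces restoring the enclosed (signed) area of a ring.

    Derived from ``E = k_area (A - A0)^2 / (2 A0)`` with the shoelace area;
    used for the nucleus, whose interior is effectively incompressible.
    """
    pos = np.asarray(pos, dtype=float)
    from .state import polygon_area
    area = polygon_area(pos)
    coef = k_area * (area0 - area) / area0
    grad = 0.5 * np.column_stack([
        np.roll(pos[:, 1], -1) - np.roll(pos[:, 1], 1),
        np.roll(pos[:, 0], 1) - np.roll(pos[:, 0], -1),
    ])
    return coef * grad


# --------------------------------------------------------------------------
# WCA steric repulsion
# --------------------------------------------------------------------------

def wca_pair_force(r: np.ndarray, sigma: float, eps: float,
                   f_cap: float = np.inf) -> np.ndarray:
    """Purely repulsive WCA force on the bead at separation ``r`` from its
    partner (force points along ``r``, i.e. away from the partner).

    Zero for ``|r| >= 2^(1/6) sigma``; magnitude
    ``24 eps (2 (sigma/d)^13 - (sigma/d)^7) / sigma`` otherwise, capped at
    ``f_cap`` for deep overlaps.
    """
    r = np.asarray(r, dtype=float)
    d = float(np.hypot(r[0], r[1]))
    if d >= WCA_CUTOFF_FACTOR * sigma or d < 1e-12:
        return np.zeros(2)
    s6 = (sigma / d) ** 6
    mag = 24.0 * eps * (2.0 * s6 * s6 - s6) / d
    mag = min(mag, f_cap)
    return (mag / d) * r


def wca_pair_energy(d: float, sigma: float, eps: float) -> float:
    if d >= WCA_CUTOFF_FACTOR * sigma:
        return 0.0
    s6 = (sigma / d) ** 6
    return 4.0 * eps * (s6 * s6 - s6) + eps


# --------------------------------------------------------------------------
# full steric force assembly (grid accelerated)
# --------------------------------------------------------------------------

def all_steric_forces(state: CellState, env, params: Params) -> dict:
    """All WCA contributions for the current configuration.

    Pair classes (bonded neighbors and same-filament pairs excluded):
    MT bead <-> membrane bead, MT bead <-> nucleus bead, membrane <->
    nucleus, non-neighbor membrane <-> membrane (self-avoidance),
    any bead <-> obstacle/wall, centrosome <-> nucleus.  MT minus-end beads
    (pinned to the centrosome) are excluded; the centrosome-nucleus pair
    rule covers that contact.

    Returns ``{"membrane": (n_mem,2), "nucleus": ..., "centrosome": (2,),
    "mts": (N, maxB, 2)}``.  Uses the same compiled grid/pair machinery as
    the engine, with a zero Verlet skin so the pair list is exact.
    """
    from . import _kernels as K
    from .environment import Environment

    if env is None:
        env = Environment.empty()
    pl = K.PairLists.build(state, env, params, skin=0.0)
    f_mem = np.zeros_like(state.membrane.pos)
    f_nuc = np.zeros_like(state.nucleus.pos)
    f_mt = np.zeros_like(state.mts.pos)
    f_cen = np.zeros(2)
    K.eval_steric(state, env, params, pl, f_mem, f_nuc, f_mt, f_cen)
    return {"membrane": f_mem, "nucleus": f_nuc, "centrosome": f_cen,
            "mts": f_mt}


# --------------------------------------------------------------------------
# integrator
# --------------------------------------------------------------------------

def step_positions(pos: np.ndarray, forces: np.ndarray, gamma: float,
                   dt: float, v_active: np.ndarray | None = None,
                   max_disp: float = np.inf) -> np.ndarray:
    """One forward Euler step of the overdamped dynamics for one bead set.

    Raises :class:`TimestepError` if any displacement exceeds ``max_disp``
    (the engine uses ``0.5 * sigma_mt``).
    """
    v = forces / gamma
    if v_active is not None:
        v = v + v_active
    disp = dt * v
    dmax = float(np.max(np.hypot(disp[..., 0], disp[..., 1]))) if disp.size else 0.0
    if dmax > max_disp:
        raise TimestepError(
            f"timestep too large: displacement {dmax:.3g} um exceeds "
            f"{max_disp:.3g} um")
    out = pos + disp
    if not np.all(np.isfinite(out)):
        raise TimestepError("non-finite coordinate after step")
    return out


def elastic_energy(state: CellState, params: Params) -> float:
    """Total passive elastic energy (stretch + bend of all filaments and
    loops plus nucleus-membrane coupling); used in relaxation tests."""
    from .crosstalk import coupling_pairs

    mem, nuc = state.membrane, state.nucleus
    e = stretch_energy(mem.pos, params.ks_mem, mem.rest_bond, closed=True)
    e += bend_energy(mem.pos, params.kappa_mem, mem.rest_bond,
                     mem.rest_angle, closed=True)
    e += stretch_energy(nuc.pos, params.ks_nuc, nuc.rest_bond, closed=True)
    e += bend_energy(nuc.pos, params.kappa_nuc, nuc.rest_bond,
                     nuc.rest_angle, closed=True)
    for i in range(state.mts.N):
        m = int(state.mts.n_beads[i])
        if m >= 2:
            chain = state.mts.pos[i, :m]
            e += stretch_energy(chain, params.ks_mt, params.sigma_mt,
                                closed=False)
            e += bend_energy(chain, params.kappa_mt, params.sigma_mt, 0.0,
                             closed=False)
    pairs = coupling_pairs(params.n_nuc_beads, params.n_mem_beads)
    d = mem.pos[pairs] - nuc.pos
    r = np.hypot(d[:, 0], d[:, 1])
    e += float(0.5 * params.k_couple * np.sum((r - params.rest_couple) ** 2))
    return e
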