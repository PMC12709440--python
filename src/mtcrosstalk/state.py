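"""Domain types and state construction for the whole-cell simulator.

The mutable simulation state holds two bead-spring loops (cell membrane and
nucleus), a point centrosome, an ensemble of bead-chain microtubules with
their minus ends pinned at the centrosome, and the dynein attachment table.
Microtubule beads live in a padded ``(Nmt, max_beads, 2)`` array so the
ensemble can be advanced with vectorized / compiled kernels; ``Microtubule``
offers a per-filament view for single-MT operations and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParamError, Params

GROW = 1
SHRINK = 0

__all__ = [
    "GROW", "SHRINK", "BeadLoop", "Microtubule", "MTEnsemble",
    "MotorState", "CellState", "make_initial_state", "regular_polygon",
    "polygon_area", "max_mt_beads", "states_equal",
]


def regular_polygon(n: int, radius: float, center=(0.0, 0.0)) -> np.ndarray:
    """Vertices of a regular n-gon, counter-clockwise, starting at +x."""
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def polygon_area(pos: np.ndarray) -> float:
    """Shoelace area (positive for counter-clockwise winding)."""
    x, y = pos[:, 0], pos[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def polygon_is_simple(pos: np.ndarray) -> bool:
    """True if no two non-adjacent edges of the closed ring cross."""
    n = len(pos)
    edges = [(pos[i], pos[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent around the ring
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True


@dataclass
class BeadLoop:
    """Closed bead-spring ring with a rest bond length and rest angle.

    The rest angle is the exterior angle of the regular n-gon, so the
    relaxed shape of the ring is a circle of the initial radius.
    """

    pos: np.ndarray          # (n, 2) um
    rest_bond: float         # um
    rest_angle: float        # rad, exterior angle of the regular n-gon

    @classmethod
    def circle(cls, n: int, radius: float, center=(0.0, 0.0)) -> "BeadLoop":
        pos = regular_polygon(n, radius, center)
        rest_bond = 2.0 * radius * np.sin(np.pi / n)
        return cls(pos=pos, rest_bond=rest_bond, rest_angle=2.0 * np.pi / n)

    @property
    def n(self) -> int:
        return len(self.pos)

    @property
    def area(self) -> float:
        return abs(polygon_area(self.pos))

    @property
    def perimeter(self) -> float:
        d = np.roll(self.pos, -1, axis=0) - self.pos
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def centroid(self) -> np.ndarray:
        return self.pos.mean(axis=0)

    def copy(self) -> "BeadLoop":
        return BeadLoop(self.pos.copy(), self.rest_bond, self.rest_angle)


@dataclass
class Microtubule:
    """Single microtubule: bead chain with the minus end at index 0.

    ``length = (n_beads - 1) * sigma + partial_tip`` where ``partial_tip``
    in [0, sigma) accumulates sub-bead growth at the plus end.  ``direction``
    is the nucleation direction, used as the growth tangent while the chain
    has a single bead.
    """

    beads: np.ndarray        # (m, 2)
    state: int               # GROW or SHRINK
    partial_tip: float
    direction: np.ndarray    # (2,) unit vector

    def length(self, sigma: float) -> float:
        return (len(self.beads) - 1) * sigma + self.partial_tip

    def tangent(self) -> np.ndarray:
        if len(self.beads) >= 2:
            t = self.beads[-1] - self.beads[-2]
            nrm = np.hypot(t[0], t[1])
            if nrm > 1e-12:
                return t / nrm
        return self.direction.copy()


@dataclass
class MTEnsemble:
    """Padded array-of-chains microtubule ensemble."""

    pos: np.ndarray       # (N, maxB, 2)
    n_beads: np.ndarray   # (N,) int64, >= 1
    state: np.ndarray     # (N,) int64 (GROW/SHRINK)
    partial: np.ndarray   # (N,) float
    direction: np.ndarray  # (N, 2) nucleation directions
    era: np.ndarray       # (N, maxB) int64, bumped when a bead is (re)created

    @property
    def N(self) -> int:
        return len(self.n_beads)

    @property
    def max_beads(self) -> int:
        return self.pos.shape[1]

    def lengths(self, sigma: float) -> np.ndarray:
        return (self.n_beads - 1) * sigma + self.partial

    def tips(self) -> np.ndarray:
        """Plus-end tip positions, (N, 2)."""
        if self.N == 0:
            return np.zeros((0, 2))
        return self.pos[np.arange(self.N), self.n_beads - 1]

    def mt(self, i: int) -> Microtubule:
        """Copy of filament *i* as a standalone :class:`Microtubule`."""
        m = int(self.n_beads[i])
        return Microtubule(self.pos[i, :m].copy(), int(self.state[i]),
                           float(self.partial[i]), self.direction[i].copy())

    def set_mt(self, i: int, mt: Microtubule) -> None:
        m = len(mt.beads)
        if m > self.max_beads:
            raise ValueError("microtubule exceeds the padded capacity")
        old = int(self.n_beads[i])
        self.pos[i, :m] = mt.beads
        if m > old:
            self.era[i, old:m] += 1
        self.n_beads[i] = m
        self.state[i] = mt.state
        self.partial[i] = mt.partial_tip
        self.direction[i] = mt.direction

    def copy(self) -> "MTEnsemble":
        return MTEnsemble(self.pos.copy(), self.n_beads.copy(),
                          self.state.copy(), self.partial.copy(),
                          self.direction.copy(), self.era.copy())


@dataclass
class MotorState:
    """Fixed dynein anchors and their current attachments.

    ``anchor_loop`` is 0 for membrane anchors and 1 for nucleus anchors;
    unbound anchors have ``mt_index = -1``.
    """

    anchor_loop: np.ndarray  # (A,) int64
    anchor_bead: np.ndarray  # (A,) int64
    bound: np.ndarray        # (A,) bool
    mt_index: np.ndarray     # (A,) int64
    arc_pos: np.ndarray      # (A,) float, um from the minus end

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_bead)

    def copy(self) -> "MotorState":
        return MotorState(self.anchor_loop.copy(), self.anchor_bead.copy(),
                          self.bound.copy(), self.mt_index.copy(),
                          self.arc_pos.copy())


@dataclass
class CellState:
    """Full mutable simulation state."""

    membrane: BeadLoop
    nucleus: BeadLoop
    centrosome: np.ndarray   # (2,)
    mts: MTEnsemble
    motors: MotorState
    t: float
    rng_state: dict          # {"mt": ..., "motor": ...} bit-generator states
    signal_grow: np.ndarray = None   # optional exponential signal traces
    signal_shrink: np.ndarray = None

    def copy(self) -> "CellState":
        import copy as _copy
        return CellState(
            self.membrane.copy(), self.nucleus.copy(), self.centrosome.copy(),
            self.mts.copy(), self.motors.copy(), self.t,
            _copy.deepcopy(self.rng_state),
            None if self.signal_grow is None else self.signal_grow.copy(),
            None if self.signal_shrink is None else self.signal_shrink.copy(),
        )


def max_mt_beads(params: Params) -> int:
    """Padded capacity per MT: length cap plus one spare bead."""
    cap = params.mt_length_cap_factor * params.lmt_target
    return int(np.ceil(cap / params.sigma_mt)) + 2


def make_initial_state(params: Params) -> CellState:
    """Build the initial configuration.

    Membrane and nucleus are concentric regular polygons at the origin; the
    centrosome sits at ``(Rnuc + 1, 0)`` (between nucleus surface and cell
    membrane, a fixed symmetry-breaking-free offset); each of the ``Nmt``
    microtubules starts as a single bead at the centrosome with a uniformly
    random nucleation direction.  Deterministic for a given seed.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    s_init, s_mt, s_motor = ss.spawn(3)
    rng_init = np.random.Generator(np.random.PCG64(s_init))
    rng_mt = np.random.Generator(np.random.PCG64(s_mt))
    rng_motor = np.random.Generator(np.random.PCG64(s_motor))

    membrane = BeadLoop.circle(params.n_mem_beads, params.Rcell)
    nucleus = BeadLoop.circle(params.n_nuc_beads, params.Rnuc)
    centrosome = np.array([params.Rnuc + 1.0, 0.0])

    N, maxB = params.Nmt, max_mt_beads(params)
    pos = np.zeros((N, maxB, 2))
    pos[:, 0] = centrosome
    theta = rng_init.uniform(0.0, 2.0 * np.pi, size=N)
    direction = np.column_stack([np.cos(theta), np.sin(theta)])
    mts = MTEnsemble(
        pos=pos,
        n_beads=np.ones(N, dtype=np.int64),
        state=np.full(N, GROW, dtype=np.int64),
        partial=np.zeros(N),
        direction=direction,
        era=np.zeros((N, maxB), dtype=np.int64),
    )

    # fixed random motor anchors
    d = params.dynein
    n_cortex = int(round(d.rho_cortex * params.n_mem_beads))
    n_nucm = int(round(d.rho_nuc * params.n_nuc_beads))
    mem_beads = rng_init.choice(params.n_mem_beads, size=n_cortex,
                                replace=False) if n_cortex else np.empty(0, int)
    nuc_beads = rng_init.choice(params.n_nuc_beads, size=n_nucm,
                                replace=False) if n_nucm else np.empty(0, int)
    loop_ids = np.concatenate([np.zeros(n_cortex, dtype=np.int64),
                               np.ones(n_nucm, dtype=np.int64)])
    beads = np.concatenate([np.sort(mem_beads), np.sort(nuc_beads)]).astype(np.int64)
    A = len(beads)
    motors = MotorState(
        anchor_loop=loop_ids,
        anchor_bead=beads,
        bound=np.zeros(A, dtype=bool),
        mt_index=np.full(A, -1, dtype=np.int64),
        arc_pos=np.zeros(A),
    )

    state = CellState(
        membrane=membrane, nucleus=nucleus, centrosome=centrosome,
        mts=mts, motors=motors, t=0.0,
        rng_state={
            "mt": rng_mt.bit_generator.state,
            "motor": rng_motor.bit_generator.state,
        },
    )
    if params.signal_tau > 0:
        state.signal_grow = np.zeros(params.n_mem_beads)
        state.signal_shrink = np.zeros(params.n_mem_beads)
    return state


def states_equal(a: CellState, b: CellState) -> bool:
    """Bit-exact equality of two states (used by round-trip/resume tests)."""
    checks = [
        np.array_equal(a.membrane.pos, b.membrane.pos),
        a.membrane.rest_bond == b.membrane.rest_bond,
        a.membrane.rest_angle == b.membrane.rest_angle,
        np.array_equal(a.nucleus.pos, b.nucleus.pos),
        a.nucleus.rest_bond == b.nucleus.rest_bond,
        np.array_equal(a.centrosome, b.centrosome),
        np.array_equal(a.mts.pos, b.mts.pos),
        np.array_equal(a.mts.n_beads, b.mts.n_beads),
        np.array_equal(a.mts.state, b.mts.state),
        np.array_equal(a.mts.partial, b.mts.partial),
        np.array_equal(a.mts.direction, b.mts.direction),
        np.array_equal(a.mts.era, b.mts.era),
        np.array_equal(a.motors.anchor_loop, b.motors.anchor_loop),
        np.array_equal(a.motors.anchor_bead, b.motors.anchor_bead),
        np.array_equal(a.motors.bound, b.motors.bound),
        np.array_equal(a.motors.mt_index, b.motors.mt_index),
        np.array_equal(a.motors.arc_pos, b.motors.arc_pos),
        a.t == b.t,
        a.rng_state == b.rng_state,
    ]
    if (a.signal_grow is None) != (b.signal_grow is None):
        return False
    if a.signal_grow is not None:
        checks.append(np.array_equal(a.signal_grow, b.signal_grow))
        checks.append(np.array_equal(a.signal_shrink, b.signal_shrink))
    return all(checks)
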