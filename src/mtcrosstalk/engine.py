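"""Simulation loop orchestration.

Per integration step (order fixed): dynamic-instability switching ->
plus-end advance -> tip-signal computation -> passive forces (stretching,
bending, steric, nucleus-membrane coupling) -> dynein attach/walk/pull ->
crosstalk contraction force + protrusion velocity -> chemotactic bias ->
forward Euler position update -> minus-end re-pinning to the centrosome.

The loop runs in compiled chunks of one recording interval; all random
numbers for a chunk are drawn up front from two independent seeded
substreams (microtubules, motors) so that toggling motors does not shift
the MT randomness and runs are bit-reproducible, including across
snapshot/resume boundaries (pair lists are rebuilt at every chunk start so
a resumed run sees the same force sums).

:func:`reference_step` advances a state by single steps composing the
readable module-level operations; it consumes the same uniform-variate
layout as the compiled path and is used to validate the kernels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _kernels as K
from .crosstalk import (compute_tip_signals, contraction_force,
                        coupling_forces, coupling_pairs, protrusion_velocity)
from .environment import Environment, chemotactic_bias
from .mechanics import TimestepError, bend_forces, stretch_forces
from .motors import motor_attach, motor_step_and_pull
from .mt_dynamics import advance_tip, switch_probabilities
from .params import Params
from .state import CellState, GROW, SHRINK, make_initial_state

__all__ = ["Simulation", "simulate", "reference_step", "TRACK_COLUMNS"]

TRACK_COLUMNS = [
    "t", "x", "y", "cen_x", "cen_y", "nuc_x", "nuc_y",
    "area", "aspect_ratio", "n_grow", "n_shrink",
]

_STATUS_MSG = {
    K.ERR_DISPLACEMENT: "timestep too large: a bead moved more than half a "
                        "bead diameter in one step",
    K.ERR_NONFINITE: "non-finite coordinate encountered",
    K.ERR_PAIR_OVERFLOW: "steric pair-list capacity exceeded",
}


def _pack_params(params: Params, env: Environment) -> np.ndarray:
    p_cat, p_res = switch_probabilities(params)
    d = params.dynein
    PF = np.zeros(K.PF_N)
    PF[K.PF_DT] = params.dt
    PF[K.PF_SIGMA] = params.sigma_mt
    PF[K.PF_EPS] = params.eps_wca
    PF[K.PF_FCAP] = params.f_cap
    PF[K.PF_FCAP_SURF] = params.f_cap_wall
    PF[K.PF_KS_MEM] = params.ks_mem
    PF[K.PF_KAPPA_MEM] = params.kappa_mem
    PF[K.PF_KS_NUC] = params.ks_nuc
    PF[K.PF_KAPPA_NUC] = params.kappa_nuc
    PF[K.PF_KS_MT] = params.ks_mt
    PF[K.PF_KAPPA_MT] = params.kappa_mt
    PF[K.PF_K_COUPLE] = params.k_couple
    PF[K.PF_REST_COUPLE] = params.rest_couple
    PF[K.PF_V_PROT0] = params.v_prot0
    PF[K.PF_F_CONTR0] = params.f_contr0
    PF[K.PF_R_SIGNAL] = params.r_signal
    PF[K.PF_GAMMA_MEM] = params.gamma_mem
    PF[K.PF_GAMMA_NUC] = params.gamma_nuc
    PF[K.PF_GAMMA_CEN] = params.gamma_cen
    PF[K.PF_GAMMA_MT] = params.gamma_mt
    PF[K.PF_P_CAT] = p_cat
    PF[K.PF_P_RES] = p_res
    PF[K.PF_VG] = params.vg
    PF[K.PF_VS] = params.vs
    PF[K.PF_P_ON] = 1.0 - np.exp(-d.k_on * params.dt)
    PF[K.PF_P_OFF] = 1.0 - np.exp(-d.k_off * params.dt)
    PF[K.PF_V_MOTOR] = d.v_motor
    PF[K.PF_K_MOTOR] = d.k_motor
    PF[K.PF_R_CAPTURE] = d.r_capture
    PF[K.PF_F_STALL] = d.f_stall
    PF[K.PF_V_CHEMO] = params.v_chemo
    PF[K.PF_CHEMO_X] = env.v_chemo_dir[0]
    PF[K.PF_CHEMO_Y] = env.v_chemo_dir[1]
    PF[K.PF_SKIN] = params.skin
    PF[K.PF_MAX_DISP] = 0.5 * params.sigma_mt
    PF[K.PF_LEN_CAP] = params.mt_length_cap_factor * params.lmt_target
    PF[K.PF_SIG_DECAY] = (np.exp(-params.dt / params.signal_tau)
                          if params.signal_tau > 0 else 0.0)
    PF[K.PF_N_SUB] = params.n_sub
    PF[K.PF_K_AREA_NUC] = params.k_area_nuc
    PF[K.PF_A0_NUC] = (0.5 * params.n_nuc_beads
                       * np.sin(2 * np.pi / params.n_nuc_beads)
                       * params.Rnuc ** 2)
    PF[K.PF_K_AREA_MEM] = params.k_area_mem
    PF[K.PF_A0_MEM] = (0.5 * params.n_mem_beads
                       * np.sin(2 * np.pi / params.n_mem_beads)
                       * params.Rcell ** 2)
    # bond geometry of the two rings
    PF[K.PF_L0_MEM] = 2.0 * params.Rcell * np.sin(np.pi / params.n_mem_beads)
    PF[K.PF_THETA0_MEM] = 2.0 * np.pi / params.n_mem_beads
    PF[K.PF_L0_NUC] = 2.0 * params.Rnuc * np.sin(np.pi / params.n_nuc_beads)
    PF[K.PF_THETA0_NUC] = 2.0 * np.pi / params.n_nuc_beads
    return PF


def gyration_aspect_ratio(pos: np.ndarray) -> float:
    """sqrt(lambda_max / lambda_min) of the 2D gyration tensor."""
    c = pos - pos.mean(axis=0)
    g = c.T @ c / len(pos)
    ev = np.linalg.eigvalsh(g)
    if ev[0] <= 0:
        return float("inf")
    return float(np.sqrt(ev[1] / ev[0]))


class Simulation:
    """Bound (params, environment, state) triple with the compiled loop."""

    def __init__(self, params: Params, env: Environment | None = None,
                 state: CellState | None = None):
        params.validate()
        self.params = params
        self.env = env if env is not None else Environment.empty()
        self.state = state if state is not None else make_initial_state(params)
        st = self.state
        self.PF = _pack_params(params, self.env)
        nm, nn = st.membrane.n, st.nucleus.n
        N, maxB = st.mts.N, st.mts.max_beads
        A = st.motors.n_anchors
        self.pl = K.PairLists(nm, nn, N, maxB, params.skin)
        self.cpl = coupling_pairs(nn, nm)
        self.mem_aid = np.full(nm, -1, dtype=np.int64)
        self.nuc_aid = np.full(nn, -1, dtype=np.int64)
        for a in range(A):
            if st.motors.anchor_loop[a] == 0:
                self.mem_aid[st.motors.anchor_bead[a]] = a
            else:
                self.nuc_aid[st.motors.anchor_bead[a]] = a
        # scratch
        self.f_mem = np.zeros((nm, 2))
        self.f_nuc = np.zeros((nn, 2))
        self.f_mt = np.zeros((N, maxB, 2))
        self.f_cen = np.zeros(2)
        self.e_mem = np.zeros((nm, 2))
        self.e_nuc = np.zeros((nn, 2))
        self.e_mt = np.zeros((N, maxB, 2))
        self.vact = np.zeros((nm, 2))
        self.normals = np.zeros((nm, 2))
        self.ng = np.zeros(nm)
        self.nsh = np.zeros(nm)
        self.best_d2 = np.zeros(max(A, 1))
        self.best_m = np.zeros(max(A, 1), dtype=np.int64)
        self.best_b = np.zeros(max(A, 1), dtype=np.int64)
        if st.signal_grow is None:
            self.sg = np.zeros(nm)
            self.ss = np.zeros(nm)
        else:
            self.sg = st.signal_grow
            self.ss = st.signal_shrink
        self._obs = self.env.obstacle_array()
        self._segs = self.env.wall_array()
        self._rng_mt = np.random.Generator(np.random.PCG64())
        self._rng_motor = np.random.Generator(np.random.PCG64())
        self._rng_mt.bit_generator.state = st.rng_state["mt"]
        self._rng_motor.bit_generator.state = st.rng_state["motor"]

    @property
    def steps_per_chunk(self) -> int:
        n = int(round(self.params.record_every / self.params.dt))
        return max(n, 1)

    def advance(self, n_steps: int) -> None:
        """Advance by ``n_steps`` steps through the compiled kernel."""
        st = self.state
        N = st.mts.N
        A = st.motors.n_anchors
        u_sw = self._rng_mt.random((n_steps, N))
        u_th = self._rng_mt.random((n_steps, N))
        u_att = self._rng_motor.random((n_steps, A))
        u_det = self._rng_motor.random((n_steps, A))
        status, done = K.advance_chunk(
            st.membrane.pos, st.nucleus.pos, st.centrosome,
            st.mts.pos, st.mts.n_beads, st.mts.state, st.mts.partial,
            st.mts.direction, st.mts.era,
            st.motors.anchor_loop, st.motors.anchor_bead, st.motors.bound,
            st.motors.mt_index, st.motors.arc_pos,
            self.mem_aid, self.nuc_aid,
            self._obs, self._segs, self.cpl,
            self.pl.mm_i, self.pl.mm_j, self.pl.mn_i, self.pl.mn_j,
            self.pl.tm_m, self.pl.tm_b, self.pl.tm_e, self.pl.tm_t,
            self.pl.tn_m, self.pl.tn_b, self.pl.tn_e, self.pl.tn_t,
            self.pl.sb_type, self.pl.sb_i1, self.pl.sb_i2, self.pl.sb_e,
            self.pl.sb_kind, self.pl.sb_k, self.pl.cnt,
            self.pl.ref_mem, self.pl.ref_nuc, self.pl.ref_mt,
            u_sw, u_th, u_att, u_det,
            self.sg, self.ss, 1 if self.params.signal_tau > 0 else 0,
            self.f_mem, self.f_nuc, self.f_mt, self.f_cen,
            self.e_mem, self.e_nuc, self.e_mt, self.vact,
            self.normals, self.ng, self.nsh,
            self.best_d2, self.best_m, self.best_b,
            self.PF, 1,
        )
        st.t += done * self.params.dt
        if status != K.OK:
            raise TimestepError(
                f"{_STATUS_MSG[status]} at t = {st.t:.3f} s")
        st.rng_state = {
            "mt": self._rng_mt.bit_generator.state,
            "motor": self._rng_motor.bit_generator.state,
        }
        if self.params.signal_tau > 0:
            st.signal_grow = self.sg
            st.signal_shrink = self.ss

    def record_row(self) -> list:
        st = self.state
        mem = st.membrane.pos
        cx, cy = mem.mean(axis=0)
        nx, ny = st.nucleus.pos.mean(axis=0)
        grow = int(np.sum(st.mts.state == GROW))
        return [st.t, cx, cy, st.centrosome[0], st.centrosome[1], nx, ny,
                st.membrane.area, gyration_aspect_ratio(mem),
                grow, st.mts.N - grow]

    def run(self, t_total: float | None = None) -> pd.DataFrame:
        """Advance to ``t_total`` (default from params), recording every
        ``record_every`` seconds; returns the track table."""
        if t_total is None:
            t_total = self.params.t_total
        rows = [self.record_row()]
        spc = self.steps_per_chunk
        n_chunks = int(round((t_total - self.state.t) / self.params.record_every))
        for _ in range(max(n_chunks, 0)):
            self.advance(spc)
            rows.append(self.record_row())
        return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def simulate(params: Params, env: Environment | None = None,
             state: CellState | None = None,
             t_total: float | None = None
             ) -> tuple[pd.DataFrame, CellState]:
    """Run a full simulation; returns (track table, final state)."""
    sim = Simulation(params, env, state)
    track = sim.run(t_total)
    return track, sim.state


# ==========================================================================
# readable single-step reference path (validates the kernels)
# ==========================================================================

def reference_step(state: CellState, params: Params, env: Environment,
                   u_sw: np.ndarray, u_th: np.ndarray,
                   u_att: np.ndarray, u_det: np.ndarray) -> CellState:
    """One full engine step composed from the module-level operations.

    Consumes the same per-step uniform-variate rows as the compiled kernel
    (``u_sw``/``u_th`` per MT, ``u_att``/``u_det`` per motor anchor) so the
    two paths can be compared trajectory-by-trajectory.
    """
    from .mechanics import all_steric_forces

    st = state
    p = params
    p_cat, p_res = switch_probabilities(p)

    obs = env.obstacle_array()
    segs = env.wall_array()

    def growth_blocked(new, tip):
        # contact-aware bead placement with tip gliding, delegated to the
        # same deflection primitive the compiled path uses (growth stalls
        # at head-on contact, glides along surfaces otherwise)
        t = (new - tip) / p.sigma_mt
        x, y = K.deflect_growth(tip[0], tip[1], t[0], t[1],
                                st.membrane.pos, st.nucleus.pos, obs, segs,
                                p.sigma_mt)
        if not np.isfinite(x):
            return None
        return np.array([x, y])

    # 1) dynamic instability + tip advance, per filament
    for i in range(st.mts.N):
        mt = st.mts.mt(i)
        if mt.state == GROW:
            if u_sw[i] < p_cat:
                mt.state = SHRINK
        else:
            if u_sw[i] < p_res:
                mt.state = GROW
        advance_tip(mt, p, u_renuc=float(u_th[i]), blocked=growth_blocked)
        st.mts.set_mt(i, mt)
    # 2) tip signals (with the optional exponential cortical memory)
    field = compute_tip_signals(st, p)
    if p.signal_tau > 0:
        dec = np.exp(-p.dt / p.signal_tau)
        if st.signal_grow is None:
            st.signal_grow = np.zeros(st.membrane.n)
            st.signal_shrink = np.zeros(st.membrane.n)
        st.signal_grow = dec * st.signal_grow + (1 - dec) * field.n_grow
        st.signal_shrink = dec * st.signal_shrink + (1 - dec) * field.n_shrink
        field.n_grow = st.signal_grow.copy()
        field.n_shrink = st.signal_shrink.copy()
    # 3) slow forces, held constant over the step: coupling, sterics,
    #    motors, contraction; protrusion + chemotaxis as active velocities
    mem, nuc = st.membrane, st.nucleus
    f_mem, f_nuc = coupling_forces(st, p)
    from .mechanics import area_pressure_forces
    if p.k_area_nuc > 0:
        a0 = (0.5 * p.n_nuc_beads * np.sin(2 * np.pi / p.n_nuc_beads)
              * p.Rnuc ** 2)
        f_nuc = f_nuc + area_pressure_forces(nuc.pos, p.k_area_nuc, a0)
    if p.k_area_mem > 0:
        a0m = (0.5 * p.n_mem_beads * np.sin(2 * np.pi / p.n_mem_beads)
               * p.Rcell ** 2)
        f_mem = f_mem + area_pressure_forces(mem.pos, p.k_area_mem, a0m)
    f_mt = np.zeros_like(st.mts.pos)
    steric = all_steric_forces(st, env, p)
    f_mem += steric["membrane"]
    f_nuc += steric["nucleus"]
    f_mt += steric["mts"]
    f_cen = steric["centrosome"].copy()
    # dynein: walk/pull first, then attachment, as in the engine
    fm, fn, ft = motor_step_and_pull(st, p, u=u_det)
    f_mem += fm
    f_nuc += fn
    f_mt += ft
    motor_attach(st, p, u=u_att)
    f_mem += contraction_force(field, p)
    vact = protrusion_velocity(field, p) + chemotactic_bias(st, env, p)
    # 4) sub-cycled forward Euler: the stiff local elasticity (stretch +
    #    bend) is re-evaluated on each substep
    dts = p.dt / p.n_sub
    for _ in range(p.n_sub):
        e_mem = stretch_forces(mem.pos, p.ks_mem, mem.rest_bond, closed=True)
        e_mem += bend_forces(mem.pos, p.kappa_mem, mem.rest_bond,
                             mem.rest_angle, closed=True)
        e_nuc = stretch_forces(nuc.pos, p.ks_nuc, nuc.rest_bond, closed=True)
        e_nuc += bend_forces(nuc.pos, p.kappa_nuc, nuc.rest_bond,
                             nuc.rest_angle, closed=True)
        e_mt = np.zeros_like(st.mts.pos)
        for i in range(st.mts.N):
            nb = int(st.mts.n_beads[i])
            if nb >= 2:
                chain = st.mts.pos[i, :nb]
                f = stretch_forces(chain, p.ks_mt, p.sigma_mt, closed=False)
                if nb >= 3:
                    f += bend_forces(chain, p.kappa_mt, p.sigma_mt, 0.0,
                                     closed=False)
                e_mt[i, :nb] += f
        mem.pos += dts * ((f_mem + e_mem) / p.gamma_mem + vact)
        nuc.pos += dts * ((f_nuc + e_nuc) / p.gamma_nuc)
        fc_tot = f_cen.copy()
        for i in range(st.mts.N):
            nb = int(st.mts.n_beads[i])
            fc_tot += f_mt[i, 0] + e_mt[i, 0]
            st.mts.pos[i, 1:nb] += (dts / p.gamma_mt
                                    * (f_mt[i, 1:nb] + e_mt[i, 1:nb]))
        st.centrosome += dts * fc_tot / p.gamma_cen
        st.mts.pos[:, 0] = st.centrosome
    st.t += p.dt
    return st
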