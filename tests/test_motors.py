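"""Dynein attachment/detachment kinetics and pulling mechanics."""

import numpy as np
import pytest

from mtcrosstalk import Params, make_initial_state
from mtcrosstalk.motors import anchor_positions, motor_attach, motor_step_and_pull
from mtcrosstalk.state import GROW


def straight_mt_state(params, n_beads=12, direction=(1.0, 0.0)):
    """Initial state whose single MT is a straight chain from the
    centrosome along ``direction``."""
    st = make_initial_state(params)
    mt = st.mts.mt(0)
    d = np.asarray(direction, dtype=float)
    mt.beads = st.centrosome + np.outer(
        np.arange(n_beads) * params.sigma_mt, d)
    mt.state = GROW
    st.mts.set_mt(0, mt)
    return st


class TestAttachment:
    def test_no_mt_in_range_no_attachment(self):
        p = Params(Nmt=1, dynein={"k_on": 1e6})
        st = straight_mt_state(p, n_beads=3)  # MT stays near the centrosome
        motor_attach(st, p, u=np.zeros(st.motors.n_anchors))
        assert not st.motors.bound.any()

    def test_certain_attachment_in_k_on_limit(self):
        # k_on -> infinity: attachment probability 1 in a single step
        p = Params(Nmt=1, dynein={"k_on": 1e7})
        st = straight_mt_state(p, n_beads=14)  # reaches the membrane at +x
        motor_attach(st, p, u=np.random.default_rng(0).random(
            st.motors.n_anchors))
        apos = anchor_positions(st)
        nb = int(st.mts.n_beads[0])
        chain = st.mts.pos[0, :nb]
        in_range = np.array([
            np.min(np.hypot(*(chain - apos[a]).T)) < p.dynein.r_capture
            for a in range(st.motors.n_anchors)])
        assert in_range.any()
        assert np.array_equal(st.motors.bound, in_range)

    def test_attach_fraction_matches_binomial(self):
        # ~1e4 anchor trials at k_on = 1/s, dt = 0.01 s
        p = Params(Nmt=1, dt=0.01, dynein={"k_on": 1.0})
        st = straight_mt_state(p, n_beads=14)
        rng = np.random.default_rng(7)
        apos = anchor_positions(st)
        nb = int(st.mts.n_beads[0])
        chain = st.mts.pos[0, :nb]
        eligible = [a for a in range(st.motors.n_anchors)
                    if np.min(np.hypot(*(chain - apos[a]).T))
                    < p.dynein.r_capture]
        n_trials, n_attached = 0, 0
        for _ in range(10_000 // max(len(eligible), 1)):
            st.motors.bound[:] = False
            st.motors.mt_index[:] = -1
            motor_attach(st, p, u=rng.random(st.motors.n_anchors))
            n_trials += len(eligible)
            n_attached += int(st.motors.bound.sum())
        p_on = 1.0 - np.exp(-p.dynein.k_on * p.dt)
        sd = np.sqrt(n_trials * p_on * (1 - p_on))
        assert abs(n_attached - n_trials * p_on) < 3 * sd

    def test_anchor_never_double_binds(self):
        p = Params(Nmt=20, dynein={"k_on": 1e7})
        st = make_initial_state(p)
        for mt_i in range(st.mts.N):
            mt = st.mts.mt(mt_i)
            mt.beads = st.centrosome + np.outer(
                np.arange(14) * p.sigma_mt, mt.direction)
            st.mts.set_mt(mt_i, mt)
        u = np.zeros(st.motors.n_anchors)
        motor_attach(st, p, u=u)
        bound_once = st.motors.bound.copy()
        mts_once = st.motors.mt_index.copy()
        motor_attach(st, p, u=u)  # second call: bound anchors are skipped
        assert np.array_equal(st.motors.bound, bound_once)
        assert np.array_equal(st.motors.mt_index, mts_once)


class TestPulling:
    def _bind(self, st, anchor, mt=0, arc=3.0):
        st.motors.bound[anchor] = True
        st.motors.mt_index[anchor] = mt
        st.motors.arc_pos[anchor] = arc

    def test_motor_forces_are_internal(self):
        # anchor + bracketing-bead forces sum to zero
        p = Params(Nmt=1, dynein={"k_off": 0.0, "v_motor": 0.0})
        st = straight_mt_state(p, n_beads=14)
        a = int(np.flatnonzero(st.motors.anchor_loop == 0)[0])
        self._bind(st, a, arc=3.3)
        f_mem, f_nuc, f_mt = motor_step_and_pull(
            st, p, u=np.ones(st.motors.n_anchors))
        total = f_mem.sum(axis=0) + f_nuc.sum(axis=0) + \
            f_mt.reshape(-1, 2).sum(axis=0)
        assert np.allclose(total, 0.0, atol=1e-12)
        assert np.hypot(*f_mem[st.motors.anchor_bead[a]]) > 0

    def test_walk_decreases_arc_position(self):
        p = Params(Nmt=1, dynein={"k_off": 0.0, "v_motor": 0.3})
        st = straight_mt_state(p, n_beads=14)
        a = 0
        self._bind(st, a, arc=3.0)
        motor_step_and_pull(st, p, u=np.ones(st.motors.n_anchors))
        assert st.motors.arc_pos[a] == pytest.approx(3.0 - 0.3 * p.dt)

    def test_minus_end_arrival_detaches(self):
        p = Params(Nmt=1, dynein={"k_off": 0.0, "v_motor": 10.0})
        st = straight_mt_state(p, n_beads=14)
        self._bind(st, 0, arc=0.05)
        motor_step_and_pull(st, p, u=np.ones(st.motors.n_anchors))
        assert not st.motors.bound[0]

    def test_tip_shrinks_past_motor_detaches(self):
        p = Params(Nmt=1, dynein={"k_off": 0.0, "v_motor": 0.0})
        st = straight_mt_state(p, n_beads=4)  # length 1.5 um
        self._bind(st, 0, arc=3.0)            # beyond the current length
        motor_step_and_pull(st, p, u=np.ones(st.motors.n_anchors))
        assert not st.motors.bound[0]

    def test_stall_force_detaches_without_pull(self):
        p = Params(Nmt=1, dynein={"k_off": 0.0, "v_motor": 0.0,
                                  "k_motor": 2.0, "f_stall": 2.0})
        st = straight_mt_state(p, n_beads=14)
        a = int(np.flatnonzero(st.motors.anchor_loop == 0)[0])
        self._bind(st, a, arc=0.5)  # far from a membrane anchor: > 1 um
        f_mem, _, f_mt = motor_step_and_pull(
            st, p, u=np.ones(st.motors.n_anchors))
        assert not st.motors.bound[a]
        assert np.allclose(f_mem, 0.0)

    def test_arc_stays_within_length_for_survivors(self):
        p = Params(Nmt=1)
        st = straight_mt_state(p, n_beads=14)
        rng = np.random.default_rng(3)
        for a in range(st.motors.n_anchors):
            self._bind(st, a, arc=rng.uniform(0.2, 6.0))
        motor_step_and_pull(st, p, u=np.ones(st.motors.n_anchors))
        L = float(st.mts.lengths(p.sigma_mt)[0])
        sel = st.motors.bound
        assert np.all(st.motors.arc_pos[sel] >= 0)
        assert np.all(st.motors.arc_pos[sel] <= L)

    def test_centrosome_drift_matches_overdamped_relaxation(self):
        # one straight MT pulled near its minus end by one cortical motor:
        # the centrosome relaxes toward the anchor like a single
        # overdamped degree of freedom (closed-form linear ODE oracle)
        from mtcrosstalk.engine import Simulation

        p = Params(
            Nmt=1, n_mem_beads=40, n_nuc_beads=20,
            # freeze everything except the centrosome
            gamma_mem=1e12, gamma_nuc=1e12, gamma_mt=1e12, gamma_cen=10.0,
            v_prot0=0.0, f_contr0=0.0, k_couple=1e-9, fc=1e-12, fr=0.0,
            vg=1e-9, vs=2e-9, lmt_target=9.3,
            dynein={"k_on": 0.0, "k_off": 0.0, "v_motor": 0.0,
                    "k_motor": 2.0, "f_stall": 100.0, "rho_cortex": 0.2,
                    "rho_nuc": 0.2},
        )
        sim = Simulation(p)
        st = sim.state
        # a 2-bead MT pointing +x; motor anchored on a membrane bead binds
        # at the minus-end region (arc just above zero so it never leaves)
        mt = st.mts.mt(0)
        mt.beads = np.vstack([st.centrosome,
                              st.centrosome + [p.sigma_mt, 0.0]])
        st.mts.set_mt(0, mt)
        # pick the membrane anchor closest to the +x axis so the relaxation
        # path stays clear of the nucleus
        mem_anchors = np.flatnonzero(st.motors.anchor_loop == 0)
        a = int(mem_anchors[np.argmax(
            st.membrane.pos[st.motors.anchor_bead[mem_anchors], 0])])
        bead = int(st.motors.anchor_bead[a])
        st.motors.bound[a] = True
        st.motors.mt_index[a] = 0
        st.motors.arc_pos[a] = 1e-6
        anchor = st.membrane.pos[bead].copy()
        x0 = float(st.centrosome[0])
        n_steps = 100
        sim.advance(n_steps)
        # 1-DOF oracle along the x axis: the centrosome feels the motor
        # spring toward the anchor and the bond spring toward the frozen
        # second MT bead (rest length sigma):
        #   gamma_cen dx/dt = k_m (x_a - x) + ks (b1 - sigma - x)
        km, ks, g = p.dynein.k_motor, p.ks_mt, p.gamma_cen
        xa = float(anchor[0])
        xb = x0 + p.sigma_mt          # frozen bead 1
        x_eq = (km * xa + ks * (xb - p.sigma_mt)) / (km + ks)
        t = n_steps * p.dt
        x_cont = x_eq + (x0 - x_eq) * np.exp(-(km + ks) * t / g)
        assert sim.state.centrosome[1] == pytest.approx(0.0, abs=1e-9)
        assert sim.state.centrosome[0] == pytest.approx(x_cont, abs=2e-3)
        # discrete oracle mirroring the engine's sub-cycled integrator
        # (motor force held over the step, bond force per substep)
        x = x0
        dts = p.dt / p.n_sub
        for _ in range(n_steps):
            fm = km * (xa - x)
            for _ in range(p.n_sub):
                x = x + dts / g * (fm + ks * (xb - p.sigma_mt - x))
        assert sim.state.centrosome[0] == pytest.approx(x, abs=1e-5)
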