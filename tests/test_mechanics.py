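"""Passive forces: Hookean stretching, worm-like-chain bending, WCA sterics,
grid-accelerated pair assembly, and the overdamped stepper."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtcrosstalk import Params, make_initial_state
from mtcrosstalk.environment import Environment, build_obstacle_park
from mtcrosstalk.mechanics import (WCA_CUTOFF_FACTOR, TimestepError,
                                   all_steric_forces, bend_energy,
                                   bend_forces, step_positions,
                                   stretch_energy, stretch_forces,
                                   wca_pair_force)
from mtcrosstalk.state import regular_polygon


class TestStretch:
    def test_rest_separation_gives_zero_force(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0]])
        f = stretch_forces(pos, ks=10.0, rest_bond=1.0, closed=False)
        assert np.allclose(f, 0.0)

    def test_hookes_law_magnitude_and_direction(self):
        # stretched by 1 um at ks = 10 -> 10 pN attraction, antiparallel
        pos = np.array([[0.0, 0.0], [2.0, 0.0]])
        f = stretch_forces(pos, ks=10.0, rest_bond=1.0, closed=False)
        assert f[0] == pytest.approx([10.0, 0.0])
        assert f[1] == pytest.approx([-10.0, 0.0])

    @given(st.integers(min_value=4, max_value=30), st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_random_ring_newton_third_law(self, n, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(scale=3.0, size=(n, 2))
        f = stretch_forces(pos, ks=7.0, rest_bond=0.8, closed=True)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)


class TestBend:
    def test_straight_chain_zero_force(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        f = bend_forces(pos, kappa=2.0, rest_bond=1.0, rest_angle=0.0,
                        closed=False)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_regular_polygon_is_bending_equilibrium(self):
        pos = regular_polygon(24, 5.0)
        f = bend_forces(pos, kappa=2.0, rest_bond=1.0,
                        rest_angle=2 * np.pi / 24, closed=True)
        assert np.allclose(f, 0.0, atol=1e-9)

    @pytest.mark.parametrize("closed", [False, True])
    def test_matches_numerical_gradient(self, closed):
        # central-difference gradient of the bending energy as the oracle
        rng = np.random.default_rng(5)
        n = 8
        pos = regular_polygon(n, 2.0) + rng.normal(scale=0.3, size=(n, 2))
        kappa, l0 = 1.7, 0.9
        theta0 = 2 * np.pi / n if closed else 0.0
        f = bend_forces(pos, kappa, l0, theta0, closed=closed)
        h = 1e-6
        num = np.zeros_like(pos)
        for i in range(n):
            for k in range(2):
                for s, sign in ((h, 1.0), (-h, -1.0)):
                    q = pos.copy()
                    q[i, k] += s
                    num[i, k] += sign * bend_energy(q, kappa, l0, theta0,
                                                    closed=closed)
        num /= -2 * h
        assert np.allclose(f, num, rtol=1e-6, atol=1e-6)

    def test_net_force_and_torque_free(self):
        rng = np.random.default_rng(9)
        pos = np.cumsum(rng.normal(scale=1.0, size=(12, 2)), axis=0)
        f = bend_forces(pos, 2.0, 0.5, 0.0, closed=False)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)
        torque = np.sum(pos[:, 0] * f[:, 1] - pos[:, 1] * f[:, 0])
        assert torque == pytest.approx(0.0, abs=1e-9)


class TestWCA:
    def test_zero_beyond_cutoff(self):
        f = wca_pair_force(np.array([1.13, 0.0]), sigma=1.0, eps=1.0)
        assert np.allclose(f, 0.0)

    def test_zero_at_cutoff_exactly(self):
        r = np.array([WCA_CUTOFF_FACTOR, 0.0])
        f = wca_pair_force(r, sigma=1.0, eps=1.0)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_magnitude_at_sigma(self):
        # closed-form LJ derivative at r = sigma: 24 eps / sigma
        f = wca_pair_force(np.array([1.0, 0.0]), sigma=1.0, eps=1.0)
        assert f[0] == pytest.approx(24.0)
        assert f[1] == 0.0

    def test_repulsive_and_capped(self):
        f = wca_pair_force(np.array([0.05, 0.0]), sigma=1.0, eps=1.0,
                           f_cap=3.0)
        assert f[0] == pytest.approx(3.0)

    @given(st.floats(min_value=0.5, max_value=1.4))
    @settings(max_examples=40, deadline=None)
    def test_always_repulsive_inside_cutoff(self, d):
        f = wca_pair_force(np.array([d, 0.0]), sigma=1.0, eps=0.3)
        assert f[0] >= 0.0


def brute_force_steric(state, env, params):
    """O(N^2) all-pairs oracle mirroring the documented pair classes."""
    sigma, eps, fcap = params.sigma_mt, params.eps_wca, params.f_cap
    mem, nuc = state.membrane.pos, state.nucleus.pos
    nm = len(mem)
    f_mem = np.zeros_like(mem)
    f_nuc = np.zeros_like(nuc)
    f_mt = np.zeros_like(state.mts.pos)
    f_cen = np.zeros(2)

    def wca(r):
        return wca_pair_force(r, sigma, eps, fcap)

    for i in range(nm):
        for j in range(i + 2, nm):
            if i == 0 and j == nm - 1:
                continue
            f = wca(mem[i] - mem[j])
            f_mem[i] += f
            f_mem[j] -= f
        for j in range(len(nuc)):
            f = wca(mem[i] - nuc[j])
            f_mem[i] += f
            f_nuc[j] -= f
    for m in range(state.mts.N):
        for b in range(1, int(state.mts.n_beads[m])):
            p = state.mts.pos[m, b]
            for i in range(nm):
                f = wca(p - mem[i])
                f_mt[m, b] += f
                f_mem[i] -= f
            for j in range(len(nuc)):
                f = wca(p - nuc[j])
                f_mt[m, b] += f
                f_nuc[j] -= f
    for j in range(len(nuc)):
        f = wca(state.centrosome - nuc[j])
        f_cen += f
        f_nuc[j] -= f

    def surface_force(p, g, direction):
        d = g + sigma
        r = np.array([d, 0.0])
        mag = np.hypot(*wca_pair_force(r, sigma, eps, params.f_cap_wall))
        if g < 0:
            mag = params.f_cap_wall * (1.0 - 2.0 * g / sigma)
        return mag * direction

    all_beads = ([("mem", i, mem[i]) for i in range(nm)]
                 + [("nuc", j, nuc[j]) for j in range(len(nuc))]
                 + [("mt", (m, b), state.mts.pos[m, b])
                    for m in range(state.mts.N)
                    for b in range(1, int(state.mts.n_beads[m]))])
    for kind, idx, p in all_beads:
        for (cx, cy, R) in env.obstacles:
            dv = p - np.array([cx, cy])
            dist = np.hypot(*dv)
            if dist < 1e-12:
                continue
            f = surface_force(p, dist - R, dv / dist)
            if kind == "mem":
                f_mem[idx] += f
            elif kind == "nuc":
                f_nuc[idx] += f
            else:
                f_mt[idx[0], idx[1]] += f
        for (ax, ay, bx, by, hw) in env.walls:
            v = np.array([bx - ax, by - ay])
            w = p - np.array([ax, ay])
            t = np.clip((w @ v) / (v @ v), 0.0, 1.0)
            dv = p - (np.array([ax, ay]) + t * v)
            dist = np.hypot(*dv)
            if dist < 1e-12:
                continue
            f = surface_force(p, dist - hw, dv / dist)
            if kind == "mem":
                f_mem[idx] += f
            elif kind == "nuc":
                f_nuc[idx] += f
            else:
                f_mt[idx[0], idx[1]] += f
    return {"membrane": f_mem, "nucleus": f_nuc, "mts": f_mt,
            "centrosome": f_cen}


def _squeezed_state(seed=0, Nmt=8):
    """A deliberately crowded configuration with many contacts."""
    rng = np.random.default_rng(seed)
    p = Params(Nmt=Nmt, n_mem_beads=60, n_nuc_beads=30)
    st = make_initial_state(p)
    st.membrane.pos *= 0.55          # shrink the membrane onto the nucleus
    st.membrane.pos += rng.normal(scale=0.05, size=st.membrane.pos.shape)
    st.nucleus.pos += rng.normal(scale=0.05, size=st.nucleus.pos.shape)
    for m in range(st.mts.N):
        mt = st.mts.mt(m)
        nb = rng.integers(2, 12)
        direc = mt.direction
        mt.beads = st.centrosome + np.outer(np.arange(nb) * p.sigma_mt, direc)
        st.mts.set_mt(m, mt)
    return p, st


class TestAllStericForces:
    def test_grid_equals_brute_force_free_space(self):
        p, st = _squeezed_state()
        env = Environment.empty()
        got = all_steric_forces(st, env, p)
        want = brute_force_steric(st, env, p)
        for key in want:
            assert np.allclose(got[key], want[key], atol=1e-9), key

    def test_grid_equals_brute_force_with_obstacles_and_walls(self):
        p, st = _squeezed_state(seed=3)
        env = build_obstacle_park(Robs=4.0, spacing=20.0, extent=40.0)
        env.walls.append((-3.0, -8.0, 3.0, 8.0, 0.5))
        got = all_steric_forces(st, env, p)
        want = brute_force_steric(st, env, p)
        for key in want:
            assert np.allclose(got[key], want[key], atol=1e-9), key

    def test_isolated_cell_has_no_steric_forces(self):
        p = Params()
        st = make_initial_state(p)
        got = all_steric_forces(st, Environment.empty(), p)
        # relaxed initial geometry: nothing is within a WCA cutoff
        for key in ("membrane", "nucleus", "mts"):
            assert np.allclose(got[key], 0.0)

    def test_internal_pair_forces_sum_to_zero(self):
        p, st = _squeezed_state(seed=7)
        got = all_steric_forces(st, Environment.empty(), p)
        total = (got["membrane"].sum(axis=0) + got["nucleus"].sum(axis=0)
                 + got["mts"].reshape(-1, 2).sum(axis=0) + got["centrosome"])
        assert np.allclose(total, 0.0, atol=1e-9)

    def test_mt_membrane_reciprocity(self):
        # an MT tip pressed into the membrane pushes the membrane outward
        # and feels the equal opposite force
        p = Params(Nmt=1)
        st = make_initial_state(p)
        mt = st.mts.mt(0)
        target = st.membrane.pos[0]  # bead at (Rcell, 0)
        mt.beads = np.array([st.centrosome,
                             target - [0.45 * p.sigma_mt, 0.0]])
        st.mts.set_mt(0, mt)
        got = all_steric_forces(st, Environment.empty(), p)
        f_on_mt = got["mts"][0, 1]
        f_on_mem_total = got["membrane"].sum(axis=0)
        # outward push on the membrane, equal inward push on the MT tip
        # (the tip may touch several adjacent membrane beads)
        assert f_on_mt[0] < 0 < got["membrane"][0, 0]
        assert np.allclose(f_on_mt + f_on_mem_total, 0.0, atol=1e-12)


class TestStepper:
    def test_zero_force_leaves_positions_unchanged(self):
        pos = np.arange(10.0).reshape(5, 2)
        out = step_positions(pos, np.zeros_like(pos), gamma=1.0, dt=0.01)
        assert np.array_equal(out, pos)

    def test_constant_force_advances_linearly(self):
        pos = np.zeros((1, 2))
        f = np.array([[1.0, 0.0]])
        for _ in range(100):
            pos = step_positions(pos, f, gamma=1.0, dt=0.01)
        assert pos[0, 0] == pytest.approx(1.0)

    def test_displacement_guard_raises(self):
        pos = np.zeros((1, 2))
        f = np.array([[1000.0, 0.0]])
        with pytest.raises(TimestepError, match="timestep too large"):
            step_positions(pos, f, gamma=1.0, dt=0.01, max_disp=0.25)

    def test_passive_ring_relaxation_dissipates_energy(self):
        # a perturbed ring under stretch+bend only: the elastic energy is
        # non-increasing at every forward-Euler step
        rng = np.random.default_rng(2)
        n, R, ks, kappa = 40, 5.0, 10.0, 1.0
        l0 = 2 * R * np.sin(np.pi / n)
        th0 = 2 * np.pi / n
        pos = regular_polygon(n, R) + rng.normal(scale=0.25, size=(n, 2))

        def energy(q):
            return (stretch_energy(q, ks, l0, closed=True)
                    + bend_energy(q, kappa, l0, th0, closed=True))

        e = energy(pos)
        for _ in range(2000):
            f = (stretch_forces(pos, ks, l0, closed=True)
                 + bend_forces(pos, kappa, l0, th0, closed=True))
            pos = step_positions(pos, f, gamma=1.0, dt=0.005)
            e_new = energy(pos)
            assert e_new <= e + 1e-12 * max(abs(e), 1.0)
            e = e_new
        # and it relaxes essentially back to the circle
        r = np.hypot(*(pos - pos.mean(axis=0)).T)
        assert np.std(r) < 0.1
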