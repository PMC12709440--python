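"""Confinement geometries, signed distances, entry scoring, and the
chemotactic bias."""

import numpy as np
import pytest

from mtcrosstalk import Params, make_initial_state
from mtcrosstalk.environment import (ENTRY_DEPTH, Environment,
                                     build_multichannel, build_obstacle_park,
                                     build_y_junction, channel_entry_check,
                                     chemotactic_bias, signed_distance)


class TestObstaclePark:
    def test_printed_geometry_counts_and_gaps(self):
        # radius 4, pitch 20, extent 100 -> 6 x 6 pillars, 12 um gaps
        env = build_obstacle_park(Robs=4.0, spacing=20.0, extent=100.0)
        assert len(env.obstacles) == 36
        centers = np.array([o[:2] for o in env.obstacles])
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(20.0)
        assert d.min() - 2 * 4.0 == pytest.approx(12.0)

    def test_larger_pillars_reduce_gap(self):
        env = build_obstacle_park(Robs=5.0, spacing=20.0, extent=100.0)
        centers = np.array([o[:2] for o in env.obstacles])
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        assert d.min() - 2 * 5.0 == pytest.approx(10.0)

    def test_signed_distance_at_center_is_minus_radius(self):
        env = build_obstacle_park(Robs=4.0, spacing=20.0, extent=40.0)
        cx, cy, _ = env.obstacles[0]
        assert signed_distance(env, (cx, cy)) == pytest.approx(-4.0)

    def test_origin_is_a_lattice_cell_center(self):
        env = build_obstacle_park(Robs=4.0, spacing=20.0, extent=100.0)
        assert signed_distance(env, (0.0, 0.0)) == pytest.approx(
            np.hypot(10.0, 10.0) - 4.0)

    def test_rejects_overlapping_pillars(self):
        with pytest.raises(ValueError):
            build_obstacle_park(Robs=10.0, spacing=20.0, extent=100.0)

    def test_builders_are_pure(self):
        a = build_obstacle_park(4.0, 20.0, 100.0)
        b = build_obstacle_park(4.0, 20.0, 100.0)
        assert a.obstacles == b.obstacles
        c = build_y_junction()
        d = build_y_junction()
        assert c.walls == d.walls

    def test_hex_lattice_option(self):
        env = build_obstacle_park(4.0, 20.0, 60.0, lattice="hex")
        assert len(env.obstacles) > 0


class TestYJunction:
    def test_equal_widths_mirror_symmetric(self):
        env = build_y_junction(w_left=10.0, w_right=10.0)
        walls = np.array(env.walls)
        # reflect about the stem axis (y -> -y) and compare as sets of
        # segments (endpoints may swap)
        def canon(w):
            a, b = tuple(np.round(w[:2], 9)), tuple(np.round(w[2:4], 9))
            return (min(a, b), max(a, b), round(w[4], 9))
        mirrored = walls.copy()
        mirrored[:, [1, 3]] *= -1
        assert {canon(w) for w in walls} == {canon(w) for w in mirrored}

    def test_stem_surface_at_half_width(self):
        env = build_y_junction(stem_w=10.0)
        # a point on the stem axis sits half a channel width from the walls
        assert signed_distance(env, (-15.0, 0.0)) == pytest.approx(5.0)

    def test_asymmetric_device_has_both_widths(self):
        env = build_y_junction(w_left=10.0, w_right=6.0)
        widths = {c.id: c.width for c in env.channels}
        assert widths == {"left": 10.0, "right": 6.0}

    def test_arm_interior_clearance_matches_width(self):
        env = build_y_junction(w_left=10.0, w_right=10.0, arm_angle=45.0)
        ch = env.channels[0]
        # probe the mid-line of the left arm well past the junction
        probe = ch.mouth + 15.0 * ch.axis + 5.0 * np.array(
            [-ch.axis[1], ch.axis[0]])
        assert signed_distance(env, probe) == pytest.approx(5.0, abs=0.3)


class TestMultichannel:
    def test_four_channel_device(self):
        env = build_multichannel((2.0, 4.0, 6.0, 8.0))
        assert [c.width for c in env.channels] == [2.0, 4.0, 6.0, 8.0]
        # equal center-to-center spacing
        ys = [c.mouth[1] for c in env.channels]
        gaps = np.diff(ys)
        assert np.allclose(gaps, gaps[0])

    def test_single_width_degenerates_to_straight_channel(self):
        env = build_multichannel((10.0,))
        assert len(env.channels) == 1
        c = env.channels[0]
        assert signed_distance(env, c.mouth + np.array([20.0, 0.0])) == \
            pytest.approx(5.0)

    def test_all_mouths_reachable_from_feeder(self):
        env = build_multichannel((2.0, 4.0, 6.0, 8.0))
        # each channel mouth center is open: clearance at least w/2
        for c in env.channels:
            d = signed_distance(env, c.mouth + 0.1 * c.axis)
            assert d >= c.width / 2 - 0.6

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            build_multichannel((4.0, 0.0))


class TestEntryCheck:
    def _cell_at(self, params, center):
        # entry scoring only reads the membrane ring; a bare polygon state
        # avoids needing a full (validated) simulation state for a small cell
        from types import SimpleNamespace
        from mtcrosstalk.state import regular_polygon
        pos = regular_polygon(60, params.Rcell, center)
        return SimpleNamespace(membrane=SimpleNamespace(pos=pos))

    def test_whole_cell_past_mouth_scores_entry(self):
        p = Params(Rcell=2.0)  # small test polygon fits in the channel
        env = build_multichannel((6.0, 6.0))
        ch = env.channels[0]
        st = self._cell_at(p, ch.mouth + (ENTRY_DEPTH + 2.1) * ch.axis)
        assert channel_entry_check(st, env) == ch.id

    def test_one_trailing_bead_blocks_entry(self):
        p = Params(Rcell=2.0)
        env = build_multichannel((6.0, 6.0))
        ch = env.channels[0]
        st = self._cell_at(p, ch.mouth + (ENTRY_DEPTH + 2.1) * ch.axis)
        trailing = int(np.argmin(st.membrane.pos @ ch.axis))
        st.membrane.pos[trailing] = ch.mouth + 4.9 * ch.axis
        assert channel_entry_check(st, env) is None

    def test_cell_in_feeder_scores_none(self):
        p = Params(Rcell=2.0)
        env = build_multichannel((6.0, 6.0))
        st = self._cell_at(p, (-10.0, 0.0))
        assert channel_entry_check(st, env) is None


class TestChemotaxis:
    def test_zero_bias_gives_zero_velocity(self):
        p = Params(v_chemo=0.0)
        st = make_initial_state(p)
        v = chemotactic_bias(st, Environment.empty(), p)
        assert np.allclose(v, 0.0)

    def test_isolated_cell_translates_at_exactly_v_chemo(self):
        # uniform bias on a relaxed free membrane: rigid translation at
        # exactly v_chemo (nucleus decoupled; with the nucleus attached the
        # coupled system moves slower by the drag ratio)
        from mtcrosstalk.engine import Simulation
        p = Params(Nmt=0, v_chemo=0.02, t_total=50.0, record_every=10.0,
                   k_couple=1e-9, eps_wca=1e-9,
                   dynein={"rho_cortex": 0.0, "rho_nuc": 0.0})
        sim = Simulation(p)
        track = sim.run()
        x = track["x"].to_numpy()
        v = np.diff(x) / np.diff(track["t"].to_numpy())
        assert np.allclose(v, 0.02, atol=1e-9)
        assert np.allclose(track["y"], track["y"].iloc[0], atol=1e-9)
        # area unchanged by the divergence-free uniform translation
        assert track["area"].iloc[-1] == pytest.approx(track["area"].iloc[0],
                                                       rel=1e-9)

    def test_no_bead_ends_inside_an_obstacle(self):
        # containment invariant during a confined run
        from mtcrosstalk.engine import Simulation
        p = Params(Nmt=30, t_total=120.0, record_every=10.0, seed=2)
        env = build_obstacle_park(Robs=4.0, spacing=20.0, extent=80.0)
        sim = Simulation(p, env)
        spc = sim.steps_per_chunk
        for _ in range(int(p.t_total / p.record_every)):
            sim.advance(spc)
            st = sim.state
            for beads in (st.membrane.pos, st.nucleus.pos):
                for b in beads:
                    assert signed_distance(env, b) > -0.45
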