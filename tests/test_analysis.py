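"""Trajectory estimators against fixtures with known statistics."""

import numpy as np
import pandas as pd
import pytest

from mtcrosstalk import analysis as an
from mtcrosstalk import fixtures as fx
from mtcrosstalk.state import regular_polygon


class TestMSD:
    def test_stationary_track_is_zero(self):
        track = pd.DataFrame({"t": np.arange(50) * 5.0,
                              "x": np.ones(50), "y": np.zeros(50)})
        assert np.allclose(an.msd(track)["msd"], 0.0)

    def test_ballistic_closed_form(self):
        v, dt = 0.05, 5.0
        track = fx.ballistic_track(n=200, speed=v, dt=dt)
        table = an.msd(track)
        assert np.allclose(table["msd"], (v * table["tau"]) ** 2, rtol=1e-9)
        alpha, _ = an.fit_msd_exponent(table)
        assert alpha == pytest.approx(2.0, abs=1e-9)

    def test_brownian_slope_near_one(self):
        track = fx.brownian_track(n=4000, step=0.25, seed=5)
        table = an.msd(track, np.arange(1, 40))
        alpha, logA = an.fit_msd_exponent(table)
        assert alpha == pytest.approx(1.0, abs=0.12)
        # amplitude: MSD(1 frame) = 2 step^2
        assert np.exp(logA + alpha * np.log(5.0)) == pytest.approx(
            2 * 0.25 ** 2, rel=0.2)


class TestLocalAlpha:
    def test_ballistic_window_classified_directed(self):
        track = fx.ballistic_track(n=400, speed=0.05, dt=5.0)
        segs = an.local_alpha(track, window=300.0)
        assert len(segs) == 6
        for s in segs:
            assert s.alpha == pytest.approx(2.0, abs=0.01)
            assert s.dphi == pytest.approx(0.0, abs=1e-6)
            assert s.directed

    def test_brownian_windows_classified_random(self):
        track = fx.brownian_track(n=2000, step=0.3, dt=5.0, seed=2)
        segs = an.local_alpha(track, window=300.0)
        alphas = np.array([s.alpha for s in segs])
        assert np.nanmedian(alphas) < 1.5
        assert np.mean([s.directed for s in segs]) < 0.2

    def test_threshold_rule_requires_both_criteria(self):
        # a window with high alpha but dispersed headings is random:
        # outward-then-back spiky motion has alpha ~ 2 per lag pair but
        # large circular spread
        segs = [an.SegmentClassification(0.0, a, 0.0, d,
                                         a > an.ALPHA_DIRECTED
                                         and d < an.DPHI_DIRECTED)
                for a, d in ((1.8, 1.0), (1.8, 0.5), (1.5, 0.1))]
        assert [s.directed for s in segs] == [False, True, False]

    def test_zero_displacement_window_flagged_random(self):
        track = pd.DataFrame({"t": np.arange(120) * 5.0,
                              "x": np.zeros(120), "y": np.zeros(120)})
        segs = an.local_alpha(track, window=300.0)
        assert all(s.flagged and not s.directed for s in segs)

    def test_piecewise_labels_recovered(self):
        track, labels = fx.piecewise_track(n_segments=8, seg_frames=60,
                                           dt=5.0, seed=1)
        segs = an.local_alpha(track.iloc[1:], window=300.0)
        got = [s.directed for s in segs[:len(labels)]]
        acc = np.mean([g == l for g, l in zip(got, labels)])
        assert acc >= 0.95

    def test_whole_track_window_agrees_with_global_msd(self):
        track = fx.wlc_track(n=360, step=0.3, lp=80.0, dt=5.0, seed=3)
        n = len(track)
        window = n * 5.0
        segs = an.local_alpha(track, window=window - 2.5)
        table = an.msd(track, np.arange(1, int(n / 3)))
        alpha_global, _ = an.fit_msd_exponent(table)
        assert segs[0].alpha == pytest.approx(alpha_global, abs=0.05)


class TestPersistenceLength:
    def test_straight_path_reports_contour_lower_bound(self):
        track = fx.ballistic_track(n=300, speed=0.05, dt=5.0)
        lp, bounded = an.persistence_length(track)
        assert bounded
        assert lp == pytest.approx(299 * 0.25, rel=1e-6)

    def test_wlc_parameter_recovery(self):
        # ensemble of three independent fixtures: the single-track
        # estimator variance at 1e4 steps is ~13%
        lps = []
        for seed in (8, 9, 10):
            track = fx.wlc_track(n=10000, step=0.25, lp=30.0, seed=seed)
            lp, bounded = an.persistence_length(track)
            assert not bounded
            lps.append(lp)
        assert np.mean(lps) == pytest.approx(30.0, rel=0.15)

    def test_white_noise_headings_give_step_scale_lp(self):
        rng = np.random.default_rng(4)
        step = 0.3
        th = rng.uniform(0, 2 * np.pi, 3000)
        xy = np.cumsum(step * np.column_stack([np.cos(th), np.sin(th)]),
                       axis=0)
        track = pd.DataFrame({"t": np.arange(3000) * 5.0,
                              "x": xy[:, 0], "y": xy[:, 1]})
        lp, _ = an.persistence_length(track)
        # uncorrelated tangents decorrelate within about one step length
        assert lp < 2 * step


class TestPolarityAngle:
    def _track(self, axis_offset):
        n = 60
        t = np.arange(n) * 5.0
        x = 0.05 * t
        y = np.zeros(n)
        cen = np.column_stack([x, y]) + axis_offset
        return pd.DataFrame({"t": t, "x": x, "y": y,
                             "cen_x": cen[:, 0], "cen_y": cen[:, 1],
                             "nuc_x": x, "nuc_y": y})

    def test_centrosome_ahead_gives_zero(self):
        th = an.polarity_angle(self._track(np.array([1.0, 0.0])))
        assert np.allclose(th, 0.0, atol=1e-9)

    def test_centrosome_sideways_gives_ninety(self):
        th = an.polarity_angle(self._track(np.array([0.0, 1.0])))
        assert np.allclose(th, 90.0, atol=1e-9)

    def test_centrosome_behind_gives_one_eighty(self):
        th = an.polarity_angle(self._track(np.array([-1.0, 0.0])))
        assert np.allclose(th, 180.0, atol=1e-9)

    def test_slow_frames_excluded(self):
        track = self._track(np.array([1.0, 0.0]))
        track["x"] = 0.0  # stationary: all frames below the speed floor
        assert len(an.polarity_angle(track)) == 0


class TestMorphology:
    def test_regular_polygon_metrics(self):
        n, R = 100, 7.0
        mem = regular_polygon(n, R)
        nuc = regular_polygon(50, 3.0)
        m = an.morphology(mem, nuc, np.array([4.0, 0.0]), Rcell=R)
        assert m["aspect_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert m["area_ratio"] == pytest.approx(
            n / (2 * np.pi) * np.sin(2 * np.pi / n), rel=1e-12)
        assert m["d_nuc_center"] == pytest.approx(0.0, abs=1e-9)
        assert m["d_cen_center"] == pytest.approx(4.0, abs=1e-9)

    def test_two_to_one_ellipse_aspect_ratio(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        mem = np.column_stack([6.0 * np.cos(th), 3.0 * np.sin(th)])
        m = an.morphology(mem, regular_polygon(30, 1.0), np.zeros(2), 7.0)
        assert m["aspect_ratio"] == pytest.approx(2.0, rel=0.02)


class TestChannelChoice:
    def test_fractions_and_times(self):
        entries = [("w8", 100.0)] * 9 + [("w6", 200.0)] * 1 + [(None, 0.0)] * 2
        table = an.channel_choice_stats(entries)
        by = table.set_index("channel")
        assert by.loc["w8", "fraction"] == pytest.approx(9 / 12)
        assert by.loc["w6", "fraction"] == pytest.approx(1 / 12)
        assert by.loc["censored", "fraction"] == pytest.approx(2 / 12)
        assert table["fraction"].sum() == pytest.approx(1.0)
        assert by.loc["w8", "mean_entry_time"] == pytest.approx(100.0)

    def test_all_runs_one_channel(self):
        table = an.channel_choice_stats([("left", 50.0)] * 5)
        by = table.set_index("channel")
        assert by.loc["left", "fraction"] == 1.0
        assert by.loc["censored", "n"] == 0
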