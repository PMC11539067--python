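"""Feature tests: tortuosity, velocities, bending angle, occupancy,
escape time series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finwave.features import (
    centre_occupancy,
    escape_timeseries,
    max_bending_angle,
    occupancy_map,
    tortuosity,
    velocity_series,
)
from finwave.synthetic import ArenaSpec, Trajectory, simulate_escape_sequence
from finwave.wave_model import Midline, MidlineSequence


def _straight_midline(n=51, length=30.0):
    return Midline(np.column_stack([np.linspace(0, length, n), np.zeros(n)]))


def _arc_midline(total_angle, n=51, length=30.0):
    R = length / total_angle
    ang = np.linspace(0, total_angle, n)
    return Midline(np.column_stack([R * np.sin(ang), R * (1 - np.cos(ang))]))


class TestTortuosity:
    def test_straight_midline_is_zero(self):
        assert tortuosity(_straight_midline()) == 0.0

    def test_head_touching_tail_is_one(self):
        m = _arc_midline(2 * np.pi - 1e-12)
        assert tortuosity(m) == pytest.approx(1.0, abs=1e-9)

    def test_semicircle_closed_form(self):
        assert tortuosity(_arc_midline(np.pi, n=501)) == pytest.approx(
            (np.pi - 2) / np.pi, abs=1e-4)

    @given(angle=st.floats(0.3, 5.5), scale=st.floats(0.1, 50.0),
           rot=st.floats(0, 2 * np.pi), dx=st.floats(-100, 100),
           dy=st.floats(-100, 100))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_similarity_transforms(self, angle, scale, rot,
                                                   dx, dy):
        m = _arc_midline(angle)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        moved = Midline(scale * (m.points @ R.T) + np.array([dx, dy]))
        assert tortuosity(moved) == pytest.approx(tortuosity(m), abs=1e-9)


class TestVelocitySeries:
    def test_stationary_trajectory_zero(self):
        t = np.arange(10) / 10.0
        traj = Trajectory(times_s=t, x_mm=np.full(10, 3.0),
                          y_mm=np.full(10, 4.0), fps=10.0)
        v = velocity_series(traj)
        assert np.allclose(v["speed"], 0.0)
        assert np.allclose(v["thrust_velocity"], 0.0)

    def test_uniform_motion_exact(self):
        fps, vtrue = 50.0, 12.0
        t = np.arange(100) / fps
        traj = Trajectory(times_s=t, x_mm=vtrue * t, y_mm=np.zeros_like(t),
                          fps=fps)
        v = velocity_series(traj)
        assert np.median(v["speed"]) == pytest.approx(vtrue, abs=1e-9)
        assert np.median(v["thrust_velocity"]) == pytest.approx(vtrue, abs=1e-9)

    def test_circular_motion_speed(self):
        R, omega, fps = 10.0, 2.0, 100.0  # fps >= 50*omega/(2 pi)
        t = np.arange(500) / fps
        traj = Trajectory(times_s=t, x_mm=R * np.cos(omega * t),
                          y_mm=R * np.sin(omega * t), fps=fps)
        v = velocity_series(traj)
        interior = v["speed"].to_numpy()[5:-5]
        assert np.median(interior) == pytest.approx(R * omega, rel=0.02)


class TestBendingAngle:
    def test_straight_is_zero(self):
        assert max_bending_angle(_straight_midline()) == pytest.approx(0.0,
                                                                       abs=1e-9)

    def test_arc_matches_chord_geometry(self):
        # uniform arc of total turning Theta: the chord over [a, b] of
        # body fraction subtends heading (a+b)/2 * Theta, so the two
        # window chords meet at 2/3 Theta for thirds
        theta_total = 0.9
        m = _arc_midline(theta_total, n=301)
        expected = theta_total * 2 / 3
        assert max_bending_angle(m) == pytest.approx(expected, rel=1e-3)

    def test_compensated_preset_bends_more_than_stiff(self):
        from finwave.features import bending_angle_series
        from finwave.propulsion import PRESETS
        from finwave.wave_model import generate_bending_field, midlines_from_bending

        med = {}
        for name in ("stiff", "compensated"):
            p = PRESETS[name]
            seq = midlines_from_bending(
                generate_bending_field(p, duration_s=2.0, fps=100.0), p)
            med[name] = bending_angle_series(seq).attrs["median"]
        assert med["compensated"] > med["stiff"]


class TestOccupancy:
    spec = ArenaSpec()

    def _traj(self, x, y, fps=50.0):
        t = np.arange(len(x)) / fps
        return Trajectory(times_s=t, x_mm=np.asarray(x, float),
                          y_mm=np.asarray(y, float), fps=fps)

    def test_percentages_sum_to_100(self, rng):
        x = rng.uniform(0, self.spec.width_mm, 1000)
        y = rng.uniform(0, self.spec.height_mm, 1000)
        om = occupancy_map(self._traj(x, y), self.spec)
        assert om.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_sum_invariant_to_binning(self, rng):
        x = rng.uniform(0, self.spec.width_mm, 500)
        y = rng.uniform(0, self.spec.height_mm, 500)
        for n_bins in (5, 13, 40):
            om = occupancy_map(self._traj(x, y), self.spec, n_bins=n_bins)
            assert om.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_stationary_point_mass(self):
        om = occupancy_map(self._traj([50.0] * 10, [20.0] * 10), self.spec)
        assert om.percent.max() == pytest.approx(100.0, abs=1e-9)

    def test_uniform_positions_multinomial_spread(self, rng):
        # max-bin deviation across seeds consistent with a multinomial
        # oracle simulated at the same n
        n, n_bins, seeds = 10_000, 10, 100
        n_cells = n_bins * n_bins
        dev = []
        for _ in range(seeds):
            x = rng.uniform(0, self.spec.width_mm, n)
            y = rng.uniform(0, self.spec.height_mm, n)
            om = occupancy_map(self._traj(x, y), self.spec, n_bins=n_bins)
            dev.append(np.abs(om.percent - 100.0 / n_cells).max())
        counts = rng.multinomial(n, np.full(n_cells, 1.0 / n_cells),
                                 size=seeds)
        oracle = np.abs(counts / n * 100 - 100.0 / n_cells).max(axis=1)
        assert np.mean(dev) == pytest.approx(np.mean(oracle), rel=0.15)

    def test_outside_positions_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            om = occupancy_map(self._traj([-5.0, 10.0, 300.0], [10.0, 20.0, 30.0]),
                               self.spec)
        assert om.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_trajectory_raises(self):
        with pytest.raises(ValueError):
            occupancy_map(self._traj([], []), self.spec)

    def test_centre_occupancy_limits(self):
        centre_y = self.spec.height_mm / 2
        inside = self._traj([10.0] * 5, [centre_y] * 5)
        outside = self._traj([10.0] * 5, [0.5] * 5)
        assert centre_occupancy(inside, self.spec) == 1.0
        assert centre_occupancy(outside, self.spec) == 0.0


class TestEscapeTimeseries:
    def test_single_individual_band_collapses(self):
        seq, truth = simulate_escape_sequence(duration_s=1.0, fps=200.0,
                                              stim_time_s=0.3)
        out = escape_timeseries([seq], stim_times_s=[0.3])
        assert np.allclose(out["tortuosity_lo"], out["median_tortuosity"])
        assert np.allclose(out["tortuosity_hi"], out["median_tortuosity"])

    def test_cbend_peak_occurs_after_stimulus(self):
        seqs, stims = [], []
        for k in range(5):
            seq, _ = simulate_escape_sequence(duration_s=1.0, fps=200.0,
                                              stim_time_s=0.3,
                                              bend_latency_s=0.01 + 0.002 * k)
            seqs.append(seq)
            stims.append(0.3)
        out = escape_timeseries(seqs, stim_times_s=stims)
        t_peak = out.loc[out["median_tortuosity"].idxmax(), "time_s"]
        assert t_peak > 0.0

    def test_straight_controls_stay_near_zero(self):
        seqs = [simulate_escape_sequence(duration_s=0.5, fps=200.0,
                                         stim_time_s=0.2, responds=False)[0]
                for _ in range(4)]
        out = escape_timeseries(seqs, stim_times_s=[0.2] * 4)
        assert np.all(out["median_tortuosity"] < 1e-9)
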