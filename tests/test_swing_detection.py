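"""Filtering chain, rotation-plane geometry and swing extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaswing import synthetic as syn
from aquaswing._geometry import rotation_matrix
from aquaswing.swing_detection import (
    FilterParams,
    butterworth_gain,
    detect_swings,
    duration_distribution,
    filter_series,
    rotation_normal,
    swing_boundary_signal,
    SwingEvent,
)
from aquaswing.trajectory_io import VectorSeries


def _series(v, dt=4.0, vf=None):
    s = VectorSeries(0, "DP", np.arange(len(v)) * dt, np.asarray(v, float))
    if vf is not None:
        s.v_F = np.asarray(vf, float)
    return s


def _two_rotation_series(n1=300, n2=300, mag1=60.0, mag2=80.0, dt=4.0):
    """Constant-speed rotation in the xy-plane, then an abrupt switch to
    a plane containing the z-axis."""
    v = np.empty((n1 + n2, 3))
    w1 = np.radians(mag1) / (n1 - 1)
    for k in range(n1):
        v[k] = rotation_matrix((0, 0, 1), w1 * k) @ np.array([1.0, 0, 0])
    v0 = v[n1 - 1]
    axis2 = np.cross(v0, (0, 0, 1.0))
    axis2 /= np.linalg.norm(axis2)
    w2 = np.radians(mag2) / n2
    for k in range(n2):
        v[n1 + k] = rotation_matrix(axis2, w2 * (k + 1)) @ v0
    return _series(v, dt)


class TestFiltering:
    def test_constant_vector_unchanged(self):
        v = np.tile([0.6, 0.0, 0.8], (200, 1))
        out = filter_series(_series(v))
        assert np.allclose(out.v_F, v, atol=1e-9)

    def test_cutoff_gain_is_one_over_sqrt2(self):
        # the Butterworth stage alone must pass exactly 1/sqrt(2) of a
        # 10 THz component at 4 fs sampling
        assert butterworth_gain(10.0, cutoff_thz=10.0, dt_fs=4.0) == pytest.approx(
            1.0 / np.sqrt(2.0), abs=1e-12
        )

    def test_sinusoid_attenuated_at_least_analytically(self):
        # 40 THz sinusoid in one component; the chain (double-pass
        # Butterworth + mean filter) must attenuate at least as much as
        # the single-pass analytic Butterworth response
        dt, f = 4.0, 40.0 / 1000.0  # cycles per fs
        t = np.arange(2000) * dt
        amp = 0.2
        x = amp * np.sin(2 * np.pi * f * t)
        v = np.stack([x, np.zeros_like(x), np.ones_like(x)], axis=1)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        out = filter_series(_series(v, dt))
        mid = slice(200, -200)
        gain = np.abs(out.v_F[mid, 0]).max() / amp
        assert gain <= butterworth_gain(40.0, dt_fs=dt) + 1e-6

    def test_nyquist_cutoff_is_identity(self):
        # identity limit on a band-limited (smooth) series
        series = _two_rotation_series()
        out = filter_series(series, FilterParams(cutoff_thz=124.9, mean_span=1))
        assert np.abs(out.v_F - series.v).max() < 1e-4
        exact = filter_series(series, FilterParams(cutoff_thz=125.0, mean_span=1))
        assert np.abs(exact.v_F - series.v).max() < 1e-12

    def test_too_short_series_raises(self):
        v = np.tile([0, 0, 1.0], (50, 1))
        with pytest.raises(ValueError, match="too short"):
            filter_series(_series(v))

    def test_output_renormalized(self, rng):
        v = rng.normal(size=(400, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        out = filter_series(_series(v))
        assert np.allclose(np.linalg.norm(out.v_F, axis=1), 1.0, atol=1e-12)


class TestRotationNormal:
    def test_uniform_rotation_closed_form(self):
        # v(t) = (cos wt, sin wt, 0) -> n = (0, 0, w)
        dt, w = 4.0, np.radians(1.0) / 4.0  # 1 deg per frame, rad/fs
        t = np.arange(200) * dt
        v = np.stack([np.cos(w * t), np.sin(w * t), np.zeros_like(t)], axis=1)
        n = rotation_normal(_series(v, dt, vf=v))
        interior = n[1:-1]
        assert np.abs(interior[:, 2] - w).max() / w < 1e-3
        assert np.abs(interior[:, :2]).max() < 1e-6

    def test_constant_vector_zero_normal(self):
        v = np.tile([0, 1.0, 0], (50, 1))
        n = rotation_normal(_series(v, vf=v))
        assert np.allclose(n, 0.0)

    def test_requires_filtered_vectors(self):
        v = np.tile([0, 1.0, 0], (50, 1))
        with pytest.raises(ValueError, match="filter"):
            rotation_normal(_series(v))


class TestBoundarySignal:
    def test_constant_direction_gives_zero(self):
        n = np.tile([0, 0, 0.01], (50, 1))
        assert np.allclose(swing_boundary_signal(n), 0.0)

    def test_right_angle_step_gives_one(self):
        n = np.concatenate([np.tile([0.01, 0, 0], (10, 1)),
                            np.tile([0, 0.01, 0], (10, 1))])
        q = swing_boundary_signal(n)
        assert q[9] == pytest.approx(1.0)
        assert np.allclose(np.delete(q, 9), 0.0)

    def test_reversal_gives_two(self):
        n = np.concatenate([np.tile([0, 0, 0.01], (5, 1)),
                            np.tile([0, 0, -0.01], (5, 1))])
        assert swing_boundary_signal(n).max() == pytest.approx(2.0)

    def test_degenerate_frames_carry_direction(self):
        # a stationary stretch inside one plane must not create spikes
        n = np.tile([0, 0, 0.01], (30, 1))
        n[10:20] = 0.0
        assert np.allclose(swing_boundary_signal(n), 0.0)

    def test_all_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            swing_boundary_signal(np.zeros((20, 3)))

    def test_range_bounds_on_noisy_input(self, rng):
        n = rng.normal(size=(500, 3)) * 0.01
        q = swing_boundary_signal(n)
        assert q.min() >= 0.0 and q.max() <= 2.0

    @given(seed=st.integers(0, 10_000), scale=st.floats(1e-6, 10.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_bounds_hold_for_any_normal_series(self, seed, scale):
        # q in [0, 2] for arbitrary rotation-normal series, including
        # ones with degenerate stretches
        rng = np.random.default_rng(seed)
        n = rng.normal(size=(100, 3)) * scale
        n[rng.random(100) < 0.3] = 0.0
        if not np.any(np.linalg.norm(n, axis=1) >= 1e-4):
            return
        q = swing_boundary_signal(n)
        assert q.shape == (99,)
        assert q.min() >= 0.0 and q.max() <= 2.0


class TestDetectSwings:
    def test_two_plane_rotation_two_events_one_boundary(self):
        series = _two_rotation_series()
        events = detect_swings(series, drop_edge_events=False)
        assert len(events) == 2
        mags = sorted(e.magnitude_deg for e in events)
        assert abs(mags[0] - 60.0) < 5.0 and abs(mags[1] - 80.0) < 5.0
        # exactly one interior boundary: both swings touch an edge
        assert all(e.edge for e in events)
        assert detect_swings(series) == []  # edge swings dropped by default

    def test_single_plane_rotation_is_one_swing(self):
        evs = (syn.PlantedSwing(0, 2000, 170, normal=(0, 0, 1)),)
        script = syn.SwingScript(events=evs, libration_amplitude_deg=0,
                                 jitter_deg=0, base_vector=(1, 0, 0))
        series, _ = syn.synthetic_vector_series(script, n_frames=501, seed=0)
        f = filter_series(series)
        q = swing_boundary_signal(rotation_normal(f))
        assert q[30:-30].max() <= 1e-10
        events = detect_swings(series, drop_edge_events=False)
        assert len(events) == 1
        assert events[0].magnitude_deg == pytest.approx(170, abs=2)

    def test_noise_only_series_has_no_large_events(self):
        # constant vector plus ~1 deg jitter: never a > 20 deg swing
        for seed in range(10):
            script = syn.SwingScript(events=(), libration_amplitude_deg=0,
                                     jitter_deg=1.0)
            series, _ = syn.synthetic_vector_series(script, n_frames=500, seed=seed)
            events = detect_swings(series, drop_edge_events=False)
            assert all(e.magnitude_deg <= 20 for e in events)

    def test_stationary_vector_yields_empty_list(self):
        v = np.tile([0, 0, 1.0], (200, 1))
        assert detect_swings(_series(v)) == []

    def test_rotation_equivariance(self):
        # rotating the lab frame must not change (t_start, dt, dtheta)
        rng = np.random.default_rng(5)
        script = syn.random_swing_script(rng)
        series, _ = syn.synthetic_vector_series(script, n_frames=700, seed=11)
        R = rotation_matrix(np.array([1.0, 2.0, 3.0]), 1.1)
        rotated = VectorSeries(0, "DP", series.t, series.v @ R.T)
        a = detect_swings(series)
        b = detect_swings(rotated)
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            assert ea.t_start == pytest.approx(eb.t_start, abs=1e-6)
            assert ea.duration == pytest.approx(eb.duration, abs=1e-6)
            assert ea.magnitude_deg == pytest.approx(eb.magnitude_deg, abs=1e-6)

    def test_events_time_ordered_and_nonoverlapping(self):
        rng = np.random.default_rng(6)
        script = syn.random_swing_script(rng)
        series, _ = syn.synthetic_vector_series(script, n_frames=700, seed=12)
        events = detect_swings(series, drop_edge_events=False)
        assert len(events) > 0
        for e0, e1 in zip(events[:-1], events[1:]):
            assert e1.t_start >= e0.t_end - 1e-9
        for e in events:
            assert e.duration > 0
            assert 0 <= e.magnitude_deg <= 180


class TestParameterRecovery:
    def test_planted_swing_recovery_above_resolution(self):
        """Closed loop: swings longer than the ~100 fs smoothing window
        are recovered within 10 deg / 25 fs for >= 90% of plants."""
        tot = rec = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            script = syn.random_swing_script(rng, n_events=3)
            series, truths = syn.synthetic_vector_series(
                script, n_frames=800, seed=1000 + seed
            )
            targets = [truths[i] for i in range(len(truths))
                       if i % 2 == 1 and truths[i].duration >= 100.0]
            r, _ = syn.match_events(targets, detect_swings(series))
            rec += r
            tot += len(targets)
        assert tot >= 10
        assert rec / tot >= 0.9


class TestDurationDistribution:
    def test_point_mass(self):
        events = [SwingEvent(0, "DP", 100.0 * k, 48.0, 90.0) for k in range(20)]
        edges, dens = duration_distribution(events, 0.0, bins=10)
        assert dens.sum() > 0
        widths = np.diff(edges)
        assert np.isclose((dens * widths).sum(), 1.0)

    def test_bimodal_mixture_recovers_both_modes(self):
        events = [SwingEvent(0, "DP", 0, 30.0, 90.0)] * 50 + [
            SwingEvent(0, "DP", 0, 100.0, 90.0)
        ] * 50
        edges, dens = duration_distribution(events, 0.0, bins=np.arange(0, 130, 10))
        centers = 0.5 * (edges[:-1] + edges[1:])
        occupied = centers[dens > 0]
        assert any(abs(c - 35) <= 10 for c in occupied)
        assert any(abs(c - 105) <= 10 for c in occupied)
        assert np.sum(dens > 0) == 2

    def test_threshold_above_maximum_empty_with_warning(self):
        events = [SwingEvent(0, "DP", 0, 40.0, 50.0)]
        with pytest.warns(UserWarning, match="no events"):
            _, dens = duration_distribution(events, 90.0)
        assert dens.size == 0
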