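"""Concurrent swings, defect↔swing correlation, spatial clustering."""

import numpy as np
import pytest

from aquaswing import synthetic as syn
from aquaswing._geometry import minimum_image
from aquaswing.collective import (
    ConcurrentSwingSeries,
    concurrent_swing_count,
    correlate_defects_swings,
    jumping_neighbor_distances,
    kernel_pdf,
    ks_compare,
    random_control_distances,
)
from aquaswing.hbond_network import DefectSeries
from aquaswing.swing_detection import SwingEvent
from aquaswing.trajectory_io import WaterTrajectory


def _ev(t_mid, mag=90.0, molecule=0, kind="DP"):
    # zero-duration helper: midpoint == t_start
    return SwingEvent(molecule, kind, t_mid, 0.0, mag)


class TestConcurrentCount:
    def test_no_events_gives_zero_series(self):
        grid = np.arange(0, 4000, 4.0)
        s = concurrent_swing_count([], 200.0, 40.0, grid)
        assert np.all(s.count == 0)

    def test_single_event_counted_inside_window_only(self):
        grid = np.arange(0, 4000, 4.0)
        s = concurrent_swing_count([_ev(2000.0)], 200.0, 40.0, grid)
        inside = np.abs(s.t - 2000.0) <= 100.0
        assert np.all(s.count[inside] == 1)
        assert np.all(s.count[~inside] == 0)

    def test_edge_half_windows_excluded(self):
        grid = np.arange(0, 4000, 4.0)
        s = concurrent_swing_count([], 400.0, 0.0, grid)
        assert s.t[0] >= grid[0] + 200.0
        assert s.t[-1] <= grid[-1] - 200.0

    def test_double_counting_identity(self):
        # away from edges, the series total equals the brute-force total
        grid = np.arange(0, 40_000, 4.0)
        rng = np.random.default_rng(0)
        mids = rng.uniform(5000, 35_000, size=40)
        events = [_ev(m) for m in mids]
        w = 1000.0
        s = concurrent_swing_count(events, w, 40.0, grid)
        brute = sum(
            np.sum(np.abs(s.t - m) <= w / 2) for m in mids
        )
        assert s.count.sum() == brute

    def test_poisson_stream_mean_matches_rate(self):
        rng = np.random.default_rng(42)
        T, lam, w = 400_000.0, 0.005, 1000.0
        mids = np.sort(rng.uniform(0, T, size=rng.poisson(lam * T)))
        events = [_ev(m) for m in mids]
        grid = np.arange(0, T, 4.0)
        s = concurrent_swing_count(events, w, 40.0, grid)
        se = np.sqrt(lam * w) / np.sqrt(len(mids))  # crude standard error
        assert abs(s.count.mean() - lam * w) < 3 * np.sqrt(lam * w) * 0.1 + 3 * se

    def test_window_longer_than_span_rejected(self):
        with pytest.raises(ValueError, match="window"):
            concurrent_swing_count([], 5000.0, 0.0, np.arange(0, 400, 4.0))


class TestCorrelation:
    def _series_pair(self, y):
        t = np.arange(y.size) * 4.0
        frac = (y - y.min()) / (np.ptp(y) + 1e-12)
        ds = DefectSeries(t=t, fraction=frac)
        cs = ConcurrentSwingSeries(t=t, count=y, window_fs=1000, theta_min=40)
        return ds, cs

    def test_identical_series_r_one(self):
        t = np.arange(4000) * 4.0
        y = np.sin(2 * np.pi * t / 60_000.0)
        ds, cs = self._series_pair(y)
        res = correlate_defects_swings(ds, cs, seed=0, n_boot=50, n_null=50)
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.p < 0.05

    def test_negated_series_r_minus_one(self):
        t = np.arange(4000) * 4.0
        y = np.cos(2 * np.pi * t / 60_000.0)
        ds, _ = self._series_pair(y)
        cs = ConcurrentSwingSeries(t=t, count=-y, window_fs=1000, theta_min=40)
        res = correlate_defects_swings(ds, cs, seed=0, n_boot=50, n_null=50)
        assert res.r == pytest.approx(-1.0, abs=1e-9)

    def test_constant_series_rejected(self):
        t = np.arange(1000) * 4.0
        ds = DefectSeries(t=t, fraction=np.full(1000, 0.3))
        cs = ConcurrentSwingSeries(t=t, count=np.sin(t / 500), window_fs=1000,
                                   theta_min=40)
        with pytest.raises(ValueError, match="constant"):
            correlate_defects_swings(ds, cs, use_filtered=False)

    def test_independent_ar1_surrogates_uncorrelated(self):
        # two independent AR(1) processes: |r| small and p insignificant
        # in >= 90% of seeds (raw series; the bootstrap/null machinery
        # must not manufacture significance from autocorrelation alone)
        ok = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n, burn = 3500, 500  # burn-in for stationarity
            x = np.zeros(n)
            y = np.zeros(n)
            ex, ey = rng.normal(size=(2, n))
            for k in range(1, n):
                x[k] = 0.9 * x[k - 1] + ex[k]
                y[k] = 0.9 * y[k - 1] + ey[k]
            x, y = x[burn:], y[burn:]
            t = np.arange(n - burn) * 4.0
            ds = DefectSeries(t=t, fraction=(x - x.min()) / np.ptp(x))
            cs = ConcurrentSwingSeries(t=t, count=y, window_fs=1000, theta_min=40)
            res = correlate_defects_swings(
                ds, cs, use_filtered=False, seed=seed, n_boot=20, n_null=199,
                block_fs=400.0,
            )
            if abs(res.r) < 0.2 and res.p > 0.05:
                ok += 1
        assert ok >= 0.9 * n_seeds


def _lattice_traj(n=4, a=3.0, n_frames=151):
    """Simple-cubic oxygen lattice, canonical orientation, many frames."""
    g = np.arange(n) * a
    o = np.array([[x, y, z] for x in g for y in g for z in g])
    pos = np.zeros((len(o), 3, 3))
    pos[:, 0] = o
    pos[:, 1] = o + [0.96, 0, 0]
    pos[:, 2] = o + [-0.24, 0.93, 0]
    frames = np.repeat(pos[None], n_frames, axis=0)
    return WaterTrajectory(frames, np.array([n * a] * 3))


class TestNeighborDistances:
    def test_two_jumpers_minimum_image_distance(self):
        traj = _lattice_traj(n=3, a=3.1)
        # molecules 0 (corner) and 2 (same row,末) are 3.1 A apart through
        # the boundary: minimum image, not the in-box 6.2 A
        events = [_ev(100.0, molecule=0), _ev(104.0, molecule=2)]
        res = jumping_neighbor_distances(traj, events, window_fs=200.0,
                                         theta_min=60.0, ranks=(1,))
        assert sorted(res.samples[1]) == pytest.approx([3.1, 3.1])

    def test_ranks_match_brute_force_sorted_lists(self):
        traj = _lattice_traj(n=4, a=3.0)
        rng = np.random.default_rng(1)
        members = rng.choice(traj.n_molecules, size=20, replace=False)
        events = [_ev(100.0 + i, molecule=int(m)) for i, m in enumerate(members)]
        ranks = (1, 2, 3, 4)
        res = jumping_neighbor_distances(traj, events, window_fs=200.0,
                                         theta_min=60.0, ranks=ranks)
        # oracle: explicit sorted minimum-image distance lists
        o = traj.oxygen_positions(25)
        box = traj.box[25]
        expected = {k: [] for k in ranks}
        for m in members:
            d = sorted(
                np.linalg.norm(minimum_image(o[x] - o[m], box))
                for x in members if x != m
            )
            for k in ranks:
                expected[k].append(d[k - 1])
        for k in ranks:
            assert np.allclose(np.sort(res.samples[k]), np.sort(expected[k]))

    def test_rank_monotonicity(self):
        traj = _lattice_traj(n=4, a=3.0)
        rng = np.random.default_rng(2)
        members = rng.choice(traj.n_molecules, size=12, replace=False)
        events = [_ev(100.0, molecule=int(m)) for m in members]
        res = jumping_neighbor_distances(traj, events, window_fs=200.0,
                                         theta_min=60.0, ranks=(1, 2, 3))
        for k in (1, 2):
            assert np.all(np.sort(res.samples[k + 1]) >= np.sort(res.samples[k]) - 1e-12)

    def test_windows_with_too_few_jumpers_contribute_nothing(self):
        traj = _lattice_traj()
        events = [_ev(100.0, molecule=0), _ev(104.0, molecule=5)]
        res = jumping_neighbor_distances(traj, events, window_fs=200.0,
                                         theta_min=60.0, ranks=(1, 2, 3))
        assert res.samples[1].size == 2
        assert res.samples[2].size == 0  # rank 2 needs >= 3 jumpers

    def test_random_control_deterministic_per_seed(self):
        traj = _lattice_traj()
        counts = [8, 8, 6]
        a = random_control_distances(traj, counts, seed=123, window_fs=200.0)
        b = random_control_distances(traj, counts, seed=123, window_fs=200.0)
        for k in a.samples:
            assert np.array_equal(a.samples[k], b.samples[k])
        c = random_control_distances(traj, counts, seed=124, window_fs=200.0)
        assert any(
            not np.array_equal(a.samples[k], c.samples[k]) for k in a.samples
        )

    def test_all_molecules_jumping_equals_full_population(self):
        traj = _lattice_traj(n=3, a=3.0)
        events = [_ev(100.0 + 0.1 * m, molecule=m) for m in range(traj.n_molecules)]
        jump = jumping_neighbor_distances(traj, events, window_fs=200.0,
                                          theta_min=60.0, ranks=(1, 2))
        ctrl = random_control_distances(traj, [traj.n_molecules], seed=0,
                                        window_fs=200.0, ranks=(1, 2))
        for k in (1, 2):
            assert np.allclose(np.sort(jump.samples[k]), np.sort(ctrl.samples[k]))

    def test_shuffled_labels_indistinguishable_from_control(self):
        # when "jumping" labels are random the Fig-style contrast must
        # vanish: KS p > 0.05 in >= 90% of seeds
        traj = _lattice_traj(n=4, a=3.0, n_frames=1001)
        n_seeds, ok = 20, 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            events = []
            for w in range(20):
                for m in rng.choice(traj.n_molecules, size=10, replace=False):
                    events.append(_ev(w * 200.0 + 100.0, molecule=int(m)))
            jump = jumping_neighbor_distances(traj, events, window_fs=200.0,
                                              theta_min=60.0, ranks=(1,))
            ctrl = random_control_distances(traj, jump.counts_per_window,
                                            seed=seed, window_fs=200.0, ranks=(1,))
            _, p = ks_compare(jump.samples[1], ctrl.samples[1])
            if p > 0.05:
                ok += 1
        assert ok >= 0.9 * n_seeds


class TestKernelPdf:
    def test_repeated_value_gives_narrow_peak(self):
        g, p = kernel_pdf(np.full(50, 3.0), width=0.1)
        assert g[np.argmax(p)] == pytest.approx(3.0, abs=0.02)
        assert np.trapezoid(p, g) == pytest.approx(1.0, abs=1e-3)

    def test_matches_normal_density(self, rng):
        x = rng.normal(size=4000)
        g, p = kernel_pdf(x, width=0.1, grid=np.linspace(-4, 4, 400))
        ref = np.exp(-0.5 * g**2) / np.sqrt(2 * np.pi)
        assert np.abs(p - ref).max() < 0.05

    def test_normalization_and_errors(self, rng):
        g, p = kernel_pdf(rng.uniform(2, 5, 200), width=0.15)
        assert abs(np.trapezoid(p, g) - 1.0) <= 1e-3
        with pytest.raises(ValueError, match="width"):
            kernel_pdf(np.array([1.0, 2.0]), width=0.0)


class TestKS:
    def test_identical_samples_d_zero(self):
        x = np.arange(100.0)
        d, p = ks_compare(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self):
        d, _ = ks_compare(np.arange(50.0), np.arange(100.0, 150.0))
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_compare(np.array([]), np.array([1.0]))
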