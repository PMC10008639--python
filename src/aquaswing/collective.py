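"""Collectivity of angular swings: concurrent counts, defect↔swing
correlations, and spatial clustering of jumping molecules.

The central question is whether large swings happen independently
throughout the system or as a collective burst.  Three measurements
address it:

* the number of swings whose midpoint falls in a sliding time window
  (1 ps for wave visualisation, 200 fs for concurrency statistics);
* the Pearson correlation between the 0.1 THz-filtered defect-fraction
  and concurrent-swing series, with a moving-block bootstrap
  uncertainty (plain p-values are invalid under strong autocorrelation,
  so the null is built from circularly shifted series);
* the distance distribution from each jumping molecule to its k-th
  nearest *other* jumping molecule, compared against equally many
  randomly selected molecules via two-sample Kolmogorov–Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from ._geometry import minimum_image
from .hbond_network import DefectSeries
from .swing_detection import FilterParams, SwingEvent, filter_lowpass
from .trajectory_io import WaterTrajectory

__all__ = [
    "ConcurrentSwingSeries",
    "CorrelationResult",
    "NeighborDistanceSamples",
    "concurrent_swing_count",
    "correlate_defects_swings",
    "jumping_neighbor_distances",
    "random_control_distances",
    "kernel_pdf",
    "ks_compare",
]


@dataclass
class ConcurrentSwingSeries:
    """Number of swings per sliding time window.

    ``count[i]`` is the number of events (above ``theta_min``) whose
    midpoint lies in ``[t[i] − w/2, t[i] + w/2]``.  Half-windows at the
    trajectory edges are excluded from the grid.
    """

    t: np.ndarray
    count: np.ndarray
    window_fs: float
    theta_min: float
    kind: str = "DP"


@dataclass
class CorrelationResult:
    """Pearson correlation with block-bootstrap uncertainty."""

    r: float
    r_err: float
    p: float
    n: int


@dataclass
class NeighborDistanceSamples:
    """Pooled k-th-nearest-jumper distances over disjoint windows."""

    samples: dict[int, np.ndarray]
    counts_per_window: np.ndarray
    window_centers_fs: np.ndarray
    window_fs: float
    theta_min: float
    population: str = "jumping"


# ---------------------------------------------------------------------------
# concurrent swings
# ---------------------------------------------------------------------------

def _midpoints(
    events: Iterable[SwingEvent],
    theta_min: float,
    kind: Optional[str],
    timestamp: str = "midpoint",
) -> np.ndarray:
    ts = [
        e.t_mid if timestamp == "midpoint" else e.t_start
        for e in events
        if e.magnitude_deg > theta_min and (kind is None or e.kind == kind)
    ]
    return np.sort(np.asarray(ts, dtype=float))


def concurrent_swing_count(
    events: Iterable[SwingEvent],
    window_fs: float,
    theta_min: float,
    grid: np.ndarray,
    kind: Optional[str] = None,
    timestamp: str = "midpoint",
) -> ConcurrentSwingSeries:
    """Sliding-window concurrent-swing count, stride one frame.

    ``grid`` is the trajectory's frame-time grid (fs); the output grid
    excludes the half-windows at either end, where the count would be
    biased low.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and window_fs > grid[-1] - grid[0]:
        raise ValueError("window longer than the trajectory span")
    mids = _midpoints(events, theta_min, kind, timestamp)
    half = 0.5 * window_fs
    keep = (grid >= grid[0] + half) & (grid <= grid[-1] - half)
    t = grid[keep]
    lo = np.searchsorted(mids, t - half, side="left")
    hi = np.searchsorted(mids, t + half, side="right")
    return ConcurrentSwingSeries(
        t=t,
        count=(hi - lo).astype(float),
        window_fs=window_fs,
        theta_min=theta_min,
        kind=kind or "any",
    )


# ---------------------------------------------------------------------------
# defect <-> swing correlation
# ---------------------------------------------------------------------------

def correlate_defects_swings(
    defects: DefectSeries,
    swings: ConcurrentSwingSeries,
    block_fs: float = 10_000.0,
    n_boot: int = 200,
    n_null: int = 200,
    use_filtered: bool = True,
    params: FilterParams | None = None,
    seed: int | None = None,
) -> CorrelationResult:
    """Pearson r between defect fraction and concurrent-swing count.

    Both series are restricted to their common time grid and (by
    default) low-pass filtered at 0.1 THz before correlating, so that
    the comparison is between the slow collective waves rather than the
    frame-to-frame noise.  The uncertainty is the standard deviation of
    a moving-block bootstrap (block length ``block_fs``, default 10 ps);
    the p-value is computed against a null of random circular shifts,
    which preserves each series' autocorrelation.
    """
    params = params or FilterParams()
    rng = np.random.default_rng(seed)
    t_common, ia, ib = np.intersect1d(
        defects.t, swings.t, assume_unique=True, return_indices=True
    )
    if t_common.size < 10:
        raise ValueError("series share fewer than 10 time points")
    x = defects.fraction[ia]
    y = swings.count[ib]
    if use_filtered:
        dt = float(t_common[1] - t_common[0])
        x = filter_lowpass(x, params.post_cutoff_thz, dt, order=params.order)
        y = filter_lowpass(y, params.post_cutoff_thz, dt, order=params.order)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")

    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    dt = float(t_common[1] - t_common[0])
    block = max(2, min(n, int(round(block_fs / dt))))

    # moving-block bootstrap of the pair (x, y)
    n_blocks = int(np.ceil(n / block))
    starts_max = n - block
    r_boot = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            r_boot[b] = np.nan
        else:
            r_boot[b] = np.corrcoef(xb, yb)[0, 1]
    r_err = float(np.nanstd(r_boot))

    # circular-shift null (shifts at least one block away from zero lag)
    r_null = np.empty(n_null)
    for b in range(n_null):
        s = int(rng.integers(block, n - block)) if n > 2 * block else int(
            rng.integers(1, n)
        )
        r_null[b] = np.corrcoef(x, np.roll(y, s))[0, 1]
    p = float((1 + np.sum(np.abs(r_null) >= abs(r))) / (n_null + 1))
    return CorrelationResult(r=r, r_err=r_err, p=p, n=n)


# ---------------------------------------------------------------------------
# spatial clustering of jumping molecules
# ---------------------------------------------------------------------------

def _rank_distances(
    positions: np.ndarray, box: np.ndarray, members: np.ndarray,
    ranks: Sequence[int],
) -> dict[int, list[float]]:
    """k-th-nearest minimum-image O–O distances within ``members``."""
    out: dict[int, list[float]] = {k: [] for k in ranks}
    m = members.size
    if m < 2:
        return out
    pos = positions[members]
    diff = minimum_image(pos[:, None, :] - pos[None, :, :], box)
    d = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    for k in ranks:
        if k <= m - 1:
            out[k].extend(d[:, k - 1].tolist())
    return out


def jumping_neighbor_distances(
    traj: WaterTrajectory,
    events: Iterable[SwingEvent],
    window_fs: float = 200.0,
    theta_min: float = 60.0,
    ranks: Sequence[int] = (1, 2, 3, 4),
    kind: Optional[str] = None,
    timestamp: str = "midpoint",
) -> NeighborDistanceSamples:
    """Distances from each jumping molecule to its k-th nearest jumper.

    The trajectory is cut into disjoint windows of ``window_fs``; in each
    window the "jumping" molecules are those with at least one event
    (magnitude above ``theta_min``) whose timestamp falls inside.
    Distances are minimum-image O–O distances evaluated at the window's
    central frame and pooled over windows.  Windows with fewer than k+1
    jumpers contribute nothing at rank k.
    """
    span = traj.times[-1]
    n_windows = int(span // window_fs)
    if n_windows < 1:
        raise ValueError("window longer than the trajectory")
    events = list(events)
    pooled: dict[int, list[float]] = {k: [] for k in ranks}
    counts, centers = [], []
    for w in range(n_windows):
        t0, t1 = w * window_fs, (w + 1) * window_fs
        members = set()
        for e in events:
            if e.magnitude_deg <= theta_min:
                continue
            if kind is not None and e.kind != kind:
                continue
            ts = e.t_mid if timestamp == "midpoint" else e.t_start
            if t0 <= ts < t1:
                members.add(e.molecule)
        members = np.asarray(sorted(members), dtype=int)
        center_frame = int(round((t0 + t1) / 2 / traj.dt_frame))
        center_frame = min(center_frame, traj.n_frames - 1)
        res = _rank_distances(
            traj.oxygen_positions(center_frame), traj.box[center_frame],
            members, ranks,
        )
        for k in ranks:
            pooled[k].extend(res[k])
        counts.append(members.size)
        centers.append((t0 + t1) / 2)
    return NeighborDistanceSamples(
        samples={k: np.asarray(v) for k, v in pooled.items()},
        counts_per_window=np.asarray(counts, dtype=int),
        window_centers_fs=np.asarray(centers),
        window_fs=window_fs,
        theta_min=theta_min,
        population="jumping",
    )


def random_control_distances(
    traj: WaterTrajectory,
    counts_per_window: Sequence[int],
    ranks: Sequence[int] = (1, 2, 3, 4),
    seed: int | None = None,
    window_fs: float = 200.0,
) -> NeighborDistanceSamples:
    """Same rank statistics for uniformly drawn random molecules.

    Per window, as many molecules as there were jumpers are drawn
    uniformly without replacement; everything else matches
    :func:`jumping_neighbor_distances`, so any difference between the
    two distance distributions reflects genuine spatial clustering of
    the jumpers.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts_per_window, dtype=int)
    pooled: dict[int, list[float]] = {k: [] for k in ranks}
    centers = []
    for w, c in enumerate(counts):
        t0, t1 = w * window_fs, (w + 1) * window_fs
        c = min(int(c), traj.n_molecules)
        members = np.sort(rng.choice(traj.n_molecules, size=c, replace=False))
        center_frame = int(round((t0 + t1) / 2 / traj.dt_frame))
        center_frame = min(center_frame, traj.n_frames - 1)
        res = _rank_distances(
            traj.oxygen_positions(center_frame), traj.box[center_frame],
            members, ranks,
        )
        for k in ranks:
            pooled[k].extend(res[k])
        centers.append((t0 + t1) / 2)
    return NeighborDistanceSamples(
        samples={k: np.asarray(v) for k, v in pooled.items()},
        counts_per_window=counts,
        window_centers_fs=np.asarray(centers),
        window_fs=window_fs,
        theta_min=np.nan,
        population="random-control",
    )


# ---------------------------------------------------------------------------
# smoothing and testing
# ---------------------------------------------------------------------------

def kernel_pdf(
    samples: np.ndarray,
    width: float = 0.15,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width Gaussian kernel density, renormalized on the grid.

    ``width`` is the kernel standard deviation in the sample units
    (0.1–0.2 Å for O–O distance distributions).  Returns
    ``(grid, density)`` with ∫density = 1 on the grid to within 1e−3.
    """
    if width <= 0:
        raise ValueError("kernel width must be positive")
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1:
        raise ValueError("need at least one sample")
    if grid is None:
        lo = samples.min() - 4 * width
        hi = samples.max() + 4 * width
        grid = np.linspace(lo, hi, 512)
    z = (grid[:, None] - samples[None, :]) / width
    density = np.exp(-0.5 * z**2).sum(axis=1)
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise ValueError("grid does not cover the samples")
    return grid, density / area


def ks_compare(samples_a: np.ndarray, samples_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p-value)."""
    a, b = np.asarray(samples_a), np.asarray(samples_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
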