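"""Local context of angular swings: H-bond breaking and Voronoi density.

Two observables characterise the environment of a detected swing:

* *bond breaking* — compare the donated-partner and accepted-partner
  sets of the swinging molecule at the start and end boundary frames; a
  partner present before and absent after is a break on that side.
  Large swings break donated (outgoing) bonds far more often than
  accepted (ingoing) ones, because outgoing bonds pivot with the O–H
  bond of the swinging molecule itself.
* *Voronoi density* ρ_voro — the inverse of the summed periodic Voronoi
  cell volumes of the molecule's O, H1 and H2 atoms, evaluated at the
  swing midpoint frame.  Low-density regions host the large swings.

The periodic Voronoi tessellation is obtained by replicating atoms into
neighbouring images, tessellating with scipy and keeping the cells of
the central copies; the correctness contract is the conservation
invariant (cell volumes sum to the box volume), not the particular
replication scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, Voronoi

from .collective import kernel_pdf
from .hbond_network import HBondGraph, hydrogen_bonds
from .swing_detection import SwingEvent
from .trajectory_io import WaterTrajectory

__all__ = [
    "SwingEnvironment",
    "swing_bond_breaking",
    "bond_breaking_fractions",
    "voronoi_volumes",
    "voronoi_density",
    "swing_density_distribution",
]


@dataclass
class SwingEnvironment:
    """Per-swing local context."""

    event: SwingEvent
    broke_out: int
    broke_in: int
    formed_out: int
    formed_in: int
    rho_voro: Optional[float] = None


# ---------------------------------------------------------------------------
# bond breaking across swings
# ---------------------------------------------------------------------------

class _GraphCache:
    """Build each frame's H-bond graph at most once."""

    def __init__(self, traj: WaterTrajectory, **kwargs):
        self.traj = traj
        self.kwargs = kwargs
        self._cache: dict[int, HBondGraph] = {}

    def __call__(self, frame: int) -> HBondGraph:
        if frame not in self._cache:
            self._cache[frame] = hydrogen_bonds(
                self.traj.positions[frame], self.traj.box[frame],
                frame=frame, **self.kwargs,
            )
        return self._cache[frame]


def swing_bond_breaking(
    events: Iterable[SwingEvent],
    traj: WaterTrajectory,
    buffer_frames: int = 0,
    graph_kwargs: dict | None = None,
) -> list[SwingEnvironment]:
    """Count hydrogen bonds lost across each swing, per side.

    The donated/accepted partner sets are compared between the frames at
    ``t_start − buffer`` and ``t_start + Δt + buffer`` (buffer default 0:
    the exact boundary frames).  Partners present before and absent
    after count as breaks; newly appearing partners are recorded as
    formations but are not part of the headline fractions.  Events whose
    frames fall outside the trajectory are skipped with a warning.
    """
    cache = _GraphCache(traj, **(graph_kwargs or {}))
    dt = traj.dt_frame
    out: list[SwingEnvironment] = []
    for e in events:
        f0 = int(round(e.t_start / dt)) - buffer_frames
        f1 = int(round(e.t_end / dt)) + buffer_frames
        if f0 < 0 or f1 >= traj.n_frames:
            warnings.warn(
                f"event at t={e.t_start} fs touches the trajectory edge; "
                "skipped", stacklevel=2,
            )
            continue
        g0, g1 = cache(f0), cache(f1)
        out_before, out_after = g0.donated_partners(e.molecule), g1.donated_partners(e.molecule)
        in_before, in_after = g0.accepted_partners(e.molecule), g1.accepted_partners(e.molecule)
        out.append(
            SwingEnvironment(
                event=e,
                broke_out=len(out_before - out_after),
                broke_in=len(in_before - in_after),
                formed_out=len(out_after - out_before),
                formed_in=len(in_after - in_before),
            )
        )
    return out


def bond_breaking_fractions(
    environments: Sequence[SwingEnvironment],
    theta_thresholds: Sequence[float] = (0, 20, 40, 60, 80),
    kind: Optional[str] = None,
):
    """Fraction of swings with ≥1 broken bond, per side and ΔΘ threshold.

    Returns a DataFrame with, per threshold: the per-event probability
    that a swing of magnitude above the threshold broke at least one
    donated (``frac_out``) / accepted (``frac_in``) bond, plus the
    bond-weighted alternatives (mean number of breaks per event).
    """
    import pandas as pd

    rows = []
    for thr in theta_thresholds:
        sel = [
            env for env in environments
            if env.event.magnitude_deg > thr
            and (kind is None or env.event.kind == kind)
        ]
        n = len(sel)
        rows.append(
            {
                "theta_min": thr,
                "n_events": n,
                "frac_out": np.mean([env.broke_out > 0 for env in sel]) if n else np.nan,
                "frac_in": np.mean([env.broke_in > 0 for env in sel]) if n else np.nan,
                "mean_broke_out": np.mean([env.broke_out for env in sel]) if n else np.nan,
                "mean_broke_in": np.mean([env.broke_in for env in sel]) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# periodic Voronoi density
# ---------------------------------------------------------------------------

def voronoi_volumes(
    positions: np.ndarray,
    box: np.ndarray,
    buffer: float = 6.0,
) -> np.ndarray:
    """Periodic Voronoi cell volume of every atom of every water.

    ``positions`` has shape (n_molecules, 3, 3); all 3N atoms are
    Voronoi sites.  Sites are wrapped into the box and image copies
    within ``buffer`` Å of the boundary are added before tessellating;
    the returned array has shape (n_molecules, 3) and sums to the box
    volume (each atomic cell in dense water has a radius well below the
    default buffer).
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    n_mol = positions.shape[0]
    sites = np.mod(positions.reshape(-1, 3), box)
    n_sites = sites.shape[0]
    if n_sites < 4:
        raise ValueError("need at least 4 atoms for a 3-D tessellation")
    buffer = min(float(buffer), float(np.min(box)))

    all_sites = [sites]
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                if (sx, sy, sz) == (0, 0, 0):
                    continue
                shifted = sites + np.array([sx, sy, sz]) * box
                keep = np.all(
                    (shifted > -buffer) & (shifted < box + buffer), axis=1
                )
                if np.any(keep):
                    all_sites.append(shifted[keep])
    pts = np.concatenate(all_sites, axis=0)

    # coincident sites make the tessellation degenerate
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    close = tree.query_pairs(1e-6)
    if close:
        raise ValueError("coincident Voronoi sites: degenerate configuration")

    vor = Voronoi(pts)
    volumes = np.empty(n_sites)
    for i in range(n_sites):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise ValueError(
                f"unbounded Voronoi cell for atom {i}; increase the image buffer"
            )
        volumes[i] = ConvexHull(vor.vertices[region]).volume
    return volumes.reshape(n_mol, 3)


def voronoi_density(
    positions: np.ndarray,
    box: np.ndarray,
    molecule: int,
    volumes: np.ndarray | None = None,
) -> float:
    """ρ_voro = 1 / (V_O + V_H1 + V_H2) of one molecule, in Å⁻³.

    Pass precomputed ``volumes`` (from :func:`voronoi_volumes`) when
    evaluating many molecules of the same frame.
    """
    if volumes is None:
        volumes = voronoi_volumes(positions, box)
    v = float(volumes[molecule].sum())
    if v <= 0:
        raise ValueError(f"non-positive Voronoi volume for molecule {molecule}")
    return 1.0 / v


def swing_density_distribution(
    events: Iterable[SwingEvent],
    traj: WaterTrajectory,
    theta_thresholds: Sequence[float] = (0, 20, 40, 60),
    kernel_width: float = 1e-3,
    grid: np.ndarray | None = None,
    kind: Optional[str] = None,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Kernel-smoothed PDF of ρ_voro at swing midpoints, per ΔΘ threshold.

    The density is evaluated at the frame nearest each swing's midpoint
    ``t_start + Δt/2``.  ``kernel_width`` is in Å⁻³ (water's molecular
    ρ_voro is ~0.03 Å⁻³, so the default 0.001 resolves the
    distribution).  Thresholds with no qualifying events yield an empty
    PDF with a warning.
    """
    events = list(events)
    frame_volumes: dict[int, np.ndarray] = {}

    def volumes_at(frame: int) -> np.ndarray:
        if frame not in frame_volumes:
            frame_volumes[frame] = voronoi_volumes(
                traj.positions[frame], traj.box[frame]
            )
        return frame_volumes[frame]

    rho: dict[float, list[float]] = {thr: [] for thr in theta_thresholds}
    for e in events:
        if kind is not None and e.kind != kind:
            continue
        frame = int(round(e.t_mid / traj.dt_frame))
        if not 0 <= frame < traj.n_frames:
            continue
        vols = volumes_at(frame)
        r = 1.0 / float(vols[e.molecule].sum())
        for thr in theta_thresholds:
            if e.magnitude_deg > thr:
                rho[thr].append(r)

    out: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for thr in theta_thresholds:
        if not rho[thr]:
            warnings.warn(f"no events above {thr} deg", stacklevel=2)
            out[thr] = (np.array([]), np.array([]))
            continue
        out[thr] = kernel_pdf(np.asarray(rho[thr]), width=kernel_width, grid=grid)
    return out
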