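"""Hydrogen-bond graphs, coordination defects and defect-fraction series.

A pair of waters is hydrogen bonded by the geometric (Luzar–Chandler)
criterion: donor–acceptor oxygen distance O_D–O_A ≤ 3.5 Å and the angle
between the O_D→H_D bond vector and O_D→O_A smaller than 30°.  Both
hydrogens of every molecule are tested as donors; by default a hydrogen
may bond two acceptors simultaneously (bifurcation), since the pure
geometric criterion does not exclude it — ``unique_donor=True`` restricts
each hydrogen to its smallest-angle acceptor.

A molecule is a coordination *defect* when its (accepted, donated) bond
counts differ from the tetrahedral (2, 2) pattern.  The fraction of
defective molecules per frame, low-pass filtered at 0.1 THz, exposes the
slow collective "defect waves" of the network on the 10 ps scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import minimum_image
from .swing_detection import FilterParams, filter_lowpass
from .trajectory_io import WaterTrajectory

__all__ = [
    "HBondGraph",
    "DefectSeries",
    "hydrogen_bonds",
    "coordination_states",
    "defect_fraction_series",
    "defect_taxonomy",
]

OO_CUTOFF = 3.5     # Å, donor–acceptor oxygen distance
ANGLE_CUTOFF = 30.0  # degrees, H_D–O_D vs O_D–O_A angle at the donor
MIN_OO = 0.5        # Å, oxygens closer than this indicate a corrupt frame


@dataclass
class HBondGraph:
    """Directed donor→acceptor hydrogen-bond list of one frame.

    ``bonds`` has shape (n_bonds, 3): donor molecule, donor H index
    (0 or 1), acceptor molecule.  ``n_in``/``n_out`` are the per-molecule
    accepted/donated bond counts.
    """

    frame: int
    bonds: np.ndarray
    n_in: np.ndarray
    n_out: np.ndarray

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]

    def donated_partners(self, molecule: int) -> set[int]:
        """Acceptor molecules of bonds donated by ``molecule``."""
        if self.n_bonds == 0:
            return set()
        sel = self.bonds[:, 0] == molecule
        return set(self.bonds[sel, 2].tolist())

    def accepted_partners(self, molecule: int) -> set[int]:
        """Donor molecules of bonds accepted by ``molecule``."""
        if self.n_bonds == 0:
            return set()
        sel = self.bonds[:, 2] == molecule
        return set(self.bonds[sel, 0].tolist())


@dataclass
class DefectSeries:
    """Per-frame fraction of coordination-defective molecules."""

    t: np.ndarray
    fraction: np.ndarray
    filtered: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("defect fraction must lie in [0, 1]")


def _candidate_pairs(o_wrapped: np.ndarray, box: np.ndarray, cutoff: float):
    """Unordered O–O pairs within the cutoff under periodic boundaries."""
    if np.min(box) > 2.0 * cutoff + 1e-9:
        tree = cKDTree(o_wrapped, boxsize=box)
        return np.asarray(sorted(tree.query_pairs(cutoff)), dtype=int).reshape(-1, 2)
    # box too small for the KD-tree periodic query: all-pairs fallback
    n = o_wrapped.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    d = minimum_image(o_wrapped[ii] - o_wrapped[jj], box)
    keep = np.linalg.norm(d, axis=1) <= cutoff
    return np.stack([ii[keep], jj[keep]], axis=1)


def hydrogen_bonds(
    positions: np.ndarray,
    box: np.ndarray,
    frame: int = 0,
    oo_cutoff: float = OO_CUTOFF,
    angle_cutoff: float = ANGLE_CUTOFF,
    unique_donor: bool = False,
) -> HBondGraph:
    """Build the hydrogen-bond graph of one frame.

    ``positions`` has shape (n_molecules, 3, 3) — (O, H1, H2) per
    molecule, Å; ``box`` the (3,) orthorhombic box.  All distances use
    the minimum-image convention.  Neighbor search uses a periodic
    KD-tree with the 3.5 Å cutoff; tiny boxes fall back to brute force.
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    n_mol = positions.shape[0]
    o = positions[:, 0, :]
    o_wrapped = np.mod(o, box)
    pairs = _candidate_pairs(o_wrapped, box, oo_cutoff)

    if pairs.size:
        doo = minimum_image(o_wrapped[pairs[:, 1]] - o_wrapped[pairs[:, 0]], box)
        roo = np.linalg.norm(doo, axis=1)
        if np.any(roo < MIN_OO):
            k = int(np.argmin(roo))
            raise ValueError(
                f"overlapping oxygens (molecules {pairs[k, 0]} and "
                f"{pairs[k, 1]}, distance {roo[k]:.3f} Å): corrupt frame"
            )

    # O→H bond directions within the molecule (minimum image for safety)
    oh = minimum_image(positions[:, 1:, :] - positions[:, 0:1, :], box)
    oh_unit = oh / np.linalg.norm(oh, axis=-1, keepdims=True)
    cos_cut = np.cos(np.radians(angle_cutoff))

    if pairs.size:
        doo = minimum_image(o_wrapped[pairs[:, 1]] - o_wrapped[pairs[:, 0]], box)
        roo = np.linalg.norm(doo, axis=1)
        # both orientations of every O-O pair are candidate donor→acceptor
        donors = np.concatenate([pairs[:, 0], pairs[:, 1]])
        acceptors = np.concatenate([pairs[:, 1], pairs[:, 0]])
        u = np.concatenate([doo, -doo]) / np.concatenate([roo, roo])[:, None]
        cosang = np.einsum("phc,pc->ph", oh_unit[donors], u)  # (2P, 2)
        d_idx, h_idx = np.nonzero(cosang > cos_cut)  # angle strictly < cutoff
        bonds = np.stack(
            [donors[d_idx], h_idx, acceptors[d_idx]], axis=1
        ).astype(int)
        bond_cos = cosang[d_idx, h_idx]
    else:
        bonds = np.empty((0, 3), dtype=int)
        bond_cos = np.empty(0)

    if unique_donor and bonds.shape[0]:
        # keep the smallest-angle acceptor per donating hydrogen
        order = np.lexsort((-bond_cos, bonds[:, 1], bonds[:, 0]))
        bonds = bonds[order]
        key = bonds[:, 0] * 2 + bonds[:, 1]
        keep = np.concatenate([[True], key[1:] != key[:-1]])
        bonds = bonds[keep]

    arr = bonds
    n_in = np.bincount(arr[:, 2], minlength=n_mol)
    n_out = np.bincount(arr[:, 0], minlength=n_mol)
    return HBondGraph(frame=frame, bonds=arr, n_in=n_in, n_out=n_out)


def coordination_states(
    graph: HBondGraph, n_molecules: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-molecule (n_in, n_out) and the defective flag.

    A molecule is defective iff it does not accept exactly two and donate
    exactly two hydrogen bonds.
    """
    n_in, n_out = graph.n_in, graph.n_out
    if n_molecules is not None and n_in.size != n_molecules:
        pad = n_molecules - n_in.size
        if pad < 0:
            raise ValueError("graph refers to more molecules than n_molecules")
        n_in = np.concatenate([n_in, np.zeros(pad, dtype=int)])
        n_out = np.concatenate([n_out, np.zeros(pad, dtype=int)])
    defective = (n_in != 2) | (n_out != 2)
    return n_in, n_out, defective


def defect_taxonomy(n_in: np.ndarray, n_out: np.ndarray) -> dict[str, int]:
    """Counts of coordination classes labelled ``"<n_in>in-<n_out>out"``."""
    counts = Counter(f"{i}in-{o}out" for i, o in zip(n_in, n_out))
    return dict(counts)


def defect_fraction_series(
    traj: WaterTrajectory,
    params: FilterParams | None = None,
    unique_donor: bool = False,
) -> DefectSeries:
    """Raw and 0.1 THz-filtered defect-fraction time series.

    The fraction is computed from the raw (unfiltered) bond graphs frame
    by frame; the slow Butterworth filter is post-processing only, used
    to visualise and correlate the defect waves.
    """
    params = params or FilterParams()
    frac = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        g = hydrogen_bonds(
            traj.positions[f], traj.box[f], frame=f, unique_donor=unique_donor
        )
        _, _, defective = coordination_states(g, traj.n_molecules)
        frac[f] = defective.mean()
    filtered = _post_filter(frac, params, traj.dt_frame)
    return DefectSeries(t=traj.times, fraction=frac, filtered=filtered)


def _post_filter(x: np.ndarray, params: FilterParams, dt_fs: float) -> np.ndarray:
    # forward-backward filtering needs a minimum series length; below it
    # the series is returned unfiltered
    if x.size <= 3 * (2 * params.order + 1):
        return x.copy()
    return filter_lowpass(
        x, params.post_cutoff_thz, dt_fs, order=params.order, zero_phase=True
    )
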