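"""Reading water MD trajectories and deriving body-fixed vector series.

This module is deliberately water-only: every residue must consist of one
oxygen and two hydrogens.  Supported on-disk formats are GRO (optionally
with an XTC frame file), multi-model PDB with a CRYST1 record, and a
multi-frame XYZ dialect whose comment line carries the orthorhombic box
(either ``box Lx Ly Lz`` or an extended-XYZ ``Lattice="..."`` entry).
GRO/PDB/XTC parsing is delegated to MDAnalysis.

Units: Å, fs.  Boxes are orthorhombic; triclinic input is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._geometry import angle_between_deg, minimum_image, normalize

__all__ = [
    "WaterTrajectory",
    "VectorSeries",
    "read_trajectory",
    "write_xyz",
    "write_gro",
    "compute_body_vectors",
    "lab_angle_series",
]

#: residue names recognised as water in topology files
WATER_RESIDUE_NAMES = (
    "SOL", "WAT", "HOH", "H2O", "TIP3", "TIP4", "TIP5", "SPC", "SPCE", "W",
)


@dataclass
class WaterTrajectory:
    """Per-frame O/H1/H2 coordinates of a pure-water system.

    Attributes
    ----------
    positions
        Array of shape ``(n_frames, n_molecules, 3, 3)``; the third axis
        indexes the atoms (O, H1, H2), the last the Cartesian components
        in Å.  Hydrogens are stored unwrapped relative to their oxygen.
    box
        Orthorhombic box edge lengths per frame, shape ``(n_frames, 3)`` Å.
    dt_frame
        Uniform frame spacing in fs.
    model_tag
        Free label for the water model (e.g. ``"SPC/E"``).
    """

    positions: np.ndarray
    box: np.ndarray
    dt_frame: float = 4.0
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 4 or self.positions.shape[2:] != (3, 3):
            raise ValueError(
                "positions must have shape (n_frames, n_molecules, 3, 3)"
            )
        if self.box.ndim == 1:
            self.box = np.broadcast_to(
                self.box, (self.positions.shape[0], 3)
            ).copy()
        if self.box.shape != (self.positions.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.dt_frame <= 0:
            raise ValueError("dt_frame must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs, starting at 0."""
        return np.arange(self.n_frames) * self.dt_frame

    def oxygen_positions(self, frame: int) -> np.ndarray:
        """O coordinates of one frame, shape ``(n_molecules, 3)``."""
        return self.positions[frame, :, 0, :]


@dataclass
class VectorSeries:
    """Body-fixed unit-vector time series of one molecule.

    ``kind`` is ``"DP"`` (dipole direction, along the HOH bisector) or
    ``"HH"`` (H1→H2 direction).  ``v`` holds the raw unit vectors, one per
    frame; ``v_F`` the low-pass filtered variant once
    :func:`aquaswing.swing_detection.filter_series` has run.
    """

    molecule: int
    kind: str
    t: np.ndarray
    v: np.ndarray
    v_F: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (self.t.size, 3):
            raise ValueError("v must have shape (n_frames, 3)")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9 * abs(dt[0])):
                raise ValueError("time grid must be strictly uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0

    @property
    def n_frames(self) -> int:
        return self.t.size


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_trajectory(
    path: str | Path,
    topology: str | Path | None = None,
    frame_interval_fs: float = 4.0,
    box: Sequence[float] | None = None,
    model_tag: str = "",
    water_residues: Sequence[str] = WATER_RESIDUE_NAMES,
) -> WaterTrajectory:
    """Read a water trajectory from GRO(+XTC), PDB or XYZ.

    Parameters
    ----------
    path
        Trajectory file.  For GRO+XTC pass the XTC here and the GRO as
        ``topology``.
    frame_interval_fs
        Frame spacing to use when the file carries no time information.
        When the file does provide times they must be uniform and are
        converted to fs.
    box
        Required for XYZ files without a box comment line; ignored for
        formats that store the box.

    Notes
    -----
    Molecules are grouped O, H1, H2 in topology order; hydrogen
    coordinates are unwrapped to sit within the minimum image of their
    oxygen.  Any residue that is not a 1-oxygen/2-hydrogen water raises:
    this tool analyses pure water only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".xyz":
        positions, boxes = _read_xyz(path, box)
        dt = float(frame_interval_fs)
    else:
        positions, boxes, dt = _read_mdanalysis(
            path, topology, frame_interval_fs, water_residues
        )
    positions = _unwrap_hydrogens(positions, boxes)
    return WaterTrajectory(positions, boxes, dt_frame=dt, model_tag=model_tag)


def _read_mdanalysis(path, topology, frame_interval_fs, water_residues):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if topology is not None:
            u = mda.Universe(str(topology), str(path))
        else:
            u = mda.Universe(str(path))

    order = _water_atom_order(u, water_residues)

    frames, boxes, times = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.dimensions is None or np.all(ts.dimensions[:3] == 0):
                raise ValueError(f"{path}: no box information in frame {ts.frame}")
            if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
                raise ValueError(
                    f"{path}: only orthorhombic boxes are supported "
                    f"(angles {ts.dimensions[3:]})"
                )
            frames.append(ts.positions[order].copy())
            boxes.append(ts.dimensions[:3].copy())
            times.append(float(ts.time))

    n_frames = len(frames)
    n_mol = order.shape[0] // 3
    positions = np.asarray(frames).reshape(n_frames, n_mol, 3, 3)
    boxes = np.asarray(boxes, dtype=float)

    times = np.asarray(times)
    if n_frames > 1 and np.any(np.diff(times) > 0):
        dts = np.diff(times)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: non-uniform frame time spacing")
        dt = float(dts[0]) * 1000.0  # MDAnalysis times are ps
    else:
        dt = float(frame_interval_fs)
    return positions, boxes, dt


def _water_atom_order(u, water_residues) -> np.ndarray:
    """Indices rearranging the topology into O,H1,H2 per molecule."""
    allowed = {n.upper() for n in water_residues}
    order = []
    for res in u.residues:
        atoms = res.atoms
        names = [a.name.upper() for a in atoms]
        if len(atoms) != 3 or res.resname.upper() not in allowed:
            raise ValueError(
                f"non-water residue '{res.resname}' with atoms {names}: "
                "this tool analyses pure-water systems only"
            )
        o_idx = [i for i, n in enumerate(names) if n.startswith("O")]
        h_idx = [i for i, n in enumerate(names) if n.startswith("H")]
        if len(o_idx) != 1 or len(h_idx) != 2:
            raise ValueError(
                f"residue '{res.resname}' is not an O+2H water: atoms {names}"
            )
        idx = atoms.indices
        order.extend([idx[o_idx[0]], idx[h_idx[0]], idx[h_idx[1]]])
    return np.asarray(order, dtype=int)


def _read_xyz(path: Path, box) -> tuple[np.ndarray, np.ndarray]:
    frames, boxes = [], []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n_atoms = int(header)
            comment = fh.readline()
            frame_box = _parse_xyz_box(comment)
            if frame_box is None:
                if box is None:
                    raise ValueError(
                        f"{path}: XYZ frame without box comment and no box "
                        "supplied via configuration"
                    )
                frame_box = np.asarray(box, dtype=float)
            names, coords = [], []
            for _ in range(n_atoms):
                parts = fh.readline().split()
                names.append(parts[0].upper())
                coords.append([float(x) for x in parts[1:4]])
            if n_atoms % 3:
                raise ValueError(f"{path}: atom count {n_atoms} not divisible by 3")
            for i in range(0, n_atoms, 3):
                trio = names[i : i + 3]
                if not (trio[0].startswith("O")
                        and trio[1].startswith("H")
                        and trio[2].startswith("H")):
                    raise ValueError(
                        f"{path}: atoms {trio} at index {i} are not an "
                        "O,H,H water; non-water species are not supported"
                    )
            frames.append(np.asarray(coords).reshape(-1, 3, 3))
            boxes.append(frame_box)
    if not frames:
        raise ValueError(f"{path}: empty XYZ file")
    return np.asarray(frames), np.asarray(boxes, dtype=float)


def _parse_xyz_box(comment: str):
    tokens = comment.replace('"', " ").replace("=", " ").split()
    lowered = [t.lower() for t in tokens]
    if "lattice" in lowered:
        i = lowered.index("lattice")
        vals = [float(t) for t in tokens[i + 1 : i + 10]]
        m = np.asarray(vals).reshape(3, 3)
        if not np.allclose(m, np.diag(np.diag(m))):
            raise ValueError("only orthorhombic (diagonal) lattices supported")
        return np.diag(m).astype(float)
    if "box" in lowered:
        i = lowered.index("box")
        return np.asarray([float(t) for t in tokens[i + 1 : i + 4]])
    return None


def _unwrap_hydrogens(positions: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Place each H in the minimum image of its O, frame by frame."""
    out = positions.copy()
    for f in range(out.shape[0]):
        o = out[f, :, 0:1, :]
        dh = out[f, :, 1:, :] - o
        out[f, :, 1:, :] = o + minimum_image(dh, boxes[f])
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_xyz(traj: WaterTrajectory, path: str | Path) -> None:
    """Write a multi-frame XYZ file with a ``box Lx Ly Lz`` comment line."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_molecules * 3}\n")
            bx = traj.box[f]
            fh.write(f"box {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}\n")
            for m in range(traj.n_molecules):
                for name, a in zip(("O", "H", "H"), range(3)):
                    x, y, z = traj.positions[f, m, a]
                    fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def write_gro(traj: WaterTrajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame as a GRO structure file (via MDAnalysis)."""
    import MDAnalysis as mda

    n_mol = traj.n_molecules
    u = mda.Universe.empty(
        n_atoms=3 * n_mol,
        n_residues=n_mol,
        atom_resindex=np.repeat(np.arange(n_mol), 3),
        residue_segindex=np.zeros(n_mol, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("name", ["OW", "HW1", "HW2"] * n_mol)
    u.add_TopologyAttr("resname", ["SOL"] * n_mol)
    u.add_TopologyAttr("resid", np.arange(1, n_mol + 1))
    u.atoms.positions = traj.positions[frame].reshape(-1, 3)
    u.dimensions = np.concatenate([traj.box[frame], [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# body-fixed vectors
# ---------------------------------------------------------------------------

def compute_body_vectors(
    traj: WaterTrajectory,
    kind: str = "DP",
    dipole_mode: str = "bisector",
) -> list[VectorSeries]:
    """Body-fixed unit-vector series for every molecule.

    ``kind="DP"`` gives the dipole direction: the unit vector from the
    oxygen towards the midpoint of the two hydrogens (the HOH bisector).
    ``kind="HH"`` gives the unit vector from H1 to H2, its sign fixed by
    the topology atom order.  ``dipole_mode="charge"`` is equivalent for
    symmetric rigid 3-site geometries and provided for completeness.

    Raises ``ValueError`` naming molecule and frame on degenerate
    geometry (coincident hydrogens, or hydrogens coincident with O).
    """
    kind = kind.upper()
    if kind not in ("DP", "HH"):
        raise ValueError(f"kind must be 'DP' or 'HH', got {kind!r}")
    o = traj.positions[:, :, 0, :]
    h1 = traj.positions[:, :, 1, :]
    h2 = traj.positions[:, :, 2, :]
    if kind == "DP":
        if dipole_mode == "bisector":
            raw = 0.5 * (h1 + h2) - o
        elif dipole_mode == "charge":
            # 3-site charge dipole: q_H[(H1-O)+(H2-O)]; direction only
            raw = (h1 - o) + (h2 - o)
        else:
            raise ValueError(f"unknown dipole_mode {dipole_mode!r}")
    else:
        raw = h2 - h1
    norms = np.linalg.norm(raw, axis=-1)
    bad = norms < 1e-6
    if np.any(bad):
        f, m = np.argwhere(bad)[0]
        raise ValueError(
            f"degenerate water geometry for molecule {m} at frame {f}: "
            f"{kind} vector has zero length"
        )
    v = raw / norms[..., None]
    t = traj.times
    return [
        VectorSeries(molecule=m, kind=kind, t=t, v=v[:, m, :])
        for m in range(traj.n_molecules)
    ]


def lab_angle_series(series: VectorSeries | np.ndarray, axis: str = "z") -> np.ndarray:
    """Angle (degrees) between the vector series and a laboratory axis.

    A proxy for the size of an angular reorientation: the trace of
    arccos(v·ê) in [0, 180]° against time, as commonly plotted for
    individual reorienting molecules.
    """
    idx = {"x": 0, "y": 1, "z": 2}
    if axis not in idx:
        raise ValueError(f"axis must be one of x, y, z; got {axis!r}")
    v = series.v if isinstance(series, VectorSeries) else np.asarray(series)
    e = np.zeros(3)
    e[idx[axis]] = 1.0
    return angle_between_deg(v, e)
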