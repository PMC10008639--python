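"""Ground-truthed synthetic inputs for every analysis stage.

Two generators make the whole pipeline testable without MD output:

* :func:`synthetic_vector_series` — unit-vector time series with planted
  in-plane rotations ("swings") of prescribed start, duration, magnitude
  and rotation plane, superimposed with a fast librational oscillation
  and per-frame angular jitter.  The librational amplitude default is
  calibrated so that the librational angular velocity matches the thermal
  rotational velocity of water at 300 K (≈0.014 rad/fs at 30 THz, giving
  ≈5° amplitude); the 30 THz frequency emulates the fast hindered
  rotational mode (~30 fs period).

* :func:`synthetic_water_box` — periodic ice-like (cubic-ice) water
  configurations in which every unperturbed molecule accepts and donates
  exactly two hydrogen bonds under the geometric 3.5 Å/30° criterion.
  Hydrogens are assigned by orienting the oxygen bond graph along an
  Eulerian circuit, which yields in-degree = out-degree = 2 at every
  oxygen.  Coordination defects of prescribed classes are planted by
  local hydrogen surgery, low-density cavities by radial dilation, and
  scripted molecular rotations couple reorientations to bond breaking.

Every generator is deterministic per seed and returns its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from ._geometry import angle_between_deg, minimum_image, normalize, rotation_matrix
from .trajectory_io import VectorSeries, WaterTrajectory

__all__ = [
    "PlantedSwing",
    "SwingScript",
    "GroundTruthSwing",
    "synthetic_vector_series",
    "random_swing_script",
    "match_events",
    "CavitySpec",
    "ScriptedRotation",
    "MotionSpec",
    "LatticePlan",
    "synthetic_water_box",
]

OH_LENGTH = 1.0          # Å, rigid SPC/E O-H bond
HOH_ANGLE = 109.47       # degrees (tetrahedral, as in SPC/E)
DEFAULT_LATTICE = 6.35   # Å: diamond lattice constant giving O-O ≈ 2.75 Å


# ---------------------------------------------------------------------------
# synthetic vector series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSwing:
    """One scripted rotation episode.

    With ``precession_turns == 0`` (default) the rotation stays in one
    plane — an angular swing proper, with a cosine-eased angle ramp.
    A non-zero value makes the rotation axis precess about the moving
    vector by that many full turns over the episode, emulating the
    diffusive orientational wander between swings, whose rotation plane
    is never fixed.
    """

    start_fs: float
    duration_fs: float
    magnitude_deg: float
    normal: Optional[tuple[float, float, float]] = None  # None: random plane
    precession_turns: float = 0.0
    #: rotation-plane angle relative to the previous episode's plane; a
    #: swing boundary only exists where the plane actually changes, so
    #: scripts control this angle rather than leaving it to chance
    plane_change_deg: Optional[float] = None


@dataclass(frozen=True)
class SwingScript:
    """Recipe for one molecule's synthetic vector series.

    ``libration_amplitude_deg`` is the tilt amplitude about each of two
    fixed axes at ``libration_freq_thz``; ``jitter_deg`` the standard
    deviation of the per-frame random rotation angle.
    """

    events: tuple[PlantedSwing, ...] = ()
    libration_amplitude_deg: float = 5.0
    libration_freq_thz: float = 30.0
    jitter_deg: float = 2.0
    base_vector: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def validate(self, n_frames: int, dt_fs: float) -> None:
        nyquist = 500.0 / dt_fs
        if self.libration_freq_thz >= nyquist:
            raise ValueError(
                f"libration frequency {self.libration_freq_thz} THz is at or "
                f"above the Nyquist frequency {nyquist} THz"
            )
        span = (n_frames - 1) * dt_fs
        intervals = sorted(
            (e.start_fs, e.start_fs + e.duration_fs) for e in self.events
        )
        for (a0, a1), (b0, b1) in zip(intervals[:-1], intervals[1:]):
            if b0 < a1:
                raise ValueError(
                    f"planted events overlap: ({a0}, {a1}) and ({b0}, {b1}) fs"
                )
        for a0, a1 in intervals:
            if a0 < 0 or a1 > span:
                raise ValueError(f"event ({a0}, {a1}) fs outside trajectory span")


@dataclass
class GroundTruthSwing:
    """Planted-event truth, including the realised raw-vector magnitude.

    ``magnitude_planted_deg`` is the scripted in-plane rotation angle;
    ``magnitude_realized_deg`` the angle between the noisy raw vectors at
    the planted boundary frames — the quantity the detection protocol's
    ΔΘ definition targets.
    """

    start_frame: int
    end_frame: int
    t_start: float
    duration: float
    magnitude_planted_deg: float
    magnitude_realized_deg: float
    normal: np.ndarray


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` (n,3) about unit ``axis`` (3,) or (n,3) by
    per-row ``angle`` (n,)."""
    axis = np.broadcast_to(axis, v.shape)
    c = np.cos(angle)[:, None]
    s = np.sin(angle)[:, None]
    cross = np.cross(axis, v)
    dot = np.sum(axis * v, axis=-1, keepdims=True)
    return v * c + cross * s + axis * dot * (1.0 - c)


def synthetic_vector_series(
    script: SwingScript,
    n_frames: int,
    dt_fs: float = 4.0,
    seed: int = 0,
    molecule: int = 0,
    kind: str = "DP",
) -> tuple[VectorSeries, list[GroundTruthSwing]]:
    """Generate a unit-vector series with planted swings and noise.

    The slow component rotates the base vector in each event's plane by a
    smooth cosine-ramped angle; libration and jitter are applied on top
    as small rotations.  Because each event's rotation axis is
    orthogonalised against the current vector, the slow component's
    in-plane angle equals the scripted magnitude exactly.
    """
    script.validate(n_frames, dt_fs)
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * dt_fs

    # slow planted component
    v_slow = np.tile(
        normalize(np.asarray(script.base_vector, dtype=float)), (n_frames, 1)
    )
    truths: list[GroundTruthSwing] = []
    events = sorted(script.events, key=lambda e: e.start_fs)
    prev_axis: Optional[np.ndarray] = None
    for ev in events:
        f0 = int(round(ev.start_fs / dt_fs))
        f1 = int(round((ev.start_fs + ev.duration_fs) / dt_fs))
        f1 = min(f1, n_frames - 1)
        v0 = v_slow[f0]
        if ev.normal is not None:
            raw_normal = np.asarray(ev.normal, dtype=float)
        elif ev.plane_change_deg is not None and prev_axis is not None:
            # rotate the previous plane's normal about the current vector
            # (both normals are perpendicular to v at the junction)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            raw_normal = rotation_matrix(
                v0, sign * np.radians(ev.plane_change_deg)
            ) @ prev_axis
        else:
            raw_normal = _random_perpendicular(rng, v0)
        axis = raw_normal - (raw_normal @ v0) * v0  # force axis ⊥ v0
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            raise ValueError("event normal is parallel to the current vector")
        axis = axis / nrm
        prev_axis = axis
        if ev.precession_turns == 0.0:
            s = (np.arange(f0, n_frames) - f0) / max(f1 - f0, 1)
            ramp = np.where(
                s >= 1.0, 1.0, 0.5 * (1.0 - np.cos(np.pi * np.clip(s, 0, 1)))
            )
            angles = np.radians(ev.magnitude_deg) * ramp
            v_slow[f0:] = _rodrigues(np.tile(v0, (n_frames - f0, 1)), axis, angles)
        else:
            # diffusive wander: constant angular speed, precessing plane
            n_steps = max(f1 - f0, 1)
            step = np.radians(ev.magnitude_deg) / n_steps
            dphi = 2.0 * np.pi * ev.precession_turns / n_steps
            vk, ak = v0.copy(), axis.copy()
            for k in range(f0, f1):
                vk = rotation_matrix(ak, step) @ vk
                vk /= np.linalg.norm(vk)
                ak = rotation_matrix(vk, dphi) @ ak
                ak -= (ak @ vk) * vk
                ak /= np.linalg.norm(ak)
                v_slow[k + 1] = vk
            v_slow[f1:] = vk
        truths.append(
            GroundTruthSwing(
                start_frame=f0,
                end_frame=f1,
                t_start=f0 * dt_fs,
                duration=(f1 - f0) * dt_fs,
                magnitude_planted_deg=ev.magnitude_deg,
                magnitude_realized_deg=np.nan,  # filled after noise
                normal=axis,
            )
        )

    # libration: oscillatory tilts about two fixed random orthogonal axes
    v = v_slow
    if script.libration_amplitude_deg > 0:
        amp = np.radians(script.libration_amplitude_deg)
        omega = 2.0 * np.pi * script.libration_freq_thz / 1000.0  # rad/fs
        e1 = normalize(rng.normal(size=3))
        e2 = normalize(np.cross(e1, rng.normal(size=3)))
        phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
        v = _rodrigues(v, e1, amp * np.sin(omega * t + phi1))
        v = _rodrigues(v, e2, amp * np.sin(omega * t + phi2))

    # per-frame random jitter rotations
    if script.jitter_deg > 0:
        axes = normalize(rng.normal(size=(n_frames, 3)))
        ang = np.radians(script.jitter_deg) * rng.normal(size=n_frames)
        v = _rodrigues(v, axes, ang)

    v = normalize(v)
    for tr in truths:
        tr.magnitude_realized_deg = float(
            angle_between_deg(v[tr.start_frame], v[tr.end_frame])
        )
    series = VectorSeries(molecule=molecule, kind=kind, t=t, v=v)
    return series, truths


def _random_perpendicular(rng: np.random.Generator, v: np.ndarray) -> np.ndarray:
    while True:
        x = rng.normal(size=3)
        x -= (x @ v) * v
        n = np.linalg.norm(x)
        if n > 1e-6:
            return x / n


def random_swing_script(
    rng: np.random.Generator,
    n_events: int = 3,
    magnitude_range: tuple[float, float] = (40.0, 120.0),
    interlude_duration_range: tuple[float, float] = (100.0, 200.0),
    speed_range_deg_fs: tuple[float, float] = (0.6, 1.0),
    plane_change_range: tuple[float, float] = (50.0, 130.0),
    start_fs: float = 100.0,
    **script_kwargs,
) -> SwingScript:
    """Random script of planted swings embedded in diffusive wander.

    Water reorientation alternates between occasional large in-plane
    swings and diffusive orientational wander whose rotation plane
    precesses continuously.  The script tiles the trajectory
    accordingly: ``n_events`` planar swings (default 40–120°), each
    flanked by precessing interludes.  Two choices are physical rather
    than convenient: the chain is contiguous, because a swing boundary
    is a *change of rotation plane* and the protocol can only localise
    it where one rotation hands over to the next; and every episode's
    duration follows from its magnitude at a thermal angular speed
    (default 0.4–0.8 °/fs, of order √(kT/I) for water at 300 K), which
    places the large swings in the 40–200 fs duration regime.

    Large events are the recovery targets; select them from the returned
    ground truth by ``magnitude_planted_deg >= magnitude_range[0]``.
    """
    events = []
    t = start_fs

    def add_interlude():
        nonlocal t
        dur = rng.uniform(*interlude_duration_range)
        speed = rng.uniform(*speed_range_deg_fs)
        events.append(
            PlantedSwing(
                start_fs=t, duration_fs=dur, magnitude_deg=speed * dur,
                plane_change_deg=rng.uniform(*plane_change_range),
            )
        )
        t += dur

    add_interlude()
    for _ in range(n_events):
        mag = rng.uniform(*magnitude_range)
        dur = mag / rng.uniform(*speed_range_deg_fs)
        events.append(
            PlantedSwing(
                start_fs=t, duration_fs=dur, magnitude_deg=mag,
                plane_change_deg=rng.uniform(*plane_change_range),
            )
        )
        t += dur
        add_interlude()
    return SwingScript(events=tuple(events), **script_kwargs)


def match_events(
    truths: Sequence[GroundTruthSwing],
    detected: Sequence,
    theta_tol: float = 10.0,
    dt_tol: float = 25.0,
    use_realized: bool = True,
) -> tuple[int, list[tuple[float, float]]]:
    """Count planted swings recovered within the stated tolerances.

    A planted swing is recovered when some detected event's interval
    overlaps it, the detected ΔΘ is within ``theta_tol`` degrees of the
    ground-truth magnitude and the detected Δt within ``dt_tol`` fs of
    the planted duration.  Returns the number recovered and the
    (ΔΘ error, Δt error) pairs of the best overlap match per truth.
    """
    recovered = 0
    errors: list[tuple[float, float]] = []
    for tr in truths:
        t0, t1 = tr.t_start, tr.t_start + tr.duration
        best = None
        best_overlap = 0.0
        for ev in detected:
            ov = min(t1, ev.t_end) - max(t0, ev.t_start)
            if ov > best_overlap:
                best_overlap = ov
                best = ev
        if best is None:
            errors.append((np.inf, np.inf))
            continue
        target = tr.magnitude_realized_deg if use_realized else tr.magnitude_planted_deg
        dtheta = abs(best.magnitude_deg - target)
        ddur = abs(best.duration - tr.duration)
        errors.append((dtheta, ddur))
        if dtheta <= theta_tol and ddur <= dt_tol:
            recovered += 1
    return recovered, errors


# ---------------------------------------------------------------------------
# synthetic water boxes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CavitySpec:
    """Radial dilation creating a low-density region.

    Molecules whose O lies within ``radius`` of ``center`` are displaced
    outward: their distance from the center is scaled by ``dilation``.
    """

    center: tuple[float, float, float]
    radius: float
    dilation: float = 1.3


@dataclass(frozen=True)
class ScriptedRotation:
    """Progressive rigid rotation of one molecule about its oxygen."""

    molecule: int
    start_frame: int
    end_frame: int
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    angle_deg: float = 109.47


@dataclass(frozen=True)
class MotionSpec:
    """Frame-to-frame motion of the synthetic box (no dynamics).

    ``jitter_pos_A`` translates each molecule rigidly by an iid random
    displacement per frame; ``jitter_rot_deg`` applies an iid random
    rotation of each molecule about its oxygen per frame.  ``scripted``
    rotations reorient selected molecules progressively, coupling a
    detectable angular swing to hydrogen-bond breaking.
    """

    jitter_pos_A: float = 0.0
    jitter_rot_deg: float = 0.0
    scripted: tuple[ScriptedRotation, ...] = ()


@dataclass(frozen=True)
class LatticePlan:
    """Recipe for a hydrogen-bonded cubic-ice configuration.

    ``defects`` lists (molecule, class) surgeries with class one of
    ``2in-1out``, ``1in-2out``, ``1in-1out``, ``2in-0out``, ``0in-2out``;
    alternatively ``defect_fraction`` plants randomly placed broken-bond
    pairs until approximately that fraction of molecules is defective.
    """

    lattice_constant: float = DEFAULT_LATTICE
    n_cells: tuple[int, int, int] = (2, 2, 2)
    defects: tuple[tuple[int, str], ...] = ()
    defect_fraction: float = 0.0
    cavity: Optional[CavitySpec] = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cells) < 2:
            raise ValueError(
                "need at least 2 unit cells per dimension so that the four "
                "hydrogen-bond neighbours of each molecule are distinct"
            )
        nn = self.lattice_constant * np.sqrt(3) / 4.0
        if not 1.5 <= nn <= 3.5:
            # O-O spacing must sit inside the H-bond distance window
            raise ValueError(
                f"lattice constant {self.lattice_constant} Å gives O-O "
                f"distance {nn:.2f} Å outside the hydrogen-bond range"
            )
        if not 0 <= self.defect_fraction < 1:
            raise ValueError("defect_fraction must be in [0, 1)")


def _diamond_oxygens(plan: LatticePlan) -> tuple[np.ndarray, np.ndarray]:
    a = plan.lattice_constant
    base = np.array(
        [
            [0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0],
            [0.25, 0.25, 0.25], [0.25, 0.75, 0.75],
            [0.75, 0.25, 0.75], [0.75, 0.75, 0.25],
        ]
    )
    nx_, ny_, nz_ = plan.n_cells
    cells = np.array(
        [[i, j, k] for i in range(nx_) for j in range(ny_) for k in range(nz_)],
        dtype=float,
    )
    frac = (cells[:, None, :] + base[None, :, :]).reshape(-1, 3)
    box = a * np.asarray(plan.n_cells, dtype=float)
    return frac * a, box


def _oriented_bond_graph(oxy: np.ndarray, box: np.ndarray, a: float):
    """Orient the O-O nearest-neighbour graph with in=out=2 everywhere."""
    nn_dist = a * np.sqrt(3) / 4.0
    tree = cKDTree(np.mod(oxy, box), boxsize=box)
    pairs = sorted(tree.query_pairs(nn_dist * 1.1))
    g = nx.Graph(pairs)
    if any(d != 4 for _, d in g.degree) or g.number_of_nodes() != oxy.shape[0]:
        raise ValueError("lattice plan incompatible with 4-coordination")
    # every vertex has even degree, so an Eulerian circuit exists; each
    # vertex is entered as often as it is left -> in-degree = out-degree = 2
    donated: dict[int, list[int]] = {i: [] for i in g.nodes}
    for u, v in nx.eulerian_circuit(g):
        donated[u].append(v)
    return donated


def synthetic_water_box(
    plan: LatticePlan,
    n_frames: int = 1,
    dt_fs: float = 4.0,
    motion: MotionSpec | None = None,
    seed: Optional[int] = None,
) -> tuple[WaterTrajectory, dict]:
    """Build a periodic water configuration with planted H-bond topology.

    Returns the trajectory and a ground-truth dict with keys
    ``defective`` (sorted molecule indices expected to be defective),
    ``classes`` (molecule → planted coordination class, including the
    surgery's partner molecules), ``defect_fraction`` and
    ``cavity_molecules`` (indices initially inside the cavity).

    Defect surgery moves a donating hydrogen onto the bisector of the
    molecule's two *accepted* bond directions, which is ≥54° away from
    every neighbour direction and therefore cleanly removes exactly the
    targeted bond.  When a cavity is dilated, the exact defect truth no
    longer holds for molecules near the cavity.
    """
    plan.validate()
    motion = motion or MotionSpec()
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    oxy, box = _diamond_oxygens(plan)
    n_mol = oxy.shape[0]
    donated = _oriented_bond_graph(oxy, box, plan.lattice_constant)

    # neighbour unit directions (4 per molecule, minimum image)
    def direction(i: int, j: int) -> np.ndarray:
        return normalize(minimum_image(oxy[j] - oxy[i], box))

    accepted: dict[int, list[int]] = {i: [] for i in range(n_mol)}
    for d, accs in donated.items():
        for a_ in accs:
            accepted[a_].append(d)

    h_dirs = np.empty((n_mol, 2, 3))
    for i in range(n_mol):
        for h, acc in enumerate(donated[i]):
            h_dirs[i, h] = direction(i, acc)

    # --- plant defects -----------------------------------------------------
    classes: dict[int, str] = {}
    used: set[int] = set()

    def break_donated(mol: int, h: int) -> int:
        """Point H ``h`` of ``mol`` along the bisector of its accepted
        directions; returns the acceptor that loses a bond."""
        acc = donated[mol][h]
        d1 = direction(mol, accepted[mol][0])
        d2 = direction(mol, accepted[mol][1])
        h_dirs[mol, h] = normalize(d1 + d2)
        return acc

    if plan.defect_fraction > 0:
        # each broken donor→acceptor bond makes exactly two defectives
        n_pairs = int(round(plan.defect_fraction * n_mol / 2))
        planted = 0
        for mol in rng.permutation(n_mol):
            if planted >= n_pairs:
                break
            if mol in used:
                continue
            h = next(
                (h for h in (0, 1) if donated[mol][h] not in used), None
            )
            if h is None:
                continue
            acc = break_donated(int(mol), h)
            used.update((int(mol), int(acc)))
            classes[int(mol)] = "2in-1out"
            classes.setdefault(int(acc), "partner")
            planted += 1
        if planted < n_pairs:
            raise ValueError(
                "could not place the requested defect fraction without "
                "overlapping surgeries; reduce defect_fraction or enlarge the box"
            )

    surgeries = list(plan.defects)

    for mol, cls in surgeries:
        touched = {mol}
        if cls in ("2in-1out", "1in-1out"):
            touched.add(break_donated(mol, 0))
        if cls == "2in-0out":
            touched.add(break_donated(mol, 0))
            touched.add(break_donated(mol, 1))
        if cls in ("1in-2out", "1in-1out", "0in-2out"):
            donors = accepted[mol]
            count = 2 if cls == "0in-2out" else 1
            for d in donors[:count]:
                h = donated[d].index(mol)
                # move the donor's H onto its own accepted-bisector
                dd1 = direction(d, accepted[d][0])
                dd2 = direction(d, accepted[d][1])
                h_dirs[d, h] = normalize(dd1 + dd2)
                touched.add(d)
        if cls not in ("2in-1out", "1in-2out", "1in-1out", "2in-0out", "0in-2out"):
            raise ValueError(f"unknown defect class {cls!r}")
        if used & touched:
            raise ValueError(
                f"defect surgeries overlap at molecules {sorted(used & touched)}"
            )
        used |= touched
        classes[mol] = cls
        for p in touched - {mol}:
            classes.setdefault(p, "partner")

    # --- assemble coordinates ---------------------------------------------
    base = np.empty((n_mol, 3, 3))
    base[:, 0] = oxy
    base[:, 1] = oxy + OH_LENGTH * h_dirs[:, 0]
    base[:, 2] = oxy + OH_LENGTH * h_dirs[:, 1]

    cavity_molecules: list[int] = []
    if plan.cavity is not None:
        c = np.asarray(plan.cavity.center, dtype=float)
        d = minimum_image(base[:, 0] - c, box)
        r = np.linalg.norm(d, axis=1)
        inside = r < plan.cavity.radius
        cavity_molecules = np.where(inside)[0].tolist()
        shift = (plan.cavity.dilation - 1.0) * d[inside]
        base[inside] += shift[:, None, :]

    frames = np.repeat(base[None], n_frames, axis=0)
    # scripted rotations compose in script order, so the same molecule
    # may rotate out and back (a burst that heals its own defects)
    composed: dict[int, np.ndarray] = {}
    for rot in motion.scripted:
        f0, f1 = rot.start_frame, rot.end_frame
        if not (0 <= f0 < f1 < n_frames):
            raise ValueError(f"scripted rotation frames ({f0}, {f1}) out of range")
        m = rot.molecule
        if m not in composed:
            composed[m] = np.tile(np.eye(3), (n_frames, 1, 1))
        axis = np.asarray(rot.axis, dtype=float)
        for f in range(f0, n_frames):
            s = min(1.0, (f - f0) / (f1 - f0))
            ramp = 0.5 * (1.0 - np.cos(np.pi * s))
            composed[m][f] = (
                rotation_matrix(axis, np.radians(rot.angle_deg) * ramp)
                @ composed[m][f]
            )
    for m, R in composed.items():
        rel = base[m, 1:] - base[m, 0]
        for f in range(n_frames):
            frames[f, m, 1:] = frames[f, m, 0] + rel @ R[f].T
    if motion.jitter_rot_deg > 0:
        axes = normalize(rng.normal(size=(n_frames, n_mol, 1, 3)))
        angs = np.radians(motion.jitter_rot_deg) * rng.normal(
            size=(n_frames, n_mol, 1, 1)
        )
        o = frames[:, :, 0:1, :]
        rel = frames[:, :, 1:, :] - o
        c, s = np.cos(angs), np.sin(angs)
        cross = np.cross(np.broadcast_to(axes, rel.shape), rel)
        dot = np.sum(axes * rel, axis=-1, keepdims=True)
        frames[:, :, 1:, :] = o + rel * c + cross * s + axes * dot * (1.0 - c)
    if motion.jitter_pos_A > 0:
        frames += rng.normal(
            scale=motion.jitter_pos_A, size=(n_frames, n_mol, 1, 1)
        ) * normalize(rng.normal(size=(n_frames, n_mol, 1, 3)))

    traj = WaterTrajectory(
        frames, np.broadcast_to(box, (n_frames, 3)).copy(),
        dt_frame=dt_fs, model_tag="synthetic-ice",
    )
    defective = sorted(int(m) for m in classes)
    truth = {
        "defective": defective,
        "classes": {int(k): v for k, v in classes.items()},
        "defect_fraction": len(defective) / n_mol,
        "cavity_molecules": cavity_molecules,
        "n_molecules": n_mol,
        "box": box,
    }
    return traj, truth


def burst_scenario(
    seed: int = 0,
    n_cells: tuple[int, int, int] = (3, 3, 3),
    n_frames: int = 1000,
    dt_fs: float = 4.0,
    burst_frames: Sequence[int] = (150, 400, 650),
    molecules_per_burst: int = 18,
    rotation_deg: float = 100.0,
    half_duration_frames: int = 25,
    cluster_radius: float = 7.0,
    jitter_rot_deg: float = 1.5,
) -> tuple[WaterTrajectory, dict]:
    """Cooperative-burst trajectory: clustered swings coupled to defects.

    Starting from a pristine hydrogen-bonded lattice, groups of
    spatially clustered molecules perform large out-and-back rotations
    (out over ``half_duration_frames``, back over the next).  While a
    molecule is rotated away its donated bonds are broken, so each
    burst produces simultaneously: a spike in the defect fraction, a
    spike in the concurrent large-swing count, and a spatial cluster of
    jumping molecules — the qualitative signature of the collective
    burst mechanism, here with known ground truth.

    Returns the trajectory and a truth dict with the per-burst molecule
    sets and frame windows.
    """
    rng = np.random.default_rng(seed)
    plan = LatticePlan(n_cells=n_cells, seed=seed)
    oxy, box = _diamond_oxygens(plan)
    n_mol = oxy.shape[0]
    scripted: list[ScriptedRotation] = []
    bursts: list[dict] = []
    for f0 in burst_frames:
        center = oxy[rng.integers(n_mol)]
        d = np.linalg.norm(minimum_image(oxy - center, box), axis=1)
        candidates = np.where(d <= cluster_radius)[0]
        members = rng.choice(
            candidates, size=min(molecules_per_burst, candidates.size),
            replace=False,
        )
        for m in members:
            axis = tuple(rng.normal(size=3))
            stagger = int(rng.integers(0, 6))
            scripted.append(
                ScriptedRotation(int(m), f0 + stagger,
                                 f0 + stagger + half_duration_frames,
                                 axis=axis, angle_deg=rotation_deg)
            )
            scripted.append(
                ScriptedRotation(int(m), f0 + stagger + half_duration_frames,
                                 f0 + stagger + 2 * half_duration_frames,
                                 axis=axis, angle_deg=-rotation_deg)
            )
        bursts.append(
            {"frame": int(f0), "molecules": sorted(int(m) for m in members)}
        )
    motion = MotionSpec(jitter_rot_deg=jitter_rot_deg, scripted=tuple(scripted))
    traj, _ = synthetic_water_box(plan, n_frames=n_frames, dt_fs=dt_fs,
                                  motion=motion, seed=seed)
    return traj, {"bursts": bursts, "half_duration_frames": half_duration_frames}
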