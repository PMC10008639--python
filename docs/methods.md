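# Methods

This note documents the models, parameters and numerical choices behind
`aquaswing`, and what its synthetic closed-loop tests do and do not show
about real MD data.

## Units and conventions

Coordinates are Å, times fs, frequencies THz (1 fs⁻¹ = 1000 THz).
Boxes are orthorhombic; triclinic input is rejected.  Molecules are
stored O, H1, H2 with hydrogens unwrapped into the minimum image of
their oxygen.  The dipole (DP) vector is the geometric HOH bisector:
for rigid 3-site models the charge dipole lies along the bisector, so
this definition is model-agnostic; a charge-weighted variant is
available (`dipole_mode="charge"`) but identical for symmetric rigid
geometries.  The HH vector's sign follows topology atom order, which
makes swing magnitudes free of the 180° ambiguity.

## The swing detector

The filtering chain is a 2nd-order digital Butterworth low-pass with a
10 THz cutoff (magnitude response 1/√2 at the cutoff, checked
analytically in the tests) followed by a centered 25-sample moving mean
(100 fs at the default 4 fs frame spacing), applied per Cartesian
component.  The Butterworth stage is applied forward–backward
(zero-phase) by default: detected boundaries then align with extrema of
the raw series instead of being shifted by the group delay.  A causal
single-pass mode is retained (`zero_phase=False`).  Component-wise
filtering shortens the vector, so v_F is re-normalized before any
rotation-plane geometry; this restores the unit-sphere contract that
makes n = v_F × dv_F/dt a pure rotation-rate vector (its magnitude is
the angular speed in rad/fs).

The derivative uses central differences, one-sided at the trajectory
ends.  Where ‖n‖ < `eps_norm` (default 1e−4 fs⁻¹) the vector is
effectively stationary and has no rotation plane; the last valid plane
direction is carried forward (leading frames take the first valid one)
so stationary stretches do not emit spurious boundaries.

Boundaries are local maxima of q(t) with height and prominence above
`q_threshold` (default 1e−3) separated by at least
`min_separation_frames` (default 2).  q is identically zero for any
noiseless single-plane rotation, so the threshold only rejects
numerical noise; the tests sweep its neighborhood implicitly through
the noisy closed loop.  Peak positions are refined to sub-frame
resolution by parabolic interpolation for the start time and duration;
ΔΘ always uses the raw vectors at the nearest integer frames, exactly
at the boundary (a `endpoint_average` option averages ±1 frame to damp
librational aliasing, off by default).  Swings touching a trajectory
end have an unobserved boundary and are dropped by default
(`drop_edge_events=False` keeps them, flagged).  For windowed counting
each swing is timestamped at its midpoint t_start + Δt/2
(configurable to the start time).

### Resolution limit

The 100 fs moving mean bounds how precisely a boundary can be located.
In a noiseless experiment, the measured q-peak gap for a planted planar
swing of duration d between thermal-speed neighbours behaves like
√(d² + w²) with w ≈ 76 fs: a 40 fs swing is reported as ≈100 fs, while
durations above ~100 fs are recovered within ~20 fs.  Consequently the
closed-loop recovery of planted swings is near-perfect (≈97%) for
durations ≥ 100 fs and degrades for shorter plants; duration estimates
below the smoothing window should be read as upper bounds.  This is a
property of the protocol's filter chain, not of the implementation.

## Hydrogen bonds and defects

A pair is bonded when the donor–acceptor O–O distance is ≤ 3.5 Å and
the angle between O_D→H_D and O_D→O_A is < 30°, both anchored at the
donor oxygen.  Both hydrogens are tested as donors and a hydrogen may
bond two acceptors (bifurcation) — the pure geometric criterion does
not exclude it; `unique_donor=True` keeps only the smallest-angle
acceptor per hydrogen.  Neighbor search uses a periodic KD-tree with
the 3.5 Å cutoff and falls back to brute force for boxes smaller than
twice the cutoff; the optimized path is tested for exact equality with
an all-pairs oracle.

A molecule is a coordination defect unless (n_in, n_out) = (2, 2).
Defect fractions are computed from raw per-frame graphs; the 0.1 THz
2nd-order Butterworth applied afterwards is post-processing only, used
to expose the ~10 ps defect waves.  That filter is meaningful only for
series much longer than 10 ps; on shorter series the raw fraction
should be used (the CLI exposes `--raw`).

## Collectivity measures

Concurrent-swing series count event midpoints in a sliding window
(stride one frame; half-windows at the edges excluded).  Wave
visualisation uses a 1 ps window, concurrency statistics 200 fs.
Pearson correlations between defect fractions and swing counts are
computed on the common time grid, by default after 0.1 THz filtering of
both series.  Because both series are strongly autocorrelated, naive
p-values are invalid: the uncertainty is the standard deviation of a
moving-block bootstrap (default block 10 ps) and the p-value comes from
a null of random circular shifts, which preserves each series'
autocorrelation.

Nearest-jumper distances pool, over disjoint windows (stride = window,
to limit double counting), the minimum-image O–O distance from each
jumping molecule to its k-th nearest *other* jumping molecule at the
window's central frame.  The random control redraws, per window, the
same number of molecules uniformly without replacement, with a recorded
seed.  Distributions are smoothed with a fixed-width Gaussian kernel
(0.1–0.2 Å for distances) renormalized on the grid, and compared with
the two-sample Kolmogorov–Smirnov test (asymptotic p).  The headline
contrast must vanish under label shuffling; this null equivalence is a
standing test.

## Local environment of swings

Bond breaking compares the donated- and accepted-partner sets of the
swinging molecule at the exact boundary frames (a ±δ frame buffer is
available); a partner present before and absent after is a break on
that side.  Newly appearing partners are recorded as formations but are
not part of the headline per-event fractions, which report the
probability of ≥1 break per side as a function of the ΔΘ threshold
(bond-weighted means are emitted alongside, since the per-event
probability is one of two defensible readings).

Voronoi densities use all three atoms of every water as sites.  The
periodic tessellation replicates sites into neighbouring images within
a 6 Å buffer of each boundary (a bounded form of full 27-image
replication); the contract is exact volume conservation — the cells of
the central copies tile the box to ≤1e−6 relative error — not any
particular replication scheme.  ρ_voro = 1/(V_O+V_H1+V_H2) is ~0.03 Å⁻³
in water-like configurations; density PDFs default to a 0.001 Å⁻³
kernel width.

## The synthetic generators

The generators define the package's test conditions; their defaults
were fixed from physical considerations, once.

**Vector series.**  Planted swings are smooth (cosine-eased) in-plane
rotations; the rotation axis is orthogonalised against the current
vector so the planted in-plane angle is exact.  Libration is an
oscillatory tilt about two fixed axes at 30 THz (the fast hindered
rotational mode, ~33 fs period) with 5° amplitude — chosen so the
librational angular velocity matches the thermal rotational velocity
√(kT/I) ≈ 0.014 rad/fs of water at 300 K — plus 2° per-frame random
jitter.  Ground truth records both the scripted magnitude and the
realised angle between the raw vectors at the planted boundary frames
(the quantity the protocol's ΔΘ definition targets).

`random_swing_script` tiles the series with a *contiguous chain* of
planar episodes: target swings (40–120°) flanked by interludes of
100–200 fs, all at thermal angular speeds (0.6–1.0 °/fs, so target
durations span 40–200 fs), with junction plane changes of 50–130°.
Two aspects are deliberate: the chain is contiguous because a swing
boundary is a *change of rotation plane* — the protocol cannot localise
a boundary against a stationary background, where the filtered signal's
plane is undefined; and junction plane changes are kept away from 0°
because two successive rotations in the same plane are, by the
protocol's own definition, one swing.  What passing the closed loop
shows is that the protocol recovers swings whose boundaries are genuine
plane changes at thermal speeds; it does not certify behaviour for
sub-80 fs swings (see the resolution limit) or for motion regimes the
chain does not emulate (e.g. slow orientational diffusion between rare
jumps).

**Water boxes.**  Oxygens sit on a diamond (cubic-ice) lattice with
a = 6.35 Å, giving O–O ≈ 2.75 Å inside the H-bond window.  Hydrogens
(rigid SPC/E geometry: O–H 1.0 Å, HOH 109.47°) are assigned by
orienting the O–O bond graph along an Eulerian circuit, which exists
because every vertex has even degree (4) and guarantees exactly two
donated and two accepted bonds per molecule — the generated pristine
box is verified, not assumed, to be 100% (2,2)-coordinated under the
geometric criterion.  Coordination defects are planted by pointing a
donating hydrogen onto the bisector of the molecule's accepted-bond
directions (≥54.7° from every neighbour direction, so exactly the
targeted bond is removed); each broken bond yields a known defect pair.
Cavities dilate radial positions inside a sphere to create low-density
regions.  Scripted rotations (composable, so out-and-back bursts are
possible) couple detectable swings to bond breaking.  At least 2 unit
cells per dimension are required so each molecule's four bond
neighbours are distinct.

`burst_scenario` combines these into the desk-scale analog of the
collective burst mechanism: spatially clustered groups of molecules
perform large out-and-back rotations, producing simultaneously a defect
wave, a spike in concurrent large swings and a cluster of jumpers, all
with known ground truth.

What the box generator does *not* emulate: thermal disorder of a real
liquid (the lattice is crystalline with optional jitter), translational
diffusion, realistic H-bond lifetime statistics, and flexible or
polarizable water models.  Tests passing on these boxes certify the
geometric and topological machinery, not liquid-state statistics.

## Problem sizes

The standing test suite and the acceptance script use 200 vector series
of ~800 frames, lattice boxes of 64–216 molecules and burst
trajectories of 4 ps; these sizes give stable statistics for every
reported rate while keeping a full run in minutes on one core.  The
code is size-agnostic — the same paths handle thousands of molecules
and nanosecond trajectories.

Reproducing the reference MD statistics (defect↔swing correlations of
rigid SPC/E at 300 K, concurrent-swing populations, bond-breaking
asymmetries and model comparisons) requires externally produced
trajectories (~1000 waters, frames every 4 fs, ≥200 ps); producing them
needs an MD engine and is outside this package's scope.  The test
`test_reference_md_statistics` runs the full pipeline on such a
trajectory when placed at `data/reference_md/production.{gro,xtc}`.

## Known limitations

- Boundary localization, and hence duration estimates, are limited by
  the 100 fs smoothing window (see the resolution limit above).
- The q-based protocol is blind to transitions between rotations in
  (nearly) the same plane — by construction they are one swing.
- Voronoi tessellation cost grows quickly with atom count; per-frame
  volumes for very large boxes are the slowest path in the package.
- Only orthorhombic boxes and pure-water systems are supported.
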