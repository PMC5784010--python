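# Methods

This note documents the models, conventions and numerical choices behind
`ncpgeom`, and what its synthetic validation does and does not establish.

## The duplex axis

The per-bp axis of the nucleosomal DNA is estimated as a running mean
(window 3, shrunken at the ends) of base-pair base-centroid positions,
where a bp centroid is the mean of the base heavy atoms of both paired
nucleotides.  This deliberately replaces a full helical-axis algorithm:
at superhelix scale (radius ≈ 40 Å, pitch ≈ 25 Å) the smoothed centroid
curve tracks an ideal axis closely, with a measured systematic inward
radial bias below 0.1 Å on noise-free synthetic superhelices (test
`test_systematic_radial_bias_below_half_angstrom` bounds it at 0.5 Å).
All comparisons of derived quantities against externally reported values
therefore carry ±1.5 Å / ±3° tolerances.  Per-step curvature is the
turning angle between consecutive chord segments.  For an ideal helix the
exact closed form is `arccos[(r_e² cos Δθ + c²)/(r_e² + c²)]` with
`c = p/2π` and `r_e = r·sinc(Δθ/2)`; the widely quoted tangent form
(`r_e = r`) is its Δθ→0 limit and differs by ~10⁻⁵ deg at nucleosome
geometry, which is why the chord form is the test oracle.

## Superhelix fit

The ideal helix `q(i) = c + r(cos θᵢ û₁ + sin θᵢ û₂) + s·θᵢ û₃`,
`θᵢ = θ₀ + ωi`, is fitted to the central 129 axis points (all points,
flagged `truncated`, when fewer exist; fewer than 7 is an error).
Initialisation: principal-component plane → candidate axis; algebraic
(Kåsa) circle fit of the projected points → centre and radius; linear
fits of unwrapped azimuth vs bp index and of axial coordinate vs azimuth
→ ω, θ₀ and the pitch slope.  Because a tall helix has its axis along the
*largest* principal component, all three principal directions are tried
and the refinement (Levenberg–Marquardt, xtol 1e-12, ftol 1e-14, ≤200
iteration-equivalents) with the lowest rmsd wins; the initialisation is
kept if refinement ever degrades it.  Canonical form: ω > 0 (axis flipped
together with the phase when needed), phase wrapped to (−180°, 180°], and
the reported centre is the axis point at the central bp's phase, which
makes it comparable with the frame origin.  Handedness is the sign of the
axial slope in this right-handed parametrisation; reported pitch is the
magnitude.  Noise-free recovery is exact (≤1e-6 over a radius 20–60 Å ×
pitch 10–50 Å grid, both hands); with σ = 0.3 Å Gaussian noise the mean
recovered radius over 200 replicates is within 0.1 Å of truth.

## The NCP frame and its sign convention

Origin: mass-weighted COM of the globular histone atoms (unit masses are
a config option).  Symmetry axis `û`: origin → COM of the central bp
(index 0) or of the two half-integer-index bps for even counts.  Plane
normal: the two bps nearest ±90° of superhelical azimuth from the dyad
(selected on the fitted helix; fallback ±round(77.5/4) bp indices when no
fit is supplied) define `n₊ = û×r̂₊` and `n₋ = r̂₋×û`; the normal is their
normalised median, re-orthogonalised against `û`, and `v̂ = n̂×û` completes
a right-handed triad.  **Sign rule** (invented here; nothing in the
convention fixes a global side): `n̂` is oriented so the bp centred index
increases counterclockwise when viewed from +`n̂`.  Every signed angle
downstream (φ, δ, tilt direction) inherits this choice, and mirroring a
structure flips the normal.  Note that the median normal of an ideal
pitched superhelix is tilted `≈ asin((p/4)/r) ≈ 9°` from the cylinder
axis — the same 6–10° axis-vs-normal angle seen for fitted crystal
structures — because the quarter-turn bps sit half a pitch apart axially;
a frame construction that ignored this would misrepresent the cylinder.
The frame degenerates (error) if |û·n̂| ≥ 0.35 before re-orthogonalisation.

## Stacking parameters

With NCP1's frame: dist = |o₂−o₁|; signed rise = (o₂−o₁)·n̂₁ (magnitude
reported, signed value kept, so dist² = rise² + shift² exactly); shift =
in-plane offset; φ = signed angle of that offset vs `û₁`; δ = signed angle
between `û₁` and the in-plane projection of `û₂` (±180° reported as
+180°); tilt = plane–plane angle folded to [0°, 90°]; tilt direction =
signed angle of the projection of `n̂₂` (sign-aligned to `n̂₂·n̂₁ ≥ 0`).
Classes: head-to-tail |δ| ≥ 150°, head-to-head |δ| ≤ 30°, perpendicular
||δ|−90| < 30° (open band, so δ = 120° is "other"), tolerance
configurable.  `synthetic.place_pair` solves the construction exactly
(normal from tilt/tilt-direction, then the unique `û₂ ⊥ n̂₂` in
span{target in-plane direction, n̂₁}), so parameter round trips are exact
to 1e-6 over randomized targets; tilt = 90° is rejected (δ undefined).

Crystal pairs: every space-group operator (from the file's cell and
Hermann–Mauguin symbol via gemmi's tables) × lattice shifts in {−1,0,1}³
whose image of the gHO COM lies within 100 Å; unique unordered pairs
within the 80 Å survey cutoff are deduplicated by a rounded signature of
(dist, both rises, both shifts, tilt, |δ|), which collapses
symmetry-equivalent images; results sort by distance.  Both directed
parameter sets of a pair are kept: rise and shift are direction-dependent
whenever the two frames differ, and which particle the convention calls
NCP1 is not fixed by the source data.

## Contacts and charges

An ion pair is a basic marker atom (Lys NZ, Arg CZ) within 7.5 Å of an
acceptor marker (DNA P, Glu CD, Asp CG), reduced to unique
(residue, partner) pairs at minimum atom distance — per-residue, not
per-atom, multiplicity.  Charges: +1 Lys/Arg, −1 Glu/Asp, His neutral,
−1 per phosphate.  DNA charge counts the P atoms present (−294 for a
147-bp duplex with all phosphates; a config switch excludes 5′-terminal
phosphates, giving −292).  Tail/globular boundaries default to common
literature definitions (H3 1–36, H4 1–24, H2A 1–13 and 119–129, H2B
1–30) and are fully overridable; with the bundled reference sequences
they put +74 e on the tails and +70 e on the globular core of a +144 e
octamer.  The acidic patch is looked up per H2A/H2B copy at canonical
numbering (H2A E56/E61/E64/D90/E91/E92, H2B E110); entries absent or
renamed are reported missing rather than failing, since deposited H2B
numbering conventions differ by a few residues.

## Coarse-grained model

DNA: 74 units of 2 bp, each one neutral core bead (mean of the two bp
centroids) plus four −1 e phosphate beads at the P positions (C1′ or the
core position when a terminal phosphate is unresolved) — 370 DNA beads,
−296 e.  A 147-bp source duplicates its terminal bp to fill the 74th
unit; the model records this.  Histones: one bead per residue at Cα with
the residue's unit charge; building fails loudly when tail coordinates
are missing, because the bead model needs complete tails.  Topology:
consecutive core–core and intra-tail bonds and angles, phosphate–core
bonds, and an elastic network over globular bead pairs within 10 Å (the
cutoff is configurable; spring constants are the simulation engine's
business, not the topology's).  The bead-model frame reuses the atomic
frame machinery with core beads as bp centroids; since units straddle the
dyad, the core curve is linearly interpolated at index 0, which brings
the bead-model frame within 0.01° of the atomic one on the same geometry.
Trajectories are plain per-frame xyz plus a JSON sidecar mapping beads to
(particle, group); the only analysis provided is the pooled NCP–NCP
COM-distance histogram.

## Synthetic generators and what passing means

`make_ideal_sh_dna` winds a pseudo-atomic duplex (P, C1′, one base atom
per nucleotide; antiparallel numbering; exact 10.4 Å C1′–C1′ separation;
B-DNA twist 360/10.5°) on an exact superhelix; base atoms are placed
symmetrically so bp centroids equal axis points exactly.  Defaults are
the surveyed nucleosome geometry: radius 40.0 Å, pitch 25.5 Å, 147 bp,
77.5 bp/turn, left-handed.  `make_toy_ncp` adds an octamer of Cα strings
carrying the bundled histone sequences, arranged as point-inverted pairs
so the (globular) COM sits exactly at the superhelix centre, and records
the analytically exact frame (including the ~9° median-normal tilt).
Toy crystals place the particle at the cell centre under P 1 or
P 2₁2₁2₁ with hand-checkable closest contacts.  All generators are
seed-deterministic with provenance sidecars.

These fixtures validate the mathematics end to end — axis estimation,
fitting, frames, symmetry expansion, pair parameters, bookkeeping — but
they are ideal: real crystal structures add sequence-dependent axis
irregularity, unresolved tails, alternate conformations, multi-particle
asymmetric units and non-canonical numbering.  The pipeline handles those
paths (altloc resolution by occupancy, octamer clustering, DNA-window
selection on long duplexes, lenient domain assignment), and the tests
that check published per-structure values exercise them, but only when
the reference structures have been fetched; a clean synthetic run alone
does not certify agreement with deposited coordinates.

## Bundled reference data

Histone typing scores chains by best ungapped sliding identity (≥40%,
ties within 5% ambiguous) against bundled canonical vertebrate core
histone sequences.  Single-residue differences from any particular
deposited entry are immaterial at that threshold.  The charge and bead
counts that the acceptance script reports are computed from these
sequences at run time and should be read as properties of the bundled
reference set, not of any specific PDB deposition.

## Known limitations

* The axis estimator is not a base-pair-frame helical axis; entry/exit
  curvature contrasts are reproduced qualitatively, and absolute per-step
  values inherit the stated bias bound.
* δ, φ and tilt-direction signs depend on the package's normal-sign rule;
  comparisons with other conventions should use magnitudes.
* Crystal pair deduplication is numerical (1e-3 rounding), not
  group-theoretic.
* No energies, no simulation, no electrostatic surfaces; the CG module
  stops at topology and geometry analysis.
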