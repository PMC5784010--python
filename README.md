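# ncpgeom

Geometry toolkit for nucleosome core particles (NCPs) and
nucleosome–nucleosome stacking.

Condensed chromatin is built from face-to-face stacks of NCPs — flat
cylinders of ~145–147 bp duplex DNA wound ~1.8 left-handed superhelical
turns around a histone octamer.  Describing *how* two nucleosomes sit
against each other needs a particle-fixed coordinate system, the way base
pairs have rise/twist/roll conventions.  `ncpgeom` implements such an
NCP-centred convention for structural biologists and modellers working
with nucleosome crystal structures or coarse-grained chromatin models:

* **Superhelix fit** — nonlinear least-squares fit of an ideal helix
  `q(i) = c + r(cos θᵢ û₁ + sin θᵢ û₂) + (p/2π) θᵢ û₃`, `θᵢ = θ₀ + ωi`, to
  the central 129 axis points of the nucleosomal DNA, giving radius `r`,
  pitch `p`, bp/turn `360/|ω|`, handedness and the dyad.
* **NCP frame** — origin at the centre of mass of the globular histone
  octamer (gHO), symmetry axis `û` through the central base pair(s), and an
  oriented plane normal `n̂` built from the base pairs ±90° of superhelical
  azimuth away from the dyad.
* **Stacking parameters** — the seven pairwise quantities (distance, rise,
  shift, shift orientation φ, axes orientation δ, plane–plane tilt, tilt
  direction) locating NCP2 in NCP1's frame, plus head-to-head /
  head-to-tail / perpendicular classification and crystal-packing pair
  enumeration from space-group operators.
* **Ionic contacts & charge budgets** — Lys/Arg ↔ phosphate/carboxylate
  ion pairs under a 7.5 Å marker-atom criterion, tail vs globular charge
  bookkeeping, acidic-patch residues.
* **Coarse-grained builder** — the 5-beads-per-2-bp DNA + one-bead-per-
  residue histone model (topology, ±1 e charges, elastic network), and the
  same frame machinery applied to bead models and plain-xyz trajectories.
* **Synthetic ground truth** — generators for ideal superhelical DNA, toy
  NCPs, prescribed-parameter NCP pairs and toy crystals, so every stage is
  validated by exact round trips.

## Worked example

```python
import ncpgeom as ng

model, truth = ng.make_toy_ncp(ng.SyntheticSpec(seed=0))  # ideal 147-bp NCP
ng.assign_domains(model)
ng.pair_bases(model)

ax = ng.compute_axis(model)
fit = ng.fit_superhelix(ax)
frame = ng.build_frame(model, sh=fit)
comp = ng.compare_frames(fit, frame, ax)
```

prints, via the obvious f-strings:

```text
radius = 39.91 A, pitch = 25.50 A, 77.50 bp/turn, left-handed
SH centre to NCP origin: 0.00 A; dyad vs symmetry axis: 0.00 deg; SH axis vs plane normal: 8.89 deg
stack: dist=58.5 A rise=55.0 A shift=20.0 A delta=-25 deg tilt=8 deg -> head-to-head
CG model: 1352 beads, charges {'dna': -296, 'gho': 70, 'tails': 74}, net -152 e
```

The generator wound the DNA at radius 40.0 Å and pitch 25.5 Å: the fitted
radius is 0.09 Å low (the smoothed-centroid axis estimator's known inward
bias), the pitch and 77.5 bp/turn are exact, and the frame origin lands on
the superhelix centre by construction.  The 8.9° angle between superhelix
axis and plane normal is a real geometric feature of the construction, not
an error — the quarter-turn base pairs defining the plane sit half a pitch
apart axially.  The stack line shows a prescribed tetranucleosome-like
placement (rise 55 Å, shift 20 Å, δ = −25°) recovered exactly by
`compute_stack_params`, and the last line is the coarse-grained topology's
charge audit.

A command-line interface mirrors the library:

```sh
ncpgeom synth --preset toy-crystal --out crystal.pdb
ncpgeom stack crystal.pdb            # per-pair CSV: dist, rise, shift, ...
ncpgeom analyze *.pdb --out survey.csv
ncpgeom contacts my_ncp.pdb
ncpgeom cg-build my_ncp.pdb --out cg.json
```

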