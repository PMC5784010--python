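"""Ground-truth synthetic fixtures: ideal superhelical DNA, toy NCPs,
prescribed-parameter NCP pairs and toy crystals.

Everything here is generated geometry with recorded ground truth, so each
pipeline stage (axis estimation, superhelix fit, frame construction,
stacking parameters, crystal expansion) can be tested as an exact round
trip.  Pseudo-atoms follow PDB naming (residues DA/DT, atoms P/C1'/N1)
so fixtures pass through the real readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .axis import DuplexAxis
from .frame import NCPFrame
from .geometry import rotation_about_axis, unit
from .structure import ATOM_COLUMNS, AtomicModel, NCPModel, write_pdb
from . import refdata

__all__ = ["SyntheticSpec", "make_ideal_sh_dna", "make_straight_dna",
           "make_toy_ncp", "place_pair", "make_toy_crystal"]

B_DNA_TWIST_DEG = 360.0 / 10.5
C1_HALF_SEPARATION = 5.2        # half the C1'-C1' through-axis distance
PHOSPHATE_RADIUS = 8.9


@dataclass
class SyntheticSpec:
    """Parameters of the ideal left-handed nucleosomal superhelix.

    Defaults are the study conditions reported for nucleosome crystal
    structures: radius ~40 A, pitch ~25.5 A, 147 bp, ~77.5 bp per
    superhelical turn, left-handed winding, B-DNA duplex template.
    """

    radius: float = 40.0
    pitch: float = 25.5
    bp: int = 147
    bp_per_turn: float = 77.5
    handedness: str = "left"
    duplex_rise: float = 3.4       # A/bp, straight-duplex template
    c1_offset: float = C1_HALF_SEPARATION
    noise_sigma: float = 0.0
    seed: int = 0
    centre: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.radius, self.pitch, self.bp_per_turn, self.duplex_rise) <= 0:
            raise ValueError("all superhelix lengths/rates must be positive")
        if self.bp < 10:
            raise ValueError("need at least 10 bp")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")

    @property
    def omega_deg(self) -> float:
        return 360.0 / self.bp_per_turn

    def provenance(self) -> dict:
        return {"generator": "ncpgeom.synthetic", "seed": self.seed,
                "radius": self.radius, "pitch": self.pitch, "bp": self.bp,
                "bp_per_turn": self.bp_per_turn, "handedness": self.handedness,
                "noise_sigma": self.noise_sigma}


def _sh_axis_points(spec: SyntheticSpec):
    """Exact axis points, local twist frames and helix ground truth."""
    n = spec.bp
    centred = np.arange(n) - (n - 1) / 2.0
    omega = np.radians(spec.omega_deg)
    slope = spec.pitch / (2 * np.pi) * (1.0 if spec.handedness == "right" else -1.0)
    th = omega * centred
    centre = np.asarray(spec.centre, float)
    u1, u2, u3 = np.eye(3)
    pts = (centre
           + spec.radius * (np.cos(th)[:, None] * u1 + np.sin(th)[:, None] * u2)
           + (slope * th)[:, None] * u3)
    tangents = (spec.radius * (-np.sin(th)[:, None] * u1 + np.cos(th)[:, None] * u2)
                + slope * np.ones_like(th)[:, None] * u3)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    radial = np.cos(th)[:, None] * u1 + np.sin(th)[:, None] * u2
    truth = {
        "centre": centre, "axis": u3.copy(), "radius": spec.radius,
        "pitch": spec.pitch, "omega_deg": spec.omega_deg,
        "handedness": spec.handedness, "dyad": u1.copy(),
        "arc_per_bp": omega * np.sqrt(spec.radius**2 + slope**2),
    }
    return centred, pts, tangents, radial, truth


def _exact_plane_normal(spec: SyntheticSpec, centred: np.ndarray,
                        pts: np.ndarray, centre: np.ndarray,
                        u: np.ndarray) -> np.ndarray:
    """Median plane normal of the exact construction on the exact geometry.

    Note the result is *not* the cylinder axis: because the quarter-turn
    base pairs sit half a pitch apart axially, the median normal is tilted
    away from the superhelix axis by ~asin(pitch/4 / radius) (~9 degrees
    at nucleosome geometry) -- the same tilt seen between the fitted-helix
    axis and the symmetry-frame normal in crystal structures.
    """
    th = spec.omega_deg * centred
    k_plus = int(np.argmin(np.abs(th - 90.0)))
    k_minus = int(np.argmin(np.abs(th + 90.0)))
    r_plus = pts[k_plus] - centre
    r_minus = pts[k_minus] - centre
    n = unit(unit(np.cross(u, r_plus)) + unit(np.cross(r_minus, u)))
    # bp index increases counterclockwise about +z in this construction
    if n[2] < 0:
        n = -n
    return n


def _duplex_atoms(spec: SyntheticSpec, centred, pts, tangents, radial,
                  rng: np.random.Generator | None):
    """Pseudo-atomic duplex wound on the given axis curve."""
    n = spec.bp
    rows = []
    serial = 0
    twist = np.radians(B_DNA_TWIST_DEG)
    strand2_rows = []
    for k in range(n):
        t_hat = tangents[k]
        e1 = radial[k] - np.dot(radial[k], t_hat) * t_hat
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(t_hat, e1)
        phi = twist * k
        g = np.cos(phi) * e1 + np.sin(phi) * e2
        gp = -np.sin(phi) * e1 + np.cos(phi) * e2
        a = pts[k]
        p_dir1 = np.cos(phi + 1.2) * e1 + np.sin(phi + 1.2) * e2
        p_dir2 = -(np.cos(phi - 1.2) * e1 + np.sin(phi - 1.2) * e2)
        # strand 1 residue k+1 (5'->3' along increasing index)
        for name, pos in (("P", a + PHOSPHATE_RADIUS * p_dir1),
                          ("C1'", a + spec.c1_offset * g),
                          ("N1", a + 0.5 * g)):
            serial += 1
            rows.append((serial, name, "", "DA", k + 1, "I",
                         "P" if name == "P" else "C", 1.0, *pos))
        # strand 2 residue n-k pairs with strand-1 residue k+1
        s2 = []
        for name, pos in (("P", a + PHOSPHATE_RADIUS * p_dir2),
                          ("C1'", a - spec.c1_offset * g),
                          ("N1", a - 0.5 * g)):
            s2.append((name, "DT", n - k, "J",
                       "P" if name == "P" else "C", pos))
        strand2_rows.append(s2)
    # strand 2 written in its own 5'->3' residue order
    for s2 in reversed(strand2_rows):
        for name, resname, resseq, chain, elem, pos in s2:
            serial += 1
            rows.append((serial, name, "", resname, resseq, chain, elem, 1.0, *pos))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        atoms[["x", "y", "z"]] += rng.normal(0.0, spec.noise_sigma,
                                             (len(atoms), 3))
    return atoms


def _dna_strand_lists(n: int):
    s1 = [("I", k + 1, "DA") for k in range(n)]
    s2 = [("J", j + 1, "DT") for j in range(n)]
    return s1, s2


def make_ideal_sh_dna(spec: SyntheticSpec) -> tuple[NCPModel, DuplexAxis]:
    """Ideal superhelical duplex plus its exact ground-truth axis."""
    centred, pts, tangents, radial, truth = _sh_axis_points(spec)
    atoms = _duplex_atoms(spec, centred, pts, tangents, radial, None)
    model = NCPModel(atoms=atoms, chain_types={},
                     dna_strands=_dna_strand_lists(spec.bp))
    model.truth = truth                    # type: ignore[attr-defined]
    axis = DuplexAxis(centred, pts, provenance="synthetic-exact")
    return model, axis


def make_straight_dna(n_bp: int = 30, rise: float = 3.4,
                      c1_offset: float = C1_HALF_SEPARATION) -> tuple[NCPModel, DuplexAxis]:
    """Straight B-DNA-like duplex along +z (axis exactly collinear)."""
    centred = np.arange(n_bp) - (n_bp - 1) / 2.0
    rows = []
    serial = 0
    twist = np.radians(B_DNA_TWIST_DEG)
    strand2 = []
    for k in range(n_bp):
        a = np.array([0.0, 0.0, rise * centred[k]])
        g = np.array([np.cos(twist * k), np.sin(twist * k), 0.0])
        for name, pos in (("C1'", a + c1_offset * g), ("N1", a + 0.5 * g)):
            serial += 1
            rows.append((serial, name, "", "DA", k + 1, "I", "C", 1.0, *pos))
        strand2.append([("C1'", a - c1_offset * g), ("N1", a - 0.5 * g), k])
    for entry in reversed(strand2):
        (n1, p1), (n2, p2), k = entry
        for name, pos in ((n1, p1), (n2, p2)):
            serial += 1
            rows.append((serial, name, "", "DT", n_bp - k, "J", "C", 1.0, *pos))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    model = NCPModel(atoms=atoms, chain_types={},
                     dna_strands=_dna_strand_lists(n_bp))
    pts = np.column_stack([np.zeros(n_bp), np.zeros(n_bp), rise * centred])
    return model, DuplexAxis(centred, pts, provenance="synthetic-exact")


# --------------------------------------------------------------------------
# toy NCP


_CHAIN_LAYOUT = [("A", "H3"), ("B", "H4"), ("C", "H2A"), ("D", "H2B"),
                 ("E", "H3"), ("F", "H4"), ("G", "H2A"), ("H", "H2B")]


def _octamer_atoms(spec: SyntheticSpec, histones: str, serial0: int) -> pd.DataFrame:
    """Dummy octamer whose (globular) COM is exactly the superhelix centre.

    Chains E-H are point inversions of chains A-D through the centre, so
    both the full COM and, with the default tail table, the globular COM
    coincide with the centre by construction.
    """
    centre = np.asarray(spec.centre, float)
    rows = []
    serial = serial0
    for ci, (chain, htype) in enumerate(_CHAIN_LAYOUT[:4]):
        if histones == "reference":
            seq = refdata.HISTONE_SEQUENCES[htype]
            inv = {v: k for k, v in sorted(refdata.AA3TO1.items())
                   if k not in ("MSE", "SEC", "PYL")}
            residues = [inv[a] for a in seq]
        else:
            residues = ["ALA"] * 70
        n_res = len(residues)
        # a compact helical string inside the DNA superhelix
        base_ang = ci * np.pi / 2.0
        tt = np.linspace(0, 2.5 * np.pi, n_res)
        pos = np.column_stack([
            (14.0 + 6.0 * np.cos(tt)) * np.cos(base_ang + tt / 3.0),
            (14.0 + 6.0 * np.sin(tt)) * np.sin(base_ang + tt / 3.0),
            6.0 * np.sin(tt + base_ang),
        ]) + centre
        mirror = 2.0 * centre - pos
        for local, (chain2, _) in ((pos, (chain, htype)),
                                   (mirror, (_CHAIN_LAYOUT[ci + 4][0], htype))):
            for r, (resname, xyz) in enumerate(zip(residues, local), start=1):
                serial += 1
                rows.append((serial, "CA", "", resname, r, chain2, "C", 1.0, *xyz))
    return pd.DataFrame(rows, columns=ATOM_COLUMNS)


def make_toy_ncp(spec: SyntheticSpec | None = None,
                 histones: str = "reference") -> tuple[NCPModel, dict]:
    """Ideal-superhelix DNA plus a dummy octamer, with frame ground truth.

    `histones="reference"` threads the bundled histone sequences as
    C-alpha strings (so chain typing and domain assignment work on the
    fixture); `histones="beads"` uses plain 70-residue poly-Ala chains.
    Returns the model and a ground-truth dict with the designed origin,
    symmetry axis, plane normal and superhelix parameters.
    """
    spec = spec or SyntheticSpec()
    centred, pts, tangents, radial, truth = _sh_axis_points(spec)
    rng = np.random.default_rng(spec.seed)
    dna = _duplex_atoms(spec, centred, pts, tangents, radial, rng)
    octa = _octamer_atoms(spec, histones, serial0=int(dna["serial"].max()))
    atoms = pd.concat([dna, octa], ignore_index=True)
    chain_types = {}
    seen: dict[str, int] = {}
    for chain, htype in _CHAIN_LAYOUT:
        chain_types[chain] = (htype, seen.get(htype, 0))
        seen[htype] = seen.get(htype, 0) + 1
    model = NCPModel(atoms=atoms, chain_types=chain_types,
                     dna_strands=_dna_strand_lists(spec.bp))
    n = spec.bp
    if n % 2:
        u = unit(pts[(n - 1) // 2] - truth["centre"])
    else:
        u = unit(0.5 * (pts[n // 2 - 1] + pts[n // 2]) - truth["centre"])
    truth = dict(truth)
    normal = _exact_plane_normal(spec, centred, pts, truth["centre"], u)
    truth.update({"origin": truth["centre"], "u": u, "normal": normal,
                  "v": np.cross(normal, u),
                  "provenance": spec.provenance()})
    model.truth = truth                    # type: ignore[attr-defined]
    return model, truth


def truth_frame(truth: dict) -> NCPFrame:
    """Ground-truth NCPFrame of a toy particle (normal re-orthogonalised)."""
    u = unit(truth["u"])
    nrm = unit(truth["normal"] - np.dot(truth["normal"], u) * u)
    return NCPFrame(origin=np.asarray(truth["origin"], float), u=u,
                    normal=nrm, v=np.cross(nrm, u))


# --------------------------------------------------------------------------
# prescribed-parameter pair placement


def place_pair(frame1: NCPFrame, rise_signed: float = 55.0, shift: float = 20.0,
               phi_deg: float = 0.0, delta_deg: float = 180.0,
               tilt_deg: float = 10.0, tilt_direction_deg: float = 0.0,
               dist: float | None = None) -> tuple[np.ndarray, np.ndarray, NCPFrame]:
    """Rigid transform placing a second NCP at exactly the requested
    stacking parameters relative to `frame1`.

    `dist` is redundant (dist = hypot(rise, shift)); passing an
    inconsistent value raises.  Returns (rotation, translation, frame2)
    with frame2 = transform applied to frame1.
    """
    if not -90.0 < tilt_deg < 90.0:
        raise ValueError("tilt must lie in (-90, 90) degrees")
    implied = float(np.hypot(rise_signed, shift))
    if dist is not None and abs(dist - implied) > 1e-6:
        raise ValueError(
            f"dist={dist} inconsistent with hypot(rise, shift)={implied:.6f}; "
            "dist is derived, not independently specifiable")
    u1, v1, n1 = frame1.u, frame1.v, frame1.normal
    t = np.radians(tilt_deg)
    td = np.radians(tilt_direction_deg)
    dlt = np.radians(delta_deg)
    d_tilt = np.cos(td) * u1 + np.sin(td) * v1
    n2 = np.cos(t) * n1 + np.sin(t) * d_tilt
    g = np.cos(dlt) * u1 + np.sin(dlt) * v1
    # u2 in span{g, n1}, perpendicular to n2, in-plane projection along +g
    if abs(np.cos(t)) < 1e-9:
        raise ValueError("tilt of 90 degrees leaves delta undefined")
    beta = -np.sin(t) * np.cos(dlt - td) / np.cos(t)
    u2 = unit(g + beta * n1)
    v2 = np.cross(n2, u2)
    origin2 = (frame1.origin + shift * (np.cos(np.radians(phi_deg)) * u1
                                        + np.sin(np.radians(phi_deg)) * v1)
               + rise_signed * n1)
    B1 = np.column_stack([u1, v1, n1])
    B2 = np.column_stack([u2, v2, n2])
    R = B2 @ B1.T
    trans = origin2 - R @ frame1.origin
    frame2 = NCPFrame(origin=origin2, u=u2, normal=n2, v=v2)
    return R, trans, frame2


# --------------------------------------------------------------------------
# toy crystal


def make_toy_crystal(model: NCPModel, path: str | Path,
                     spacegroup: str = "P 1",
                     cell: tuple[float, float, float] = (150.0, 150.0, 60.0),
                     min_com_separation: float = 30.0) -> Path:
    """Write the toy NCP as a one-particle crystal (PDB with CRYST1).

    The particle is placed at the centre of the cell.  With `P 1` the
    closest neighbours are pure lattice translations (a columnar stack
    along the shortest cell edge); with `P 21 21 21` the two-fold screw
    images flip the symmetry axis, giving head-to-tail pairs.  Raises if
    any image centre comes closer than `min_com_separation`.
    """
    from .structure import expand_crystal   # local import, avoids cycle at import time

    truth = getattr(model, "truth", None)
    centre = np.zeros(3) if truth is None else np.asarray(truth["origin"], float)
    shift_to_centre = 0.5 * np.asarray(cell, float) - centre
    atoms = model.atoms.copy()
    atoms[["x", "y", "z"]] += shift_to_centre
    placed = AtomicModel(atoms=atoms, cell=(*cell, 90.0, 90.0, 90.0),
                         spacegroup=spacegroup)
    from .structure import _spacegroup_operations
    placed.operations = _spacegroup_operations(spacegroup)
    com = centre + shift_to_centre

    class _Probe:
        source = placed
        def globular_com(self):
            return com
    images = expand_crystal(_Probe(), max_com_distance=3 * max(cell), com=com)
    dists = [np.linalg.norm(p.com - com) for p in images[1:]]
    if dists and min(dists) < min_com_separation:
        raise ValueError(f"overlapping crystal images: nearest COM at "
                         f"{min(dists):.1f} A < {min_com_separation} A")
    path = Path(path)
    write_pdb(placed, path)
    sidecar = {"spacegroup": spacegroup, "cell": list(cell),
               "com": com.tolist(),
               "provenance": getattr(model, "truth", {}).get("provenance", {})
               if truth else {}}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path
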