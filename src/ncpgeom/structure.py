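"""Structure I/O and nucleosome component identification.

Atomic structures are read with gemmi (PDB and mmCIF) into a flat pandas
atom table.  Protein chains are typed against bundled histone reference
sequences by ungapped sliding identity, DNA strands are paired into a
duplex with centred base-pair indexing, histone residues are split into
tail and globular domains, and crystal symmetry is expanded into rigid
placements of the particle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from . import refdata

__all__ = [
    "AtomicModel", "TailTable", "BasePair", "NCPModel", "NCPPlacement",
    "load_structure", "write_pdb", "identify_components", "assign_domains",
    "pair_bases", "expand_crystal",
    "ParseError", "IncompleteNCPError", "AmbiguousTypingError",
    "RegisterError", "DomainTableError",
]


class ParseError(ValueError):
    pass


class IncompleteNCPError(ValueError):
    pass


class AmbiguousTypingError(ValueError):
    pass


class RegisterError(ValueError):
    pass


class DomainTableError(ValueError):
    pass


ATOM_COLUMNS = ["serial", "name", "altloc", "resname", "resseq", "chain",
                "element", "occ", "x", "y", "z"]


def _orthogonalization_matrix(cell: tuple[float, ...]) -> np.ndarray:
    """Standard fractional->Cartesian matrix for cell (a,b,c,alpha,beta,gamma)."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.radians([al, be, ga])
    cos_al, cos_be, cos_ga, sin_ga = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
    v = np.sqrt(1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga)
    return np.array([
        [a, b * cos_ga, c * cos_be],
        [0.0, b * sin_ga, c * (cos_al - cos_be * cos_ga) / sin_ga],
        [0.0, 0.0, c * v / sin_ga],
    ])


@dataclass
class AtomicModel:
    """Flat atom table plus unit cell and fractional symmetry operators."""

    atoms: pd.DataFrame
    cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str | None = None
    # list of (R_frac 3x3, t_frac 3); identity always first when present
    operations: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    source_path: str | None = None

    def __post_init__(self) -> None:
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ParseError("non-finite atom coordinates")
        if self.cell is not None and not self.operations:
            self.operations = [(np.eye(3), np.zeros(3))]

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def orth_matrix(self) -> np.ndarray:
        if self.cell is None:
            raise ValueError("model has no unit cell")
        return _orthogonalization_matrix(self.cell)

    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def chain_residues(self, chain: str) -> pd.DataFrame:
        """One row per residue (resseq, resname), ordered by residue number."""
        sub = self.atoms[self.atoms["chain"] == chain]
        res = sub.drop_duplicates(subset=["resseq"])[["resseq", "resname"]]
        return res.sort_values("resseq", kind="stable").reset_index(drop=True)


def _spacegroup_operations(sg_name: str) -> list[tuple[np.ndarray, np.ndarray]]:
    sg = gemmi.find_spacegroup_by_name(sg_name)
    if sg is None:
        raise ParseError(f"unknown space group {sg_name!r}")
    ops = []
    for op in sg.operations():
        den = float(op.DEN)
        ops.append((np.array(op.rot, float) / den, np.array(op.tran, float) / den))
    # identity first, deterministically
    ops.sort(key=lambda rt: (0 if np.allclose(rt[0], np.eye(3)) and
                             np.allclose(rt[1], 0) else 1, rt[0].tolist(), rt[1].tolist()))
    return ops


def load_structure(path: str | Path, format: str = "auto") -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    Alternate locations are resolved per atom to the highest-occupancy
    conformer (ties broken alphabetically by altloc id).  Unit cell and
    space-group operators are populated when the file records them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"{path.name}: no coordinate models")
    model = st[0]

    rows = []
    serial = 0
    for chain in model:
        for res in chain:
            for atom in res:
                serial += 1
                rows.append((serial, atom.name, atom.altloc or "", res.name,
                             res.seqid.num, chain.name, atom.element.name,
                             atom.occ, atom.pos.x, atom.pos.y, atom.pos.z))
    if not rows:
        raise ParseError(f"{path.name}: no atom coordinates")
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)

    # one conformer per atom: highest occupancy, ties alphabetical by altloc
    atoms = atoms.sort_values(["chain", "resseq", "name", "occ", "altloc"],
                              ascending=[True, True, True, False, True],
                              kind="stable")
    atoms = atoms.drop_duplicates(subset=["chain", "resseq", "name"], keep="first")
    atoms = atoms.sort_values("serial", kind="stable").reset_index(drop=True)

    cell = None
    ops: list[tuple[np.ndarray, np.ndarray]] = []
    sg_name = None
    c = st.cell
    if c is not None and c.a > 1.5 and c.b > 1.5 and c.c > 1.5:
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        sg_name = st.spacegroup_hm or "P 1"
        ops = _spacegroup_operations(sg_name)
    return AtomicModel(atoms=atoms, cell=cell, spacegroup=sg_name,
                       operations=ops, source_path=str(path))


def write_pdb(model: AtomicModel, path: str | Path) -> None:
    """Write an :class:`AtomicModel` back to a fixed-column PDB file."""
    st = gemmi.Structure()
    st.name = "ncpgeom"
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
        st.spacegroup_hm = model.spacegroup or "P 1"
    gm = gemmi.Model("1")
    for chain_name in model.chains():
        ch = gemmi.Chain(chain_name)
        sub = model.atoms[model.atoms["chain"] == chain_name]
        for resseq, res_atoms in sub.groupby("resseq", sort=True):
            res = gemmi.Residue()
            res.name = str(res_atoms["resname"].iloc[0])
            res.seqid = gemmi.SeqId(int(resseq), " ")
            for row in res_atoms.itertuples():
                at = gemmi.Atom()
                at.name = row.name
                at.element = gemmi.Element(row.element or "C")
                at.occ = float(row.occ)
                at.pos = gemmi.Position(row.x, row.y, row.z)
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# tail table


@dataclass
class TailTable:
    """Residue ranges (inclusive, file numbering) counted as flexible tail."""

    ranges: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        for htype, rr in self.ranges.items():
            spans = sorted(rr)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise DomainTableError(f"overlapping tail ranges for {htype}")

    @classmethod
    def default(cls) -> "TailTable":
        return cls({k: list(v) for k, v in refdata.DEFAULT_TAIL_RANGES.items()})

    @classmethod
    def empty(cls) -> "TailTable":
        return cls({})

    def is_tail(self, histone_type: str, resseq: int) -> bool:
        for a, b in self.ranges.get(histone_type, []):
            if a <= resseq <= b:
                return True
        return False


# --------------------------------------------------------------------------
# NCP model


@dataclass
class BasePair:
    """One Watson-Crick pair with centred index and base-centroid position."""

    index: float                     # 0 at the middle; half-integers for even counts
    res1: tuple[str, int, str]       # (chain, resseq, resname) on strand 1
    res2: tuple[str, int, str]
    centroid: np.ndarray             # mean of base heavy atoms of both nucleotides


@dataclass
class NCPModel:
    """One nucleosome: typed histone chains, paired DNA duplex, domains."""

    atoms: pd.DataFrame
    chain_types: dict[str, tuple[str, int]]          # chain -> (histone type, copy)
    dna_strands: tuple[list[tuple[str, int, str]], list[tuple[str, int, str]]]
    source: AtomicModel | None = None
    domains: dict[tuple[str, int], str] | None = None  # (chain, resseq) -> tail|globular
    base_pairs: list[BasePair] | None = None

    # -- conveniences -------------------------------------------------------

    def histone_chains(self, htype: str | None = None) -> list[str]:
        return [c for c, (t, _) in sorted(self.chain_types.items())
                if htype is None or t == htype]

    def residue_domain(self, chain: str, resseq: int) -> str:
        if self.domains is None:
            raise ValueError("domains not assigned; call assign_domains first")
        return self.domains[(chain, resseq)]

    def _histone_atoms(self) -> pd.DataFrame:
        return self.atoms[self.atoms["chain"].isin(self.chain_types)]

    def globular_com(self, mass_weighted: bool = True) -> np.ndarray:
        """Centre of mass of the globular (non-tail) histone atoms."""
        if self.domains is None:
            raise ValueError("domains not assigned; call assign_domains first")
        sub = self._histone_atoms()
        glob = np.array([self.domains[(c, r)] == "globular"
                         for c, r in zip(sub["chain"], sub["resseq"])])
        sub = sub[glob]
        if len(sub) == 0:
            raise ValueError("no globular histone atoms")
        xyz = sub[["x", "y", "z"]].to_numpy(float)
        if mass_weighted:
            w = np.array([refdata.element_mass(e) for e in sub["element"]])
        else:
            w = np.ones(len(sub))
        return (xyz * w[:, None]).sum(axis=0) / w.sum()

    def charged_residue_counts(self, domain: str | None = None) -> dict[str, int]:
        """Counts of Lys/Arg/Glu/Asp residues, optionally per domain."""
        counts = {k: 0 for k in refdata.RESIDUE_CHARGES}
        sub = self._histone_atoms().drop_duplicates(subset=["chain", "resseq"])
        for row in sub.itertuples():
            rn = row.resname.upper()
            if rn not in counts:
                continue
            if domain is not None and self.domains is not None:
                if self.domains[(row.chain, row.resseq)] != domain:
                    continue
            counts[rn] += 1
        return counts

    def bp_table(self) -> pd.DataFrame:
        """Base-pair table (index, strand residues, centroid) as a DataFrame."""
        if self.base_pairs is None:
            raise ValueError("base pairs not assigned; call pair_bases first")
        rows = [(bp.index, f"{bp.res1[0]}/{bp.res1[1]}/{bp.res1[2]}",
                 f"{bp.res2[0]}/{bp.res2[1]}/{bp.res2[2]}",
                 bp.centroid[0], bp.centroid[1], bp.centroid[2])
                for bp in self.base_pairs]
        return pd.DataFrame(rows, columns=["index", "strand1_res", "strand2_res",
                                           "centroid_x", "centroid_y", "centroid_z"])

    def summary(self) -> dict:
        n_bp = len(self.base_pairs) if self.base_pairs else None
        return {
            "chains": {c: {"type": t, "copy": i} for c, (t, i) in self.chain_types.items()},
            "dna_strand_lengths": [len(s) for s in self.dna_strands],
            "bp_count": n_bp,
            "domains_assigned": self.domains is not None,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=1))


# --------------------------------------------------------------------------
# histone typing


def _ungapped_identity(seq: str, ref: str) -> float:
    """Best ungapped-overlap identity fraction between two sequences."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(ref.encode(), dtype=np.uint8)
    best = 0.0
    for off in range(-(len(a) - 1), len(b)):
        lo_a, lo_b = max(0, -off), max(0, off)
        n = min(len(a) - lo_a, len(b) - lo_b)
        if n < 30:          # ignore tiny overlaps
            continue
        matches = int(np.count_nonzero(a[lo_a:lo_a + n] == b[lo_b:lo_b + n]))
        best = max(best, matches / n)
    return best


def _chain_sequence(model: AtomicModel, chain: str) -> str:
    res = model.chain_residues(chain)
    return refdata.one_letter_sequence(list(res["resname"]))


def _type_histone_chains(model: AtomicModel, chains: list[str],
                         references: dict[str, str], threshold: float,
                         tie_tol: float) -> dict[str, str]:
    assignment = {}
    for chain in chains:
        seq = _chain_sequence(model, chain)
        scores = sorted(((_ungapped_identity(seq, ref), ht)
                         for ht, ref in references.items()), reverse=True)
        (s1, t1), (s2, t2) = scores[0], scores[1]
        if s1 < threshold:
            continue
        if s1 - s2 < tie_tol:
            raise AmbiguousTypingError(
                f"chain {chain}: ambiguous histone type ({t1}:{s1:.2f} vs {t2}:{s2:.2f})")
        assignment[chain] = t1
    return assignment


def _chain_com(model: AtomicModel, chain: str) -> np.ndarray:
    sub = model.atoms[model.atoms["chain"] == chain]
    return sub[["x", "y", "z"]].to_numpy(float).mean(axis=0)


def identify_components(model: AtomicModel,
                        references: dict[str, str] | None = None,
                        identity_threshold: float = 0.40,
                        tie_tolerance: float = 0.05,
                        ncp_bp: int = 147) -> list[NCPModel]:
    """Split an atomic model into nucleosome core particles.

    Protein chains of histone-like length (60-180 aa) are typed against the
    reference sequences; a complete particle requires two copies of each of
    H3, H4, H2A and H2B.  When several octamers share the asymmetric unit
    the histone chains are clustered by centre of mass and each octamer is
    given the nearest DNA duplex (or, for a continuous duplex, the `ncp_bp`
    window whose base pairs lie closest to the octamer).
    """
    references = references or refdata.HISTONE_SEQUENCES
    protein, nucleic = [], []
    for chain in model.chains():
        res = model.chain_residues(chain)
        n_amino = sum(refdata.is_amino(r) for r in res["resname"])
        n_nuc = sum(refdata.is_nucleic(r) for r in res["resname"])
        if n_amino > max(10, n_nuc):
            protein.append(chain)
        elif n_nuc > 3:
            nucleic.append(chain)
    histone_like = [c for c in protein
                    if 60 <= len(model.chain_residues(c)) <= 180]
    if len(histone_like) < 8 or len(nucleic) < 2:
        raise IncompleteNCPError(
            f"need >=8 histone-like protein chains and >=2 nucleic chains, "
            f"found {len(histone_like)} and {len(nucleic)}")

    typed = _type_histone_chains(model, histone_like, references,
                                 identity_threshold, tie_tolerance)
    counts = {t: sum(1 for v in typed.values() if v == t)
              for t in refdata.HISTONE_TYPES}
    if any(c < 2 for c in counts.values()):
        raise IncompleteNCPError(f"incomplete NCP: histone copy counts {counts}")
    n_ncp = min(c // 2 for c in counts.values())
    if any(c != 2 * n_ncp for c in counts.values()):
        raise IncompleteNCPError(f"unbalanced histone copy counts {counts}")

    # group histone chains into octamers
    hchains = sorted(typed)
    if n_ncp == 1:
        groups = [hchains]
    else:
        coms = np.array([_chain_com(model, c) for c in hchains])
        labels = fcluster(linkage(pdist(coms), method="complete"),
                          n_ncp, criterion="maxclust")
        groups = [[c for c, l in zip(hchains, labels) if l == k]
                  for k in range(1, n_ncp + 1)]
        for g in groups:
            gc = {t: sum(1 for c in g if typed[c] == t) for t in refdata.HISTONE_TYPES}
            if any(v != 2 for v in gc.values()):
                raise IncompleteNCPError(
                    f"octamer clustering produced composition {gc}")
        groups.sort(key=lambda g: g[0])

    ncps = []
    for group in groups:
        octamer_com = np.mean([_chain_com(model, c) for c in group], axis=0)
        strand1, strand2 = _duplex_for_octamer(model, nucleic, octamer_com,
                                               n_ncp, ncp_bp)
        chain_types: dict[str, tuple[str, int]] = {}
        seen: dict[str, int] = {}
        for c in sorted(group):
            t = typed[c]
            chain_types[c] = (t, seen.get(t, 0))
            seen[t] = seen.get(t, 0) + 1
        keep = set(group) | {r[0] for r in strand1} | {r[0] for r in strand2}
        sub = model.atoms[model.atoms["chain"].isin(keep)].copy()
        # for window selections restrict DNA atoms to the selected residues
        sel = {(c, r) for c, r, _ in strand1} | {(c, r) for c, r, _ in strand2}
        dna_mask = sub["chain"].isin({r[0] for r in strand1} | {r[0] for r in strand2})
        in_sel = np.array([(c, r) in sel
                           for c, r in zip(sub["chain"], sub["resseq"])])
        sub = sub[~dna_mask | in_sel].reset_index(drop=True)
        ncps.append(NCPModel(atoms=sub, chain_types=chain_types,
                             dna_strands=(strand1, strand2), source=model))
    return ncps


def _duplex_for_octamer(model, nucleic, octamer_com, n_ncp, ncp_bp):
    """Pick (strand1, strand2) residue lists for one octamer."""
    def residues(chain):
        res = model.chain_residues(chain)
        return [(chain, int(r.resseq), str(r.resname)) for r in res.itertuples()
                if refdata.is_nucleic(r.resname)]

    if len(nucleic) == 2 * n_ncp and n_ncp > 1:
        # one duplex per octamer: take the two nearest chains
        order = sorted(nucleic, key=lambda c: float(
            np.linalg.norm(_chain_com(model, c) - octamer_com)))
        pick = sorted(order[:2])
        return residues(pick[0]), residues(pick[1])
    # single shared duplex (possibly longer than one NCP)
    s1, s2 = (residues(c) for c in sorted(nucleic[:2]))
    if len(s1) != len(s2):
        raise IncompleteNCPError(
            f"DNA strands have different lengths ({len(s1)} vs {len(s2)})")
    n = len(s1)
    if n <= ncp_bp + 1 or n_ncp == 1 and n <= ncp_bp + 4:
        return s1, s2
    # sliding window of ncp_bp pairs closest to the octamer
    proxies = np.empty((n, 3))
    for i in range(n):
        r1, r2 = s1[i], s2[n - 1 - i]
        at = model.atoms[((model.atoms["chain"] == r1[0]) & (model.atoms["resseq"] == r1[1])) |
                         ((model.atoms["chain"] == r2[0]) & (model.atoms["resseq"] == r2[1]))]
        proxies[i] = at[["x", "y", "z"]].to_numpy(float).mean(axis=0)
    d = np.linalg.norm(proxies - octamer_com, axis=1)
    sums = np.convolve(d, np.ones(ncp_bp), mode="valid")
    start = int(np.argmin(sums))
    return s1[start:start + ncp_bp], s2[n - start - ncp_bp:n - start]


# --------------------------------------------------------------------------
# domains


def assign_domains(ncp: NCPModel, tails: TailTable | None = None,
                   strict: bool = True) -> NCPModel:
    """Flag every histone residue as tail or globular according to the table."""
    tails = tails or TailTable.default()
    domains: dict[tuple[str, int], str] = {}
    model = ncp.source
    for chain, (htype, _) in ncp.chain_types.items():
        res = ncp.atoms[ncp.atoms["chain"] == chain].drop_duplicates(subset="resseq")
        resseqs = [int(r) for r in res["resseq"]]
        if strict:
            top = max(resseqs)
            for a, b in tails.ranges.get(htype, []):
                if a > top:
                    raise DomainTableError(
                        f"tail range {a}-{b} for {htype} lies beyond chain "
                        f"{chain} (last residue {top})")
        for r in resseqs:
            domains[(chain, r)] = "tail" if tails.is_tail(htype, r) else "globular"
    # DNA residues carry no domain flag
    ncp.domains = domains
    return ncp


# --------------------------------------------------------------------------
# base pairing


def _base_centroid(atoms: pd.DataFrame, resname: str) -> np.ndarray | None:
    parent = refdata.NUCLEOTIDE_PARENT.get(resname.upper())
    names = refdata.BASE_HEAVY_ATOMS.get(parent, [])
    sub = atoms[atoms["name"].isin(names)]
    if len(sub) == 0:
        return None
    return sub[["x", "y", "z"]].to_numpy(float).mean(axis=0)


def pair_bases(ncp: NCPModel, c1_distance: float = 10.5,
               c1_tolerance: float = 2.5, max_fail_fraction: float = 0.05) -> NCPModel:
    """Pair the two DNA strands antiparallel and assign centred bp indices.

    Base i of strand 1 pairs with base N+1-i of strand 2.  The register is
    validated by the C1'-C1' distance where both sugar atoms are present;
    centred indices run ...-1, 0, +1... for odd pair counts and half-integer
    ...-0.5, +0.5... for even counts.  The bp centroid is the mean of the
    base heavy atoms of both nucleotides (missing bases give a NaN centroid
    to be interpolated by the axis estimator).
    """
    s1, s2 = ncp.dna_strands
    if len(s1) != len(s2):
        raise RegisterError(f"strand lengths differ: {len(s1)} vs {len(s2)}")
    n = len(s1)
    offset = (n + 1) / 2.0
    pairs: list[BasePair] = []
    failing: list[float] = []
    checked = 0
    for i in range(1, n + 1):
        r1, r2 = s1[i - 1], s2[n - i]
        idx = i - offset
        a1 = ncp.atoms[(ncp.atoms["chain"] == r1[0]) & (ncp.atoms["resseq"] == r1[1])]
        a2 = ncp.atoms[(ncp.atoms["chain"] == r2[0]) & (ncp.atoms["resseq"] == r2[1])]
        c1a = a1[a1["name"].isin(["C1'", "C1*"])]
        c1b = a2[a2["name"].isin(["C1'", "C1*"])]
        if len(c1a) and len(c1b):
            checked += 1
            d = float(np.linalg.norm(c1a[["x", "y", "z"]].to_numpy(float)[0]
                                     - c1b[["x", "y", "z"]].to_numpy(float)[0]))
            if abs(d - c1_distance) > c1_tolerance:
                failing.append(idx)
        g1 = _base_centroid(a1, r1[2])
        g2 = _base_centroid(a2, r2[2])
        if g1 is None and g2 is None:
            centroid = np.full(3, np.nan)
        elif g1 is None or g2 is None:
            centroid = g1 if g2 is None else g2
        else:
            centroid = 0.5 * (g1 + g2)
        pairs.append(BasePair(index=idx, res1=r1, res2=r2, centroid=centroid))
    if checked and len(failing) / checked > max_fail_fraction:
        raise RegisterError(
            f"base-pair register error: {len(failing)}/{checked} pairs outside "
            f"{c1_distance}+/-{c1_tolerance} A C1'-C1'; failing indices {failing[:10]}")
    ncp.base_pairs = pairs
    return ncp


# --------------------------------------------------------------------------
# crystal expansion


@dataclass
class NCPPlacement:
    """A rigid crystal-symmetry image of one particle."""

    ncp: object                      # NCPModel or any frame-bearing record
    rotation: np.ndarray             # Cartesian 3x3, det +1
    translation: np.ndarray          # Cartesian, Angstrom
    op_id: int
    lattice: tuple[int, int, int]
    com: np.ndarray                  # transformed gHO COM
    is_identity: bool = False

    def transform_points(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def expand_crystal(ncp, max_com_distance: float = 100.0,
                   com: np.ndarray | None = None) -> list[NCPPlacement]:
    """Generate symmetry/lattice images whose gHO COM is within reach.

    Every space-group operator is combined with lattice translations in
    {-1,0,1}^3; an image is kept when its transformed centre lies within
    `max_com_distance` of the reference centre.  The identity placement is
    first in the returned list and flagged, so `result[1:]` is the
    neighbour list.
    """
    source = getattr(ncp, "source", None) or ncp
    cell = getattr(source, "cell", None)
    ops = getattr(source, "operations", None)
    if cell is None or not ops:
        raise ValueError("model carries no unit cell; crystal expansion needs "
                         "CRYST1/symmetry records (analyse the single model instead)")
    if com is None:
        com = ncp.globular_com()
    com = np.asarray(com, float)
    M = _orthogonalization_matrix(tuple(cell))
    Minv = np.linalg.inv(M)

    placements = [NCPPlacement(ncp=ncp, rotation=np.eye(3), translation=np.zeros(3),
                               op_id=0, lattice=(0, 0, 0), com=com, is_identity=True)]
    neighbours = []
    for op_id, (R_f, t_f) in enumerate(ops):
        R = M @ R_f @ Minv
        det = np.linalg.det(R)
        if det < 0:
            raise ValueError(f"operator {op_id} is improper (det={det:.3f})")
        for na in (-1, 0, 1):
            for nb in (-1, 0, 1):
                for nc in (-1, 0, 1):
                    t = M @ (t_f + np.array([na, nb, nc], float))
                    if op_id == 0 and na == nb == nc == 0:
                        continue
                    new_com = R @ com + t
                    if np.linalg.norm(new_com - com) <= max_com_distance:
                        neighbours.append(NCPPlacement(
                            ncp=ncp, rotation=R, translation=t, op_id=op_id,
                            lattice=(na, nb, nc), com=new_com))
    neighbours.sort(key=lambda p: (float(np.linalg.norm(p.com - com)),
                                   p.op_id, p.lattice))
    return placements + neighbours
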