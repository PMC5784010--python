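"""Ionic-contact detection, charge budgets and the acidic patch.

An ion pair is counted when the marker atoms come within a cutoff
(default 7.5 A): NZ of Lys and CZ of Arg on the basic side; DNA
phosphorus, CD of Glu and CG of Asp on the acidic side.  Contacts are
reduced to unique (basic residue, partner) pairs at the minimum atom
distance, the convention under which the published per-residue counts
are quoted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import refdata

__all__ = ["ContactCriterion", "Contact", "ContactSet", "ChargeBudget",
           "ion_contacts", "charge_budget", "acidic_patch_residues"]


@dataclass
class ContactCriterion:
    cutoff: float = 7.5
    basic_atoms: dict[str, str] = field(
        default_factory=lambda: dict(refdata.BASIC_ATOMS))
    acidic_atoms: dict[str, str] = field(
        default_factory=lambda: dict(refdata.ACIDIC_ATOMS))
    phosphorus: str = refdata.DNA_PHOSPHORUS

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class Contact:
    basic: tuple[str, int, str]       # (chain, resseq, resname)
    partner: tuple[str, int, str]
    partner_kind: str                 # "P" | "carboxylate"
    distance: float
    inter_ncp: bool = False


@dataclass
class ContactSet:
    contacts: list[Contact]
    skipped_residues: int = 0

    def count(self, resname: str | None = None,
              partner_kind: str | None = None,
              inter_ncp: bool | None = None) -> int:
        n = 0
        for c in self.contacts:
            if resname is not None and c.basic[2] != resname:
                continue
            if partner_kind is not None and c.partner_kind != partner_kind:
                continue
            if inter_ncp is not None and c.inter_ncp != inter_ncp:
                continue
            n += 1
        return n

    def summary(self) -> dict[str, int]:
        return {
            "LYS-P": self.count("LYS", "P"),
            "ARG-P": self.count("ARG", "P"),
            "LYS-carboxylate": self.count("LYS", "carboxylate"),
            "ARG-carboxylate": self.count("ARG", "carboxylate"),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [(f"{c.basic[0]}/{c.basic[1]}/{c.basic[2]}",
                 f"{c.partner[0]}/{c.partner[1]}/{c.partner[2]}",
                 c.partner_kind, c.distance, c.inter_ncp)
                for c in self.contacts]
        return pd.DataFrame(rows, columns=["basic", "partner", "kind",
                                           "distance", "inter_ncp"])


def _marker_atoms(ncp, placement=None, domain: str | None = None,
                  criterion: ContactCriterion | None = None):
    """(basic, acidic) marker-atom tables for one placement of one NCP."""
    crit = criterion or ContactCriterion()
    atoms = ncp.atoms
    histone = atoms["chain"].isin(ncp.chain_types)
    rows_b, rows_a, skipped = [], [], 0
    hist = atoms[histone]
    for (chain, resseq), res in hist.groupby(["chain", "resseq"], sort=True):
        resname = str(res["resname"].iloc[0]).upper()
        if domain is not None and ncp.domains is not None:
            if ncp.domains.get((chain, resseq)) != domain:
                continue
        target = crit.basic_atoms.get(resname) or crit.acidic_atoms.get(resname)
        if target is None:
            continue
        hit = res[res["name"] == target]
        if len(hit) == 0:
            skipped += 1
            continue
        xyz = hit[["x", "y", "z"]].to_numpy(float)[0]
        rec = ((chain, int(resseq), resname), xyz)
        if resname in crit.basic_atoms:
            rows_b.append(rec)
        else:
            rows_a.append(rec)
    # DNA phosphates are acceptors
    dna = atoms[~histone & atoms["resname"].str.upper().isin(
        refdata.NUCLEOTIDE_PARENT)]
    for (chain, resseq), res in dna.groupby(["chain", "resseq"], sort=True):
        hit = res[res["name"] == crit.phosphorus]
        if len(hit):
            rows_a.append((((chain), int(resseq), "P"),
                           hit[["x", "y", "z"]].to_numpy(float)[0]))
    if placement is not None:
        rows_b = [(k, placement.transform_points(x[None, :])[0]) for k, x in rows_b]
        rows_a = [(k, placement.transform_points(x[None, :])[0]) for k, x in rows_a]
    return rows_b, rows_a, skipped


def ion_contacts(ncp, other=None, criterion: ContactCriterion | None = None,
                 domain: str | None = None, other_placement=None) -> ContactSet:
    """All unique basic-residue/acceptor ion pairs under the cutoff.

    With `other=None` the contacts are intra-NCP.  Passing a second model
    (optionally rigidly placed via `other_placement`) adds its acceptors
    and basic residues and flags cross-particle pairs as inter-NCP.
    `domain="globular"` restricts histone residues to the structured core.
    """
    crit = criterion or ContactCriterion()
    basic1, acidic1, sk1 = _marker_atoms(ncp, None, domain, crit)
    groups = [(basic1, acidic1, 0)]
    skipped = sk1
    if other is not None:
        basic2, acidic2, sk2 = _marker_atoms(other, other_placement, domain, crit)
        groups.append((basic2, acidic2, 1))
        skipped += sk2
    if skipped:
        warnings.warn(f"{skipped} charged residues missing their marker atom",
                      stacklevel=2)

    contacts: list[Contact] = []
    for gi, (basic, _, _) in enumerate(groups):
        if not basic:
            continue
        bxyz = np.array([x for _, x in basic])
        for gj, (_, acidic, _) in enumerate(groups):
            if not acidic:
                continue
            axyz = np.array([x for _, x in acidic])
            tree = cKDTree(axyz)
            hits = tree.query_ball_point(bxyz, crit.cutoff)
            for bi, neigh in enumerate(hits):
                for ai in neigh:
                    d = float(np.linalg.norm(bxyz[bi] - axyz[ai]))
                    bkey, akey = basic[bi][0], acidic[ai][0]
                    if bkey == akey:
                        continue
                    contacts.append(Contact(
                        basic=bkey, partner=akey,
                        partner_kind="P" if akey[2] == "P" else "carboxylate",
                        distance=d, inter_ncp=(gi != gj)))
    # unique (residue, partner) with minimum distance
    best: dict[tuple, Contact] = {}
    for c in contacts:
        key = (c.basic, c.partner, c.inter_ncp)
        if key not in best or c.distance < best[key].distance:
            best[key] = c
    ordered = sorted(best.values(),
                     key=lambda c: (c.inter_ncp, c.basic, c.partner))
    return ContactSet(contacts=ordered, skipped_residues=skipped)


@dataclass
class ChargeBudget:
    """Unit-charge totals: +1 Lys/Arg, -1 Glu/Asp, -1 per phosphate."""

    dna: int
    gho: int
    tails: int

    @property
    def total(self) -> int:
        return self.dna + self.gho + self.tails

    def to_dict(self) -> dict:
        return {"dna": self.dna, "gho": self.gho, "tails": self.tails,
                "total": self.total}


def charge_budget(ncp, count_terminal_phosphates: bool = True) -> ChargeBudget:
    """Charge bookkeeping of one NCP under the coarse-grained convention.

    DNA charge is minus the number of phosphate groups; by default that is
    the number of P atoms present in the coordinates (5'-terminal
    phosphates, when resolved, included).  With
    `count_terminal_phosphates=False` the 5'-terminal nucleotide of each
    strand is not counted, i.e. 2(N-1) phosphates for an N-bp duplex.
    """
    histone_chains = set(ncp.chain_types)
    atoms = ncp.atoms
    dna_atoms = atoms[~atoms["chain"].isin(histone_chains)]
    n_p = int((dna_atoms["name"] == refdata.DNA_PHOSPHORUS).sum())
    if not count_terminal_phosphates:
        for strand in ncp.dna_strands:
            if not strand:
                continue
            chain, resseq, _ = strand[0]
            sub = dna_atoms[(dna_atoms["chain"] == chain)
                            & (dna_atoms["resseq"] == resseq)
                            & (dna_atoms["name"] == refdata.DNA_PHOSPHORUS)]
            n_p -= len(sub)
    gho = tails = 0
    hist = atoms[atoms["chain"].isin(histone_chains)]
    for (chain, resseq), res in hist.groupby(["chain", "resseq"]):
        q = refdata.RESIDUE_CHARGES.get(str(res["resname"].iloc[0]).upper(), 0)
        if q == 0:
            continue
        dom = "globular" if ncp.domains is None else ncp.domains[(chain, int(resseq))]
        if dom == "tail":
            tails += q
        else:
            gho += q
    return ChargeBudget(dna=-n_p, gho=gho, tails=tails)


def acidic_patch_residues(ncp, patch=None) -> tuple[list, list]:
    """Locate the acidic-patch residues on each NCP face.

    Returns (present, missing) lists of (chain, resseq, resname); a
    residue is missing when absent from the model or when the residue at
    that number is not the expected Glu/Asp (renamed or variant histones).
    """
    patch = patch or refdata.ACIDIC_PATCH
    present, missing = [], []
    for htype, resname, resseq in patch:
        chains = ncp.histone_chains(htype)
        if not chains:
            warnings.warn(f"no {htype} chains in model; acidic patch "
                          "incomplete", stacklevel=2)
        for chain in chains:
            sub = ncp.atoms[(ncp.atoms["chain"] == chain)
                            & (ncp.atoms["resseq"] == resseq)]
            if len(sub) and str(sub["resname"].iloc[0]).upper() == resname:
                present.append((chain, resseq, resname))
            else:
                missing.append((chain, resseq, resname))
    return present, missing
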