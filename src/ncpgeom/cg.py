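"""Coarse-grained NCP bead model: topology, charges and frame analysis.

The DNA is mapped at 5 beads per two base pairs: one neutral core bead
for the four nucleosides of a 2-bp unit plus four phosphate beads at -1 e
each; 74 units model 148 bp (one terminal bp is duplicated when the
source has 147).  Histones get one bead per residue at the C-alpha
position, +1 e for Lys/Arg and -1 e for Glu/Asp, with the globular core
held by an elastic network and the ten tails as linear bead strings.
Simulation itself is out of scope; this module covers building the model
and analysing bead geometry with the same NCP-frame machinery used for
atomic structures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .axis import DuplexAxis
from .frame import NCPFrame, build_frame
from .superhelix import fit_superhelix
from . import refdata

__all__ = ["CGBead", "CGModel", "CGTrajectory", "build_cg_ncp", "cg_frame",
           "pair_distance_distribution", "read_xyz_trajectory"]

BP_PER_UNIT = 2
BEADS_PER_UNIT = 5
N_UNITS = 74


@dataclass
class CGBead:
    bead_id: int
    group: str            # dna-core | dna-phosphate | histone-aa
    label: tuple          # unit/bp mapping or (chain, resseq, resname)
    charge: int
    xyz: np.ndarray
    domain: str | None = None    # tail | globular for histone beads


@dataclass
class CGModel:
    beads: list[CGBead]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    elastic_pairs: list[tuple[int, int]] = field(default_factory=list)
    duplicated_terminal_bp: bool = False

    def coords(self, group: str | None = None) -> np.ndarray:
        return np.array([b.xyz for b in self.beads
                         if group is None or b.group == group])

    def select(self, group: str) -> list[CGBead]:
        return [b for b in self.beads if b.group == group]

    @property
    def total_charge(self) -> int:
        return sum(b.charge for b in self.beads)

    def charge_by_group(self) -> dict[str, int]:
        out = {"dna": 0, "gho": 0, "tails": 0}
        for b in self.beads:
            if b.group.startswith("dna"):
                out["dna"] += b.charge
            elif b.domain == "tail":
                out["tails"] += b.charge
            else:
                out["gho"] += b.charge
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beads": [{"id": b.bead_id, "group": b.group,
                       "label": list(b.label), "charge": b.charge,
                       "xyz": b.xyz.tolist(), "domain": b.domain}
                      for b in self.beads],
            "bonds": self.bonds, "angles": self.angles,
            "elastic_pairs": self.elastic_pairs,
            "duplicated_terminal_bp": self.duplicated_terminal_bp,
            "total_charge": self.total_charge,
        }
        Path(path).write_text(json.dumps(payload))


def _phosphate_position(ncp, res: tuple[str, int, str], fallback: np.ndarray) -> np.ndarray:
    chain, resseq, _ = res
    sub = ncp.atoms[(ncp.atoms["chain"] == chain) & (ncp.atoms["resseq"] == resseq)]
    p = sub[sub["name"] == refdata.DNA_PHOSPHORUS]
    if len(p):
        return p[["x", "y", "z"]].to_numpy(float)[0]
    c1 = sub[sub["name"].isin(["C1'", "C1*"])]
    if len(c1):
        return c1[["x", "y", "z"]].to_numpy(float)[0]
    return fallback


def build_cg_ncp(ncp, elastic_cutoff: float = 10.0) -> CGModel:
    """Map an atomic NCP onto the 1350-bead-class coarse-grained model.

    Requires paired base pairs and assigned domains, and complete tail
    coordinates (one C-alpha per residue).  A 147-bp source duplicates its
    last bp to fill the 74th 2-bp unit (flagged on the model).
    """
    if ncp.base_pairs is None or ncp.domains is None:
        raise ValueError("run pair_bases and assign_domains before CG build")
    bps = sorted(ncp.base_pairs, key=lambda b: b.index)
    duplicated = False
    if len(bps) == 2 * N_UNITS - 1:
        bps = bps + [bps[-1]]
        duplicated = True
    if len(bps) != 2 * N_UNITS:
        raise ValueError(f"expected {2*N_UNITS-1} or {2*N_UNITS} bp, got {len(bps)}")

    beads: list[CGBead] = []
    bonds, angles, core_ids = [], [], []
    bid = 0
    for u in range(N_UNITS):
        bp1, bp2 = bps[2 * u], bps[2 * u + 1]
        core_xyz = 0.5 * (bp1.centroid + bp2.centroid)
        mean_index = 0.5 * (bp1.index + bp2.index)
        core = CGBead(bid, "dna-core", ("unit", u + 1, mean_index), 0, core_xyz)
        beads.append(core)
        core_ids.append(bid)
        bid += 1
        for res in (bp1.res1, bp1.res2, bp2.res1, bp2.res2):
            xyz = _phosphate_position(ncp, res, core_xyz)
            beads.append(CGBead(bid, "dna-phosphate", ("unit", u + 1, *res),
                                -1, xyz))
            bonds.append((core.bead_id, bid))
            bid += 1
    for i, j in zip(core_ids, core_ids[1:]):
        bonds.append((i, j))
    for i, j, k in zip(core_ids, core_ids[1:], core_ids[2:]):
        angles.append((i, j, k))

    missing_ca: dict[str, int] = {}
    for chain in ncp.histone_chains():
        sub = ncp.atoms[ncp.atoms["chain"] == chain]
        expected = {rs for (c, rs) in ncp.domains if c == chain}
        seen = set(int(r) for r in sub["resseq"].unique())
        if expected - seen:
            missing_ca[chain] = missing_ca.get(chain, 0) + len(expected - seen)
        chain_ids = []
        for resseq, res in sub.groupby("resseq", sort=True):
            resname = str(res["resname"].iloc[0]).upper()
            ca = res[res["name"] == "CA"]
            if len(ca) == 0:
                missing_ca[chain] = missing_ca.get(chain, 0) + 1
                continue
            xyz = ca[["x", "y", "z"]].to_numpy(float)[0]
            dom = ncp.domains[(chain, int(resseq))]
            beads.append(CGBead(bid, "histone-aa", (chain, int(resseq), resname),
                                refdata.RESIDUE_CHARGES.get(resname, 0),
                                xyz, domain=dom))
            chain_ids.append(bid)
            bid += 1
        for i, j in zip(chain_ids, chain_ids[1:]):
            bonds.append((i, j))
        for i, j, k in zip(chain_ids, chain_ids[1:], chain_ids[2:]):
            angles.append((i, j, k))
    if missing_ca:
        raise ValueError(
            "histone residues without C-alpha coordinates (unresolved tails?) "
            f"in chains {sorted(missing_ca)}: {missing_ca}")

    ghob = [b for b in beads if b.group == "histone-aa" and b.domain == "globular"]
    if ghob:
        xyz = np.array([b.xyz for b in ghob])
        tree = cKDTree(xyz)
        elastic = sorted((ghob[i].bead_id, ghob[j].bead_id)
                         for i, j in tree.query_pairs(elastic_cutoff))
    else:
        elastic = []
    return CGModel(beads=beads, bonds=bonds, angles=angles,
                   elastic_pairs=elastic, duplicated_terminal_bp=duplicated)


class _CGAsNCP:
    """Adapter exposing a CGModel through the NCP-frame duck type."""

    def __init__(self, cg: CGModel):
        self.cg = cg
        cores = cg.select("dna-core")
        idx = np.array([float(b.label[2]) for b in cores])
        pts = np.array([b.xyz for b in cores])
        entries = list(zip(idx, pts))
        # the 2-bp units straddle the dyad, so interpolate the core-bead
        # curve at centred index 0 to recover the central-bp position
        if not np.any(np.abs(idx) < 1e-9):
            below = np.where(idx < 0)[0]
            above = np.where(idx > 0)[0]
            if len(below) and len(above):
                i, j = below[np.argmax(idx[below])], above[np.argmin(idx[above])]
                w = -idx[i] / (idx[j] - idx[i])
                entries.append((0.0, (1 - w) * pts[i] + w * pts[j]))
        self.base_pairs = [
            type("BP", (), {"index": float(i), "centroid": p})()
            for i, p in sorted(entries, key=lambda e: e[0])]

    def globular_com(self, mass_weighted: bool = True) -> np.ndarray:
        ghob = [b for b in self.cg.select("histone-aa") if b.domain == "globular"]
        if not ghob:
            raise ValueError("no globular histone beads")
        return np.array([b.xyz for b in ghob]).mean(axis=0)


def cg_frame(cg: CGModel, use_superhelix: bool = True) -> NCPFrame:
    """NCP frame of a bead model, built like the atomic one.

    The DNA-core beads play the role of bp centroids (each carrying the
    centred index of its 2-bp unit); the origin is the mean of the
    globular histone beads; the quarter-turn units are selected on the
    superhelix fitted to the core-bead curve.
    """
    adapter = _CGAsNCP(cg)
    sh = None
    if use_superhelix:
        pts = np.array([bp.centroid for bp in adapter.base_pairs])
        idx = np.array([bp.index for bp in adapter.base_pairs])
        sh = fit_superhelix(DuplexAxis(idx, pts), window=65)
    return build_frame(adapter, sh=sh)


# --------------------------------------------------------------------------
# trajectories


@dataclass
class CGTrajectory:
    """Frames of bead coordinates plus per-bead (ncp id, group) metadata."""

    frames: np.ndarray            # (n_frames, n_beads, 3)
    ncp_ids: np.ndarray           # (n_beads,) which particle each bead belongs to
    groups: list[str]             # per-bead group labels

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        self.ncp_ids = np.asarray(self.ncp_ids)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.ncp_ids):
            raise ValueError("bead count must be constant across frames")

    def ncp_coms(self, frame_index: int) -> np.ndarray:
        """gHO-bead COM of every particle in one frame."""
        xyz = self.frames[frame_index]
        out = []
        for nid in np.unique(self.ncp_ids):
            mask = (self.ncp_ids == nid) & np.array(
                [g == "gho" or g == "histone-aa" for g in self.groups])
            if not mask.any():
                mask = self.ncp_ids == nid
            out.append(xyz[mask].mean(axis=0))
        return np.array(out)


def read_xyz_trajectory(xyz_path: str | Path, meta_path: str | Path) -> CGTrajectory:
    """Plain per-frame xyz file plus a JSON sidecar with bead metadata.

    The sidecar maps bead order to {"ncp": int, "group": str}.
    """
    meta = json.loads(Path(meta_path).read_text())
    ncp_ids = np.array([m["ncp"] for m in meta])
    groups = [m["group"] for m in meta]
    frames = []
    lines = Path(xyz_path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return CGTrajectory(frames=np.array(frames), ncp_ids=ncp_ids, groups=groups)


def pair_distance_distribution(traj: CGTrajectory, bin_width: float = 1.0,
                               max_distance: float = 200.0):
    """Pooled histogram of NCP-NCP COM distances over frames and pairs.

    Returns (bin_edges, counts).
    """
    n_ncp = len(np.unique(traj.ncp_ids))
    if n_ncp < 2:
        raise ValueError("need at least two particles per frame")
    dists = []
    for f in range(traj.frames.shape[0]):
        coms = traj.ncp_coms(f)
        for i in range(len(coms)):
            for j in range(i + 1, len(coms)):
                dists.append(float(np.linalg.norm(coms[i] - coms[j])))
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    counts, edges = np.histogram(dists, bins=edges)
    return edges, counts
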