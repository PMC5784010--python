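"""Compact per-particle geometry records.

A record holds exactly what the downstream geometry pipeline needs --
centred bp indices with base-centroid positions, the gHO centre of mass,
and the unit cell with its space group -- so a full survey row (axis,
superhelix fit, symmetry frame, crystal stacking pairs) can be recomputed
without the original coordinates.  Records are written as small JSON
files by :meth:`GeometryRecord.from_ncp` / :meth:`GeometryRecord.save`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .axis import DuplexAxis
from .structure import _spacegroup_operations

__all__ = ["GeometryRecord"]


@dataclass
class GeometryRecord:
    record_id: str
    bp_indices: np.ndarray
    bp_centroids: np.ndarray
    gho_com_xyz: np.ndarray
    cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str | None = None

    # ---- duck type used by axis/frame/stacking ---------------------------

    @property
    def base_pairs(self):
        return [type("BP", (), {"index": float(i), "centroid": c})()
                for i, c in zip(self.bp_indices, self.bp_centroids)]

    def globular_com(self, mass_weighted: bool = True) -> np.ndarray:
        return np.asarray(self.gho_com_xyz, float)

    @property
    def operations(self):
        if self.spacegroup is None:
            return []
        return _spacegroup_operations(self.spacegroup)

    @property
    def source(self):
        return self if self.cell is not None else None

    def axis_input(self) -> DuplexAxis:
        return DuplexAxis(self.bp_indices, self.bp_centroids,
                          provenance="estimated")

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_ncp(cls, ncp, record_id: str) -> "GeometryRecord":
        idx = np.array([bp.index for bp in ncp.base_pairs], float)
        cen = np.array([bp.centroid for bp in ncp.base_pairs], float)
        src = ncp.source
        return cls(record_id=record_id, bp_indices=idx, bp_centroids=cen,
                   gho_com_xyz=ncp.globular_com(),
                   cell=None if src is None else src.cell,
                   spacegroup=None if src is None else src.spacegroup)

    def save(self, path: str | Path) -> None:
        payload = {
            "id": self.record_id,
            "bp_index": self.bp_indices.tolist(),
            "bp_centroid": np.round(self.bp_centroids, 4).tolist(),
            "gho_com": np.round(np.asarray(self.gho_com_xyz, float), 4).tolist(),
            "cell": None if self.cell is None else list(self.cell),
            "spacegroup": self.spacegroup,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GeometryRecord":
        d = json.loads(Path(path).read_text())
        return cls(record_id=d["id"],
                   bp_indices=np.array(d["bp_index"], float),
                   bp_centroids=np.array(d["bp_centroid"], float),
                   gho_com_xyz=np.array(d["gho_com"], float),
                   cell=None if d.get("cell") is None else tuple(d["cell"]),
                   spacegroup=d.get("spacegroup"))
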