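"""Duplex-axis estimation and per-step curvature/length series.

The nucleosomal-DNA axis is approximated by a running mean of base-pair
base-centroid positions.  For the superhelix-scale geometry of the
nucleosome (radius ~40 A) this smoothed centroid curve tracks a true
helical-axis construction to within a fraction of an Angstrom, which is
the tolerance quoted for all downstream comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DuplexAxis", "StepSeries", "compute_axis",
           "curvature_per_step", "length_per_step"]


@dataclass
class DuplexAxis:
    """Ordered per-bp axis points carrying centred bp indices."""

    indices: np.ndarray          # centred bp indices, strictly increasing
    points: np.ndarray           # (n, 3) Angstrom
    provenance: str = "estimated"    # or "synthetic-exact"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, float)
        self.points = np.asarray(self.points, float)
        if len(self.indices) != len(self.points):
            raise ValueError("index/point count mismatch")

    def __len__(self) -> int:
        return len(self.indices)

    def window(self, half_width: float) -> "DuplexAxis":
        """Sub-axis with |index| <= half_width."""
        m = np.abs(self.indices) <= half_width + 1e-9
        return DuplexAxis(self.indices[m], self.points[m], self.provenance)

    def central(self, count: int) -> "DuplexAxis":
        """The `count` central points (all points, flagged, if fewer exist)."""
        if len(self) <= count:
            return self
        order = np.argsort(np.abs(self.indices), kind="stable")[:count]
        keep = np.sort(order)
        return DuplexAxis(self.indices[keep], self.points[keep], self.provenance)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": self.indices,
                             "x": self.points[:, 0],
                             "y": self.points[:, 1],
                             "z": self.points[:, 2]})


@dataclass
class StepSeries:
    """Per-bp-step values keyed by the step midpoint index."""

    midpoints: np.ndarray
    values: np.ndarray
    kind: str                    # "curvature" (deg/step) or "length" (A/step)
    window: str = "custom"       # inner-129 | outer-ends | custom

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": self.midpoints, "value": self.values})


def compute_axis(ncp, smoothing_window: int = 3,
                 max_missing_fraction: float = 0.10) -> DuplexAxis:
    """Estimate one axis point per base pair by window-averaging centroids.

    `smoothing_window` must be odd; end points use shrunken (one-sided)
    windows so the point count always equals the bp count.  Base pairs with
    no base atoms are linearly interpolated from their neighbours (with a
    warning); more than `max_missing_fraction` missing is an error.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    base_pairs = ncp.base_pairs
    if not base_pairs:
        raise ValueError("base pairs not assigned")
    idx = np.array([bp.index for bp in base_pairs], float)
    pts = np.array([bp.centroid for bp in base_pairs], float)

    missing = ~np.isfinite(pts).all(axis=1)
    if missing.any():
        frac = missing.mean()
        if frac > max_missing_fraction:
            raise ValueError(f"{frac:.0%} of base pairs lack base atoms")
        warnings.warn(f"interpolating {int(missing.sum())} bp centroids "
                      "missing base atoms", stacklevel=2)
        good = ~missing
        for k in range(3):
            pts[missing, k] = np.interp(idx[missing], idx[good], pts[good, k])

    half = smoothing_window // 2
    smoothed = np.empty_like(pts)
    n = len(pts)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        smoothed[i] = pts[lo:hi].mean(axis=0)
    return DuplexAxis(idx, smoothed, provenance="estimated")


def _select(axis: DuplexAxis, index_range) -> DuplexAxis:
    if index_range is None:
        return axis
    lo, hi = index_range
    m = (axis.indices >= lo - 1e-9) & (axis.indices <= hi + 1e-9)
    return DuplexAxis(axis.indices[m], axis.points[m], axis.provenance)


def curvature_per_step(axis: DuplexAxis, index_range=None,
                       window_label: str = "custom") -> StepSeries:
    """Turning angle (degrees) between successive segment vectors.

    The curvature at step i is the angle between p_i -> p_{i+1} and
    p_{i+1} -> p_{i+2}; for an ideal helix with per-step turn dtheta,
    radius r and reduced pitch c = p/2pi this equals
    arccos[(r^2 cos dtheta + c^2) / (r^2 + c^2)].
    """
    sel = _select(axis, index_range)
    if len(sel) < 3:
        raise ValueError("need at least 3 axis points for curvature")
    seg = np.diff(sel.points, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("degenerate zero-length axis segment")
    u = seg / norms[:, None]
    dots = np.clip((u[:-1] * u[1:]).sum(axis=1), -1.0, 1.0)
    crosses = np.linalg.norm(np.cross(u[:-1], u[1:]), axis=1)
    ang = np.degrees(np.arctan2(crosses, dots))
    mid = sel.indices[1:-1]
    return StepSeries(mid, ang, kind="curvature", window=window_label)


def length_per_step(axis: DuplexAxis, index_range=None,
                    window_label: str = "custom") -> StepSeries:
    """Distance |p_{i+1} - p_i| in Angstrom for each bp step."""
    sel = _select(axis, index_range)
    if len(sel) < 2:
        raise ValueError("need at least 2 axis points for step lengths")
    d = np.linalg.norm(np.diff(sel.points, axis=0), axis=1)
    mid = 0.5 * (sel.indices[:-1] + sel.indices[1:])
    return StepSeries(mid, d, kind="length", window=window_label)


def helix_step_curvature(radius: float, pitch: float, step_deg: float,
                         chord: bool = True) -> float:
    """Closed-form turning angle per step of an ideal helix, in degrees.

    With `chord=True` (matching the segment-vector definition used by
    :func:`curvature_per_step`) the chord between points at angular
    separation dtheta behaves like the tangent of a helix with effective
    radius r*sinc(dtheta/2), so the turning angle is
    arccos[(r_eff^2 cos dtheta + c^2) / (r_eff^2 + c^2)], c = p/2pi.
    `chord=False` gives the continuum tangent-turning form (same formula
    with r_eff = r), which the chord form approaches as dtheta -> 0.
    """
    c = pitch / (2.0 * np.pi)
    dtheta = np.radians(step_deg)
    r_eff = radius * (np.sinc(dtheta / (2.0 * np.pi)) if chord else 1.0)
    cosang = (r_eff**2 * np.cos(dtheta) + c**2) / (r_eff**2 + c**2)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
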