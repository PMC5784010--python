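"""The seven pairwise NCP-NCP parameters and crystal stacking pairs.

With NCP1's frame (origin, symmetry axis u1, oriented plane normal n1):

* dist  - COM-COM distance;
* rise  - distance from NCP2's origin to the NCP1 plane (signed value kept,
          magnitude reported, as only pairwise contacts are analysed);
* shift - in-plane distance of NCP2's origin projection;
* phi   - signed angle of that projection vs u1 (counterclockwise positive
          seen from +n1);
* delta - signed angle between u1 and the in-plane projection of u2
          ("symmetry-axes orientation");
* tilt  - plane-plane angle, folded to [0, 90];
* tilt direction - signed angle of the in-plane projection of n2 vs u1
          (n2 first sign-aligned with n1).

Head-to-tail stacking has delta near +/-180 degrees, head-to-head near 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .frame import NCPFrame, transform_frame
from .geometry import fold_angle_90, signed_angle_about, unit

__all__ = ["StackParams", "StackPair", "compute_stack_params",
           "classify_orientation", "find_stacking_pairs"]


@dataclass
class StackParams:
    dist: float
    rise: float              # |signed rise|
    rise_signed: float
    shift: float
    phi_deg: float
    delta_deg: float
    tilt_deg: float          # [0, 90]
    tilt_direction_deg: float
    orientation: str = "other"

    def as_tuple(self) -> tuple:
        return (self.dist, self.rise, self.shift, self.phi_deg,
                self.delta_deg, self.tilt_deg, self.tilt_direction_deg)


@dataclass
class StackPair:
    id1: int                 # placement indices
    id2: int
    params: StackParams      # NCP1 = placement id1 as reference
    reciprocal: StackParams  # NCP2 as reference

    @property
    def dist(self) -> float:
        return self.params.dist


def _signed_or_zero(a, b, axis) -> float:
    try:
        return signed_angle_about(a, b, axis)
    except ValueError:
        return 0.0


def compute_stack_params(frame1: NCPFrame, frame2: NCPFrame,
                         class_tolerance_deg: float = 30.0) -> StackParams:
    """The seven NCP-NCP parameters of frame2 relative to frame1."""
    u1, n1, v1 = frame1.u, frame1.normal, frame1.v
    d = frame2.origin - frame1.origin
    dist = float(np.linalg.norm(d))
    if dist < 1e-9:
        warnings.warn("coincident NCP origins; all stacking parameters zero",
                      stacklevel=2)
        return StackParams(0, 0, 0, 0, 0, 0, 0, 0, "other")
    rise_signed = float(np.dot(d, n1))
    in_plane = d - rise_signed * n1
    shift = float(np.linalg.norm(in_plane))
    phi = _signed_or_zero(u1, in_plane, n1) if shift > 1e-9 else 0.0

    u2 = frame2.u
    if np.linalg.norm(np.cross(u2, n1)) < 1e-9:
        raise ValueError("NCP2 symmetry axis is parallel to the NCP1 normal; "
                         "axes orientation (delta) is undefined")
    delta = signed_angle_about(u1, u2, n1)

    n2 = frame2.normal
    if np.dot(n2, n1) < 0:
        n2 = -n2
    tilt = fold_angle_90(np.degrees(np.arccos(np.clip(np.dot(frame2.normal, n1),
                                                      -1.0, 1.0))))
    tilt_dir = _signed_or_zero(u1, n2, n1)

    params = StackParams(dist=dist, rise=abs(rise_signed),
                         rise_signed=rise_signed, shift=shift,
                         phi_deg=phi, delta_deg=delta, tilt_deg=tilt,
                         tilt_direction_deg=tilt_dir)
    params.orientation = classify_orientation(params, class_tolerance_deg)
    return params


def classify_orientation(params: StackParams, tolerance_deg: float = 30.0) -> str:
    """Bin the symmetry-axes orientation delta into stacking classes."""
    a = abs(params.delta_deg)
    if a >= 180.0 - tolerance_deg:
        return "head-to-tail"
    if a <= tolerance_deg:
        return "head-to-head"
    if abs(a - 90.0) < tolerance_deg:       # open band: 120 deg is "other"
        return "perpendicular"
    return "other"


def _pair_signature(p: StackParams, q: StackParams, decimals: int = 3) -> tuple:
    a, b = sorted([p.rise, q.rise]), sorted([p.shift, q.shift])
    return (round(p.dist, decimals), round(a[0], decimals), round(a[1], decimals),
            round(b[0], decimals), round(b[1], decimals),
            round(p.tilt_deg, decimals), round(abs(p.delta_deg), decimals))


def find_stacking_pairs(placements, frames=None, dist_cutoff: float = 80.0,
                        class_tolerance_deg: float = 30.0) -> list[StackPair]:
    """Unique NCP-NCP pairs with COM distance within the cutoff.

    `placements` is the list from :func:`ncpgeom.structure.expand_crystal`
    (identity first); `frames` either one reference :class:`NCPFrame` (then
    each placement's frame is its rigid image) or a list parallel to
    `placements`.  Pairs equivalent under the crystal symmetry are counted
    once; the result is sorted by distance, so the closest pair is first.
    """
    if len(placements) < 2:
        return []
    if frames is None:
        raise ValueError("frames required: pass the reference frame or a list")
    if isinstance(frames, NCPFrame):
        frames = [transform_frame(frames, p.rotation, p.translation)
                  for p in placements]
    if len(frames) != len(placements):
        raise ValueError("frames must parallel placements")

    ref_ids = [i for i, p in enumerate(placements)
               if getattr(p, "is_identity", False)] or [0]
    pairs: list[StackPair] = []
    seen: set[tuple] = set()
    for i in ref_ids:
        for j in range(len(placements)):
            if j == i:
                continue
            d = float(np.linalg.norm(placements[j].com - placements[i].com))
            if d > dist_cutoff:
                continue
            params = compute_stack_params(frames[i], frames[j],
                                          class_tolerance_deg)
            recip = compute_stack_params(frames[j], frames[i],
                                         class_tolerance_deg)
            sig = _pair_signature(params, recip)
            if sig in seen:
                continue
            seen.add(sig)
            pairs.append(StackPair(id1=i, id2=j, params=params, reciprocal=recip))
    pairs.sort(key=lambda p: p.dist)
    return pairs
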