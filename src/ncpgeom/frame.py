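"""The NCP-centred coordinate frame.

The frame sits at the centre of mass of the globular histone octamer
(gHO), its symmetry axis points from that origin towards the central base
pair(s) of the wrapped DNA, and its plane normal is the median of the two
normals constructed from the base pairs a quarter-turn (+90 and -90
degrees of superhelical azimuth) away from the central one.

Sign convention (fixed here, inherited by every signed stacking angle):
the plane normal is oriented so that the bp centred index increases
counterclockwise when viewed from the +normal side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import signed_angle_about, unit

__all__ = ["NCPFrame", "PointCoords", "FrameError", "gho_com",
           "symmetry_axis", "plane_normal", "build_frame", "locate_point",
           "transform_frame"]

DEFAULT_BP_PER_TURN = 77.5     # fallback quarter-turn selection


class FrameError(ValueError):
    pass


@dataclass
class NCPFrame:
    """Origin, directed symmetry axis u, oriented plane normal, in-plane v."""

    origin: np.ndarray
    u: np.ndarray          # symmetry axis, unit, origin -> central bp
    normal: np.ndarray     # oriented plane normal, unit, perpendicular to u
    v: np.ndarray          # normal x u, completing the right-handed triad

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "u": self.u.tolist(),
                "normal": self.normal.tolist(), "v": self.v.tolist()}


@dataclass
class PointCoords:
    """A point expressed in an NCP frame."""

    distance: float        # to the origin
    rise: float            # signed distance to the NCP plane
    shift: float           # in-plane distance
    orientation_deg: float  # signed angle of the in-plane offset vs u


def gho_com(ncp, mass_weighted: bool = True) -> np.ndarray:
    """Mass-weighted centre of the globular histone atoms (the frame origin)."""
    return ncp.globular_com(mass_weighted=mass_weighted)


def _bp_arrays(ncp) -> tuple[np.ndarray, np.ndarray]:
    bps = ncp.base_pairs
    if not bps:
        raise FrameError("base pairs not assigned")
    idx = np.array([bp.index for bp in bps], float)
    pts = np.array([bp.centroid for bp in bps], float)
    return idx, pts


def central_bp_com(ncp) -> np.ndarray:
    """COM of the central bp (odd count) or the two middle bps (even count)."""
    idx, pts = _bp_arrays(ncp)
    order = np.argsort(np.abs(idx), kind="stable")
    if abs(idx[order[0]]) < 0.25:
        sel = pts[order[0]]
    else:
        sel = 0.5 * (pts[order[0]] + pts[order[1]])
    if not np.all(np.isfinite(sel)):
        raise FrameError("central base pair(s) lack coordinates")
    return sel


def symmetry_axis(ncp, origin: np.ndarray) -> np.ndarray:
    """Directed symmetry axis: origin towards the central base pair(s)."""
    d = central_bp_com(ncp) - np.asarray(origin, float)
    if np.linalg.norm(d) < 1e-9:
        raise FrameError("origin coincides with the central-bp COM; "
                         "symmetry axis undefined")
    return unit(d)


def _quarter_turn_indices(ncp, sh=None) -> tuple[float, float]:
    """Centred bp indices nearest +90 and -90 degrees of superhelix azimuth."""
    idx, pts = _bp_arrays(ncp)
    finite = np.isfinite(pts).all(axis=1)
    idx, pts = idx[finite], pts[finite]
    central_idx = idx[np.argmin(np.abs(idx))]
    if sh is not None:
        az = np.array([sh.angle_of(p) for p in pts])
        az = np.degrees(np.unwrap(np.radians(az)))
        az0 = az[np.argmin(np.abs(idx - central_idx))]
        rel = az - az0
        targets = []
        for goal in (90.0, -90.0):
            k = np.argmin(np.abs(np.abs(rel) - 90.0) + 1e6 * (np.sign(rel) != np.sign(goal)))
            targets.append(idx[k])
        plus, minus = targets
    else:
        q = round(DEFAULT_BP_PER_TURN / 4.0)
        plus = idx[np.argmin(np.abs(idx - (central_idx + q)))]
        minus = idx[np.argmin(np.abs(idx - (central_idx - q)))]
    if plus == minus:
        raise FrameError("cannot find distinct quarter-turn base pairs")
    return plus, minus


def plane_normal(ncp, origin: np.ndarray, u: np.ndarray, sh=None,
                 max_axis_normal_dot: float = 0.35) -> np.ndarray:
    """Oriented NCP-plane normal from the two quarter-turn base pairs.

    n+ = u x r+, n- = r- x u, with r+/- the directions from the origin to
    the bp nearest +90/-90 degrees of superhelical azimuth; the normal is
    the normalised median of the two, then sign-fixed so the bp index runs
    counterclockwise seen from +normal.
    """
    origin = np.asarray(origin, float)
    u = unit(u)
    idx, pts = _bp_arrays(ncp)
    plus_i, minus_i = _quarter_turn_indices(ncp, sh)
    r_plus = pts[np.argmin(np.abs(idx - plus_i))] - origin
    r_minus = pts[np.argmin(np.abs(idx - minus_i))] - origin
    for r in (r_plus, r_minus):
        if np.linalg.norm(np.cross(u, r)) < 1e-9:
            raise FrameError("quarter-turn bp collinear with the symmetry axis")
    n = unit(unit(np.cross(u, r_plus)) + unit(np.cross(r_minus, u)))

    # sign rule: bp index increases counterclockwise viewed from +normal
    finite = np.isfinite(pts).all(axis=1)
    az = np.unwrap([np.arctan2(np.dot(p - origin, np.cross(n, u)),
                               np.dot(p - origin, u))
                    for p in pts[finite]])
    slope = np.polyfit(idx[finite], az, 1)[0]
    if slope < 0:
        n = -n
    if abs(np.dot(u, n)) >= max_axis_normal_dot:
        raise FrameError(f"degenerate frame: |u . n| = {abs(np.dot(u, n)):.2f} "
                         f">= {max_axis_normal_dot}")
    return n


def build_frame(ncp, sh=None, mass_weighted: bool = True) -> NCPFrame:
    """Construct the full NCP frame (origin, u, normal, v) for one particle."""
    origin = gho_com(ncp, mass_weighted=mass_weighted)
    u = symmetry_axis(ncp, origin)
    n = plane_normal(ncp, origin, u, sh=sh)
    # re-orthogonalise the normal against the axis, then complete the triad
    n = unit(n - np.dot(n, u) * u)
    v = np.cross(n, u)
    return NCPFrame(origin=origin, u=u, normal=n, v=v)


def locate_point(frame: NCPFrame, point: np.ndarray) -> PointCoords:
    """Express a point in the NCP frame (distance, rise, shift, orientation)."""
    d = np.asarray(point, float) - frame.origin
    rise = float(np.dot(d, frame.normal))
    in_plane = d - rise * frame.normal
    shift = float(np.linalg.norm(in_plane))
    if shift < 1e-9:
        ang = 0.0
    else:
        ang = float(np.degrees(np.arctan2(np.dot(in_plane, frame.v),
                                          np.dot(in_plane, frame.u))))
    return PointCoords(distance=float(np.linalg.norm(d)), rise=rise,
                       shift=shift, orientation_deg=ang)


def transform_frame(frame: NCPFrame, rotation: np.ndarray,
                    translation: np.ndarray) -> NCPFrame:
    """Apply a rigid transform (proper rotation + translation) to a frame."""
    R = np.asarray(rotation, float)
    t = np.asarray(translation, float)
    return NCPFrame(origin=R @ frame.origin + t, u=R @ frame.u,
                    normal=R @ frame.normal, v=R @ frame.v)
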