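"""Least-squares fit of an ideal helix to nucleosomal-DNA axis points.

The nucleosomal DNA follows ~1.8 turns of a left-handed superhelix; its
radius, pitch and bp-per-turn are obtained by fitting the parametric helix

    q(i) = c + r (cos th_i u1 + sin th_i u2) + (p_s / 2pi) th_i u3,
    th_i = th0 + omega * i

to the central 129 axis points.  The fit is initialised from a principal-
component plane, an algebraic circle fit of the projected points and linear
fits of the unwrapped angle and axial coordinate, then refined jointly by
nonlinear least squares.  Handedness is carried by the relative sign of the
angular step omega and the signed pitch slope p_s; the reported pitch is
the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .axis import DuplexAxis
from .geometry import angle_deg, fold_angle_90, orthonormal_basis_from, unit

__all__ = ["SuperhelixFit", "FrameComparison", "fit_superhelix",
           "bp_per_turn", "sh_dyad", "compare_frames"]


@dataclass
class SuperhelixFit:
    centre: np.ndarray           # Angstrom
    axis: np.ndarray             # unit vector u3
    radius: float                # Angstrom, > 0
    pitch: float                 # Angstrom, magnitude (sign via handedness)
    pitch_signed: float          # axial advance per 2pi about +axis
    phase_deg: float             # angle th at the central bp (index 0)
    omega_deg: float             # signed angular step per bp about +axis
    rmsd: float
    handedness: str              # "left" | "right"
    dyad: np.ndarray | None = None   # unit vector perpendicular to axis
    n_points: int = 0
    truncated: bool = False      # fewer than the requested window available
    init_rmsd: float = np.nan    # rmsd of the linear initialisation

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        return orthonormal_basis_from(self.axis)

    def point_at(self, index: float) -> np.ndarray:
        u1, u2 = self.basis()
        th = np.radians(self.phase_deg + self.omega_deg * index)
        axial = self.pitch_signed / (2 * np.pi) * (th - np.radians(self.phase_deg))
        return (self.centre + self.radius * (np.cos(th) * u1 + np.sin(th) * u2)
                + axial * self.axis)

    def angle_of(self, point: np.ndarray) -> float:
        """Unwrapped-free azimuth of a point about the helix axis, degrees."""
        u1, u2 = self.basis()
        d = np.asarray(point, float) - self.centre
        return float(np.degrees(np.arctan2(np.dot(d, u2), np.dot(d, u1))))

    def to_dict(self) -> dict:
        return {
            "centre": self.centre.tolist(), "axis": self.axis.tolist(),
            "radius": self.radius, "pitch": self.pitch,
            "phase_deg": self.phase_deg, "omega_deg": self.omega_deg,
            "bp_per_turn": bp_per_turn(self), "rmsd": self.rmsd,
            "handedness": self.handedness,
            "dyad": None if self.dyad is None else self.dyad.tolist(),
            "n_points": self.n_points, "truncated": self.truncated,
        }


@dataclass
class FrameComparison:
    """Scalars comparing the superhelix frame with the NCP symmetry frame."""

    centre_distance: float           # |SH centre - frame origin|
    dyad_axis_angle: float           # angle(SH dyad, symmetry axis), [0, 90]
    axis_normal_angle: float         # angle(SH axis, plane normal), [0, 90]
    dna_centroid_com_distance: float  # |mean axis point - gHO COM|


def _fit_circle_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit; returns centre and radius."""
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:2]
    radius = float(np.sqrt(sol[2] + centre @ centre))
    return centre, radius


def _axis_from_angles(theta: float, phi: float) -> np.ndarray:
    return np.array([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(theta)])


def _residuals(params: np.ndarray, pts: np.ndarray, idx: np.ndarray) -> np.ndarray:
    cx, cy, cz, theta, phi, r, th0, omega, slope = params
    u3 = _axis_from_angles(theta, phi)
    u1, u2 = orthonormal_basis_from(u3)
    th = th0 + omega * idx
    model = (np.array([cx, cy, cz])
             + r * (np.cos(th)[:, None] * u1 + np.sin(th)[:, None] * u2)
             + (slope * th)[:, None] * u3)
    return (pts - model).ravel()


def fit_superhelix(axis_points: DuplexAxis, window: int = 129,
                   max_iterations: int = 200) -> SuperhelixFit:
    """Fit an ideal helix to the `window` central axis points.

    If fewer points are available the fit uses all of them and is flagged
    `truncated`.  Raises on collinear input or non-convergence.
    """
    central = axis_points.central(window)
    truncated = len(central) < window
    pts = central.points
    idx0 = central.indices
    n = len(pts)
    if n < 7:
        raise ValueError(f"need at least 7 axis points, got {n}")

    # --- initialisation --------------------------------------------------
    # the helix axis is usually the smallest principal component of the
    # point cloud (a squat ~1.8-turn coil), but a tall helix has it as the
    # largest; initialise from every principal direction and keep the
    # refinement with the lowest residual
    mean = pts.mean(axis=0)
    centred = pts - mean
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise ValueError("axis points are collinear; helix fit is degenerate")

    best = None
    for u3 in (vt[2], vt[0], vt[1]):
        u1, u2 = orthonormal_basis_from(u3)
        xy = np.column_stack([centred @ u1, centred @ u2])
        c2d, r0 = _fit_circle_2d(xy)
        ang = np.unwrap(np.arctan2(xy[:, 1] - c2d[1], xy[:, 0] - c2d[0]))
        # linear fit angle vs bp index
        A = np.column_stack([idx0, np.ones(n)])
        (omega0, th00), *_ = np.linalg.lstsq(A, ang, rcond=None)
        z = centred @ u3
        # axial coordinate vs angle -> pitch slope (p_signed / 2pi)
        B = np.column_stack([ang, np.ones(n)])
        (slope0, z0), *_ = np.linalg.lstsq(B, z, rcond=None)
        centre0 = mean + c2d[0] * u1 + c2d[1] * u2 + z0 * u3
        theta0 = float(np.arccos(np.clip(u3[2], -1, 1)))
        phi0 = float(np.arctan2(u3[1], u3[0]))
        p0 = np.array([*centre0, theta0, phi0, r0, th00, omega0, slope0])
        init_rmsd = float(np.sqrt((_residuals(p0, pts, idx0)**2).sum() / n))

        sol = least_squares(_residuals, p0, args=(pts, idx0), method="lm",
                            xtol=1e-12, ftol=1e-14, gtol=1e-14,
                            max_nfev=max_iterations * len(p0))
        if not sol.success and sol.status <= 0:
            continue
        rmsd = float(np.sqrt((sol.fun**2).sum() / n))
        params = sol.x
        if rmsd > init_rmsd + 1e-9:
            # refinement should never degrade the initialisation
            params, rmsd = p0, init_rmsd
        if best is None or rmsd < best[1]:
            best = (params, rmsd, init_rmsd)
        if rmsd < 1e-8:
            break
    if best is None:
        raise RuntimeError("superhelix fit did not converge from any "
                           "principal-axis initialisation")
    params, rmsd, init_rmsd = best
    cx, cy, cz, theta, phi, r, th0, omega, slope = params
    u3 = _axis_from_angles(theta, phi)
    centre = np.array([cx, cy, cz])
    if r < 0:                     # negative radius == phase shift by pi
        r, th0 = -r, th0 + np.pi
    r = float(r)

    # canonical orientation: flip the axis so omega > 0.  Under u3 -> -u3
    # the deterministic basis maps (u1, u2) -> (-u1, u2), so th -> pi - th,
    # omega -> -omega, the axial slope keeps its sign along the new axis and
    # the centre absorbs a constant axial offset.
    if omega < 0:
        centre = centre + slope * np.pi * u3
        u3 = -u3
        th0 = np.pi - th0
        omega = -omega
    # the centre is defined only up to whole-turn axial shifts (th0 -> th0
    # +/- 2pi k); wrap the phase into (-pi, pi] so the centre is the axis
    # point at the central bp's angular position
    k = np.floor((th0 + np.pi) / (2 * np.pi))
    centre = centre + slope * (2 * np.pi * k) * u3
    th0 = th0 - 2 * np.pi * k
    # report the centre as the axis point at the central bp's phase (the
    # physical middle of the superhelical path), not the basis-dependent
    # theta = 0 point
    centre = centre + slope * th0 * u3
    # handedness is the chirality of the curve: sign of the axial slope in
    # any right-handed parametrisation with increasing angle
    pitch_signed = float(slope * 2 * np.pi)
    handedness = "right" if pitch_signed > 0 else "left"

    fit = SuperhelixFit(
        centre=centre, axis=u3, radius=r,
        pitch=abs(pitch_signed), pitch_signed=pitch_signed,
        phase_deg=float(np.degrees(th0)),
        omega_deg=float(np.degrees(omega)), rmsd=rmsd,
        handedness=handedness, n_points=n, truncated=truncated,
        init_rmsd=init_rmsd)
    try:
        fit.dyad = sh_dyad(fit, axis_points)
    except ValueError:
        fit.dyad = None
    return fit


def bp_per_turn(fit: SuperhelixFit) -> float:
    """Base pairs per full 360-degree turn of the superhelix."""
    if abs(fit.omega_deg) < 1e-12:
        raise ValueError("degenerate straight fit: omega = 0")
    return 360.0 / abs(fit.omega_deg)


def sh_dyad(fit: SuperhelixFit, axis_points: DuplexAxis) -> np.ndarray:
    """Dyad of the superhelix: radial direction of the central bp.

    The central-bp axis point (centred index nearest 0; the mean of the
    two innermost points for even bp counts) is projected onto the plane
    through the helix centre perpendicular to the helix axis.
    """
    order = np.argsort(np.abs(axis_points.indices), kind="stable")
    if len(order) == 0:
        raise ValueError("no axis points")
    if abs(axis_points.indices[order[0]]) < 0.25:
        central = axis_points.points[order[0]]
    else:
        central = 0.5 * (axis_points.points[order[0]] + axis_points.points[order[1]])
    d = central - fit.centre
    d = d - np.dot(d, fit.axis) * fit.axis
    if np.linalg.norm(d) < 1e-9:
        raise ValueError("central bp lies on the superhelix axis; dyad undefined")
    return unit(d)


def compare_frames(fit: SuperhelixFit, frame, axis_points: DuplexAxis) -> FrameComparison:
    """The four scalars comparing the SH frame with the NCP symmetry frame."""
    dyad = fit.dyad if fit.dyad is not None else sh_dyad(fit, axis_points)
    return FrameComparison(
        centre_distance=float(np.linalg.norm(fit.centre - frame.origin)),
        dyad_axis_angle=fold_angle_90(angle_deg(dyad, frame.u)),
        axis_normal_angle=fold_angle_90(angle_deg(fit.axis, frame.normal)),
        dna_centroid_com_distance=float(
            np.linalg.norm(axis_points.centroid() - frame.origin)),
    )
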