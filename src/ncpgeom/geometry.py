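"""Small vector helpers shared across the package.

All angles are degrees in the public API; lengths are Angstrom.
"""

from __future__ import annotations

import numpy as np

Vec = np.ndarray


def unit(v: Vec) -> Vec:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def angle_deg(a: Vec, b: Vec) -> float:
    """Unsigned angle between two vectors in [0, 180] degrees."""
    a, b = unit(a), unit(b)
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(a, b)), np.dot(a, b))))


def fold_angle_90(theta: float) -> float:
    """Fold an unsigned vector angle to the line/plane angle in [0, 90]."""
    theta = abs(theta) % 180.0
    return min(theta, 180.0 - theta)


def signed_angle_about(a: Vec, b: Vec, axis: Vec) -> float:
    """Signed angle from `a` to `b`, counterclockwise about `axis`, in (-180, 180].

    Both vectors are projected onto the plane perpendicular to `axis` first.
    """
    axis = unit(axis)
    ap = np.asarray(a, float) - np.dot(a, axis) * axis
    bp = np.asarray(b, float) - np.dot(b, axis) * axis
    if np.linalg.norm(ap) < 1e-12 or np.linalg.norm(bp) < 1e-12:
        raise ValueError("vector is (anti)parallel to the rotation axis; angle undefined")
    ang = np.degrees(np.arctan2(np.dot(np.cross(ap, bp), axis), np.dot(ap, bp)))
    # canonical half-open interval: exactly 180 stays +180
    if ang <= -180.0 + 1e-12 or ang > 180.0:
        ang = 180.0
    return float(ang)


def rotation_about_axis(axis: Vec, angle_deg_: float) -> np.ndarray:
    """Proper rotation matrix for a counterclockwise turn about `axis` (Rodrigues)."""
    k = unit(axis)
    t = np.radians(angle_deg_)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def orthonormal_basis_from(w: Vec) -> tuple[Vec, Vec]:
    """Deterministic pair (u1, u2) completing unit vector `w` to a right-handed frame.

    The seed axis is chosen as the global coordinate axis least parallel to `w`
    so the result is continuous in a neighbourhood and reproducible.
    """
    w = unit(w)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(w)))] = 1.0
    u1 = unit(np.cross(seed, w))
    u2 = np.cross(w, u1)
    return u1, u2


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1.0
    return q
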