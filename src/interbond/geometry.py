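"""Small 3-D vector helpers shared by the detectors and the fixture builder.

All coordinates are Cartesian angstroms in numpy float64 arrays of shape (3,).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distance",
    "angle_deg",
    "unit",
    "rotation_about_axis",
    "random_rotation",
    "place_internal",
    "perpendicular",
]


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees in [0, 180]."""
    u = unit(np.asarray(a, float) - np.asarray(b, float))
    w = unit(np.asarray(c, float) - np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def perpendicular(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to v."""
    v = unit(v)
    probe = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, probe))


def rotation_about_axis(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    a = unit(axis)
    t = np.radians(angle_deg_)
    c, s = np.cos(t), np.sin(t)
    x, y, z = a
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * K + (1.0 - c) * np.outer(a, a)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def place_internal(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    length: float,
    angle: float,
    dihedral: float,
) -> np.ndarray:
    """Place a fourth atom from internal coordinates (NeRF construction).

    The new atom X is bonded to ``p3`` with bond length ``length``, bond
    angle p2-p3-X of ``angle`` degrees and dihedral p1-p2-p3-X of
    ``dihedral`` degrees.
    """
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    bc = unit(p3 - p2)
    n = unit(np.cross(p2 - p1, bc))
    m = np.cross(n, bc)
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    d = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(dih),
            length * np.sin(ang) * np.sin(dih),
        ]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n
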