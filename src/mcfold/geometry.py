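"""Small geometry kernel: angles, dihedrals, axis rotations, NeRF placement.

All coordinates are in Å, angles in radians unless a name says ``deg``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bond_angle",
    "dihedral_angle",
    "rotation_matrix",
    "rotate_about_axis",
    "nerf_place",
]


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in radians."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion a-b-c-d in radians, IUPAC sign convention, range (-pi, pi]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def _cross_rows(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis-juggling overhead."""
    out = np.empty_like(u)
    out[:, 0] = u[:, 1] * v[:, 2] - u[:, 2] * v[:, 1]
    out[:, 1] = u[:, 2] * v[:, 0] - u[:, 0] * v[:, 2]
    out[:, 2] = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    return out


def dihedral_angles(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Vectorized signed torsions for an (M, 4) index array."""
    a, b, c, d = (coords[quads[:, k]] for k in range(4))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = _cross_rows(b1, b2)
    n2 = _cross_rows(b2, b3)
    b2n = b2 / np.sqrt(np.einsum("ij,ij->i", b2, b2))[:, None]
    m1 = _cross_rows(n1, b2n)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c = np.cos(angle)
    s = np.sin(angle)
    t = 1.0 - c
    return np.array(
        [
            [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
            [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
            [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
        ]
    )


def rotate_about_axis(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle: float
) -> np.ndarray:
    """Rotate points about the line through ``origin`` with direction ``axis``."""
    rot = rotation_matrix(axis, angle)
    return (points - origin) @ rot.T + origin


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d bonded to c with given internal coordinates.

    Natural-extension-reference-frame construction: ``bond`` = |c-d|,
    ``angle`` = angle(b, c, d), ``torsion`` = dihedral(a, b, c, d).
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local
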