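"""Low-level vector geometry: internal coordinates and superposition."""

from __future__ import annotations

import numpy as np

__all__ = [
    "angle", "dihedral", "place_atom", "rotation_about_axis",
    "rotate_points", "kabsch", "wrap_angle",
]


def wrap_angle(deg):
    """Wrap an angle (degrees) into (-180, 180]."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


def angle(a, b, c) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def dihedral(a, b, c, d) -> float:
    """Torsion angle a-b-c-d in degrees, IUPAC sign convention."""
    b1 = np.asarray(b, float) - a
    b2 = np.asarray(c, float) - b
    b3 = np.asarray(d, float) - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(-np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Place atom D given A, B, C with |CD|, angle(BCD) and torsion(ABCD).

    Standard natural-extension (NeRF) construction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    th = np.radians(angle_deg)
    ph = np.radians(torsion_deg)
    d_local = bond * np.array([
        -np.cos(th),
        np.sin(th) * np.cos(ph),
        np.sin(th) * np.sin(ph),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def rotation_about_axis(axis, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def rotate_points(points, origin, axis, angle_rad: float) -> np.ndarray:
    """Rotate points about the line through `origin` along `axis`."""
    rot = rotation_about_axis(axis, angle_rad)
    pts = np.asarray(points, float) - origin
    return pts @ rot.T + origin


def kabsch(mobile, reference):
    """Optimal proper rotation/translation mapping mobile onto reference.

    Returns (R, t, rmsd) with `R @ x + t` the superposed coordinates.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("superposition needs >= 3 paired atoms")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if S[1] < 1e-12:
        raise ValueError("degenerate (collinear) geometry in superposition")
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd
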