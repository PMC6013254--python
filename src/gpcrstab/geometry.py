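"""Small 3D geometry utilities: internal-coordinate placement, dihedrals."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) = angle,
    dihedral(a,b,c,d) = dihedral_deg (degrees)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(dihedral_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def virtual_cbeta(n, ca, c) -> np.ndarray:
    """Ideal Cbeta position reconstructed from backbone N, CA, C."""
    n = np.asarray(n, float) - np.asarray(ca, float)
    c = np.asarray(c, float) - np.asarray(ca, float)
    cross = np.cross(n, c)
    return -0.58273431 * cross + 0.56802827 * n - 0.54067466 * c + np.asarray(ca, float)


def radial_distance(point, axis_point, axis_dir) -> float:
    """Distance of a point from a line (axis through axis_point along axis_dir)."""
    d = np.asarray(point, float) - np.asarray(axis_point, float)
    u = unit(np.asarray(axis_dir, float))
    return float(np.linalg.norm(d - np.dot(d, u) * u))


def angular_diff(a: float, b: float) -> float:
    """Smallest absolute difference between two angles in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)
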