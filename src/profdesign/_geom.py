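"""Small 3D geometry helpers: dihedrals, superposition, sphere sampling."""
from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d given chain a-b-c with |c-d| = bond, angle(b,c,d) and
    dihedral(a,b,c,d) — the standard internal-coordinate (NeRF) step."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(bc, n)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        -bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def kabsch(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns (rotation 3x3, translation 3,) such that
    ``moving @ R.T + t`` approximates ``fixed``; proper rotation only.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    dd = np.diag([1.0, 1.0, d])
    rot = vt.T @ dd @ u.T
    trans = cf - rot @ cm
    return rot, trans


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def molecular_frame(coords: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal frame carried along with a rigid body.

    Principal axes of the coordinate cloud with a sign convention (largest
    |component| positive, right-handed) so that rigidly rotated copies of a
    structure produce the identically rotated frame. Used to orient surface
    sample points so solvent accessibility is superposition-invariant.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1].T  # rows = axes, largest eigenvalue first
    for k in range(3):
        j = int(np.argmax(np.abs(axes[k])))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def wrapped_angle_diff(a, b):
    """Absolute difference of two angles in degrees, wrapped to [0, 180]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)
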