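"""Internal-coordinate geometry: distances, angles, dihedrals and NeRF atom placement.

All angles are in degrees at the API surface; positions are numpy arrays of
shape (3,) in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distance",
    "bond_angle",
    "dihedral",
    "place_atom",
    "random_rigid_transform",
]


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_atom(
    a3: np.ndarray,
    a2: np.ndarray,
    a1: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom X bonded to a1 with |X-a1| = bond, angle X-a1-a2 = angle and
    torsion X-a1-a2-a3 = torsion (NeRF construction).
    """
    a3, a2, a1 = (np.asarray(p, float) for p in (a3, a2, a1))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # local displacement in the frame of a1
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = a1 - a2
    bc /= np.linalg.norm(bc)
    ab = a2 - a3
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # colinear reference frame; pick any perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return a1 + rot @ d


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix + translation; used by invariance tests."""
    # QR of a Gaussian matrix gives a Haar-ish rotation; fix determinant sign.
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return q, t
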