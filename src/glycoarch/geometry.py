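"""Low-level Cartesian geometry: dihedral angles, internal-coordinate placement,
least-squares planes and rigid transforms.

All angles are in degrees at the API surface; radians appear only inside
function bodies. Coordinates are in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GeometryError",
    "dihedral",
    "nerf_place",
    "fit_plane",
    "random_rigid_transform",
]


class GeometryError(ValueError):
    """Raised for degenerate geometry (collinear or coincident points)."""


def _asarray(p):
    a = np.asarray(p, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError("points must have a trailing dimension of 3")
    return a


def dihedral(p1, p2, p3, p4):
    """Dihedral angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Uses the IUPAC sign convention: looking from p2 towards p3, the angle is
    positive when p4 is rotated clockwise relative to p1 (cis = 0).

    Inputs may be single points ``(3,)`` or stacked frames ``(n, 3)``;
    broadcasting follows numpy rules. Raises :class:`GeometryError` when any
    of the two bounding planes is degenerate (collinear triples) or when
    consecutive points coincide.
    """
    p1, p2, p3, p4 = (_asarray(p) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3

    nb1 = np.linalg.norm(b1, axis=-1)
    if np.any(nb1 < 1e-10):
        raise GeometryError("central bond p2-p3 has zero length")
    scale1 = np.linalg.norm(b0, axis=-1) * nb1
    scale2 = np.linalg.norm(b2, axis=-1) * nb1
    if np.any(scale1 < 1e-12) or np.any(scale2 < 1e-12):
        raise GeometryError("coincident consecutive points")
    if np.any(np.linalg.norm(np.cross(b0, b1), axis=-1) < 1e-9 * scale1) or np.any(
        np.linalg.norm(np.cross(b1, b2), axis=-1) < 1e-9 * scale2
    ):
        raise GeometryError("collinear points: dihedral undefined")

    b1u = b1 / nb1[..., None]
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # wrap exact -180 to +180 so the range is (-180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang if ang.ndim else float(ang)


def nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d given reference atoms a, b, c (natural extension).

    d satisfies |cd| = *bond*, angle(b, c, d) = *angle_deg* and
    dihedral(a, b, c, d) = *torsion_deg*.
    """
    a, b, c = (_asarray(p) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)

    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn < 1e-10):
        raise GeometryError("reference atoms a, b, c are collinear")
    n /= nn
    m = np.cross(n, bc)

    d_local = np.stack(
        [
            -bond * np.cos(ang) * np.ones_like(tor),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ],
        axis=-1,
    )
    frame = np.stack([bc, m, n], axis=-2)  # rows are basis vectors
    return c + np.einsum("...i,...ij->...j", d_local, frame)


def fit_plane(points):
    """Least-squares plane through *points* ``(m, 3)``.

    Returns ``(centroid, unit_normal)``; the normal's sign is arbitrary and
    must be oriented by the caller.
    """
    pts = _asarray(points)
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-9:
        raise GeometryError("points are collinear: plane undefined")
    return centroid, vt[2]


def random_rigid_transform(rng: np.random.Generator, max_shift: float = 50.0):
    """A uniformly random proper rotation matrix and a random translation.

    Returns ``(R, t)`` with det(R) = +1; used to test rigid-motion invariance.
    """
    # QR of a Gaussian matrix gives a Haar-distributed orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-max_shift, max_shift, size=3)
    return q, t
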