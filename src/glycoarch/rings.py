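"""Pyranose ring pucker analysis.

Classification uses Cremer-Pople puckering coordinates of the six-membered
ring ordered O5-C1-C2-C3-C4-C5: total amplitude Q (Angstrom), polar angle
theta (0 = one chair, 180 = the inverted chair, 90 = boat/twist-boat band)
and phase phi. The canonical rule is theta <= 45 -> 4C1, theta >= 135 ->
1C4, otherwise "other"; near-planar rings (Q below an amplitude floor) are
always "other". The two endocyclic projection torsions t1 = C1-C2-C3-C4 and
t2 = C2-C3-C4-C5 are reported alongside for projection-style plots, and a
sign-quadrant heuristic over (t1, t2) provides an independent cross-check
of the chair assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from glycoarch.geometry import GeometryError, dihedral

__all__ = [
    "cremer_pople",
    "PuckerSeries",
    "classify_pucker",
    "pucker_populations",
    "projection_state",
]

#: Rings with total puckering amplitude below this (Angstrom) are "other".
MIN_AMPLITUDE = 0.1

_J = np.arange(6)


def cremer_pople(ring_xyz):
    """Cremer-Pople coordinates of six-membered rings.

    *ring_xyz* is ``(..., 6, 3)`` with atoms ordered O5-C1-C2-C3-C4-C5.
    Returns ``(Q, theta, phi)`` with Q in Angstrom and angles in degrees,
    theta in [0, 180], phi in [0, 360). Vectorised over leading axes.
    """
    r = np.asarray(ring_xyz, dtype=float)
    if r.shape[-2:] != (6, 3):
        raise ValueError("ring coordinates must have shape (..., 6, 3)")
    r = r - r.mean(axis=-2, keepdims=True)

    s = np.sin(2.0 * np.pi * _J / 6.0)
    c = np.cos(2.0 * np.pi * _J / 6.0)
    rp = np.einsum("...jk,j->...k", r, s)
    rpp = np.einsum("...jk,j->...k", r, c)
    n = np.cross(rp, rpp)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn < 1e-10):
        raise GeometryError("degenerate ring geometry: no mean plane")
    n = n / nn
    z = np.einsum("...jk,...k->...j", r, n)

    c2 = np.cos(4.0 * np.pi * _J / 6.0)
    s2 = np.sin(4.0 * np.pi * _J / 6.0)
    q2c = np.sqrt(1.0 / 3.0) * np.einsum("...j,j->...", z, c2)
    q2s = -np.sqrt(1.0 / 3.0) * np.einsum("...j,j->...", z, s2)
    q3 = np.sqrt(1.0 / 6.0) * np.einsum("...j,j->...", z, (-1.0) ** _J)
    q2 = np.hypot(q2c, q2s)

    Q = np.sqrt(q2**2 + q3**2)
    theta = np.degrees(np.arctan2(q2, q3))  # [0, 180]
    phi = np.degrees(np.arctan2(q2s, q2c)) % 360.0
    return Q, theta, phi


@dataclass
class PuckerSeries:
    states: np.ndarray  # per-frame: "4C1" | "1C4" | "other"
    t1: np.ndarray  # C1-C2-C3-C4, degrees
    t2: np.ndarray  # C2-C3-C4-C5, degrees
    amplitude: np.ndarray  # Q, Angstrom
    theta: np.ndarray  # degrees [0, 180]
    phi: np.ndarray  # degrees [0, 360)

    def __len__(self) -> int:
        return len(self.states)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.states)),
                "state": self.states,
                "t1_deg": self.t1,
                "t2_deg": self.t2,
                "amplitude_A": self.amplitude,
                "theta_deg": self.theta,
                "phi_deg": self.phi,
            }
        )


def classify_pucker(
    ring_xyz, theta_4c1: float = 45.0, theta_1c4: float = 135.0
) -> PuckerSeries:
    """Classify ring pucker per frame from six ring atoms O5-C1-C2-C3-C4-C5.

    *ring_xyz* is ``(n_frames, 6, 3)`` (a single ring ``(6, 3)`` is
    promoted). Classification is total and rotation-invariant through the
    puckering coordinates; the t1/t2 projection torsions are always
    reported for projection-style plots.
    """
    r = np.asarray(ring_xyz, dtype=float)
    single = r.ndim == 2
    if single:
        r = r[None]
    Q, theta, phi = cremer_pople(r)
    states = np.where(
        Q < MIN_AMPLITUDE,
        "other",
        np.where(theta <= theta_4c1, "4C1", np.where(theta >= theta_1c4, "1C4", "other")),
    )
    t1 = np.atleast_1d(dihedral(r[:, 1], r[:, 2], r[:, 3], r[:, 4]))
    t2 = np.atleast_1d(dihedral(r[:, 2], r[:, 3], r[:, 4], r[:, 5]))
    return PuckerSeries(
        states=states,
        t1=t1,
        t2=t2,
        amplitude=np.atleast_1d(Q),
        theta=np.atleast_1d(theta),
        phi=np.atleast_1d(phi),
    )


def pucker_populations(series: PuckerSeries) -> dict:
    """State fractions over frames; values sum to 1 exactly."""
    n = len(series)
    if n == 0:
        raise ValueError("empty pucker series")
    out = {}
    for state in ("4C1", "1C4", "other"):
        count = int(np.sum(series.states == state))
        if count:
            out[state] = count / n
    return out


def projection_state(t1, t2, threshold: float = 20.0):
    """Chair assignment from the signs of the (t1, t2) projection torsions.

    In an ideal chair the endocyclic torsions alternate in sign around the
    ring: t1 = C1-C2-C3-C4 and t2 = C2-C3-C4-C5 sit in opposite quadrants,
    and mirroring the ring (chair inversion) swaps both signs. This is the
    quick two-torsion heuristic used for scatter-plot style analysis; it is
    cross-checked against the Cremer-Pople rule in the tests.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    out = np.full(t1.shape, "other", dtype=object)
    out[(t1 < -threshold) & (t2 > threshold)] = "4C1"
    out[(t1 > threshold) & (t2 < -threshold)] = "1C4"
    return out
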