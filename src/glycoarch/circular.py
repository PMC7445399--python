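"""Circular (directional) statistics on angles in degrees.

Torsion angles live on the circle, so ordinary means and standard deviations
are wrong near the +/-180 wrap. Everything here uses the resultant-vector
formalism: for angles t_i, R = |mean(exp(i t))|, the circular mean is
arg(mean(exp(i t))) and the circular standard deviation is
sqrt(-2 ln R) (Mardia convention), reported in degrees.
"""

from __future__ import annotations

import numpy as np
from scipy.special import iv

__all__ = [
    "wrap_degrees",
    "circular_mean",
    "resultant_length",
    "circular_sd",
    "circular_summary_values",
    "angular_difference",
    "toroidal_distances",
    "von_mises_sd",
]


def wrap_degrees(x):
    """Wrap angle(s) to the range (-180, 180]."""
    x = np.asarray(x, dtype=float)
    w = ((x + 180.0) % 360.0) - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return w if w.ndim else float(w)


def _rect(values_deg):
    t = np.radians(np.asarray(values_deg, dtype=float))
    if t.size == 0:
        raise ValueError("empty angle series")
    return np.cos(t).mean(), np.sin(t).mean()


def circular_mean(values_deg) -> float:
    """Circular mean in degrees, range (-180, 180]."""
    c, s = _rect(values_deg)
    return float(wrap_degrees(np.degrees(np.arctan2(s, c))))


def resultant_length(values_deg) -> float:
    """Mean resultant length R in [0, 1]; 1 means perfectly concentrated."""
    c, s = _rect(values_deg)
    return float(min(np.hypot(c, s), 1.0))


def circular_sd(values_deg) -> float:
    """Circular standard deviation sqrt(-2 ln R) in degrees."""
    r = resultant_length(values_deg)
    r = max(r, 1e-300)
    return float(np.degrees(np.sqrt(max(-2.0 * np.log(r), 0.0))))


def circular_summary_values(values_deg):
    """(mean, sd, R) in one pass; the tuple behind CircularSummary."""
    c, s = _rect(values_deg)
    mean = float(wrap_degrees(np.degrees(np.arctan2(s, c))))
    r = float(min(np.hypot(c, s), 1.0))
    sd = float(np.degrees(np.sqrt(max(-2.0 * np.log(max(r, 1e-300)), 0.0))))
    return mean, sd, r


def angular_difference(a, b):
    """Shortest (unsigned) angular difference |a - b| on the circle, degrees in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, 360.0 - d, d)
    return d if d.ndim else float(d)


def toroidal_distances(x, y):
    """Pairwise toroidal distances between angle vectors.

    *x* ``(n, d)`` and *y* ``(m, d)`` in degrees; per dimension the shortest
    angular difference is taken and dimensions combine Euclidean-style.
    Returns ``(n, m)``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    d2 = np.zeros((x.shape[0], y.shape[0]))
    for k in range(x.shape[1]):
        dk = np.abs(x[:, k, None] - y[None, :, k])
        dk %= 360.0
        np.minimum(dk, 360.0 - dk, out=dk)
        dk *= dk
        d2 += dk
    return np.sqrt(d2, out=d2)


def von_mises_sd(kappa: float) -> float:
    """Closed-form circular SD (degrees) of a von Mises distribution.

    R = I1(kappa)/I0(kappa), SD = sqrt(-2 ln R); the reference value used to
    validate sample statistics.
    """
    r = iv(1, kappa) / iv(0, kappa)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))
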