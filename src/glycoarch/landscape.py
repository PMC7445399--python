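"""Conformer landscapes: periodic density clustering, KDE maps, convergence.

Torsion data live on a torus, so clustering uses the toroidal metric
(shortest angular difference per dimension, Euclidean combination) and the
kernel density estimate uses a wrapped Gaussian kernel. Clusters are the
density-connected components found by DBSCAN; populations are member counts
over total frames, with unassigned frames reported as noise rather than
silently dropped. The convergence rule follows common MD practice for
torsion clusters: a trajectory is flagged for extension when any cluster's
per-dimension circular SD strictly exceeds 15 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from glycoarch.circular import circular_summary_values, toroidal_distances

__all__ = [
    "TorsionCluster",
    "ConformerLandscape",
    "ConvergenceReport",
    "cluster_torsions",
    "kde_landscape",
    "assess_convergence",
    "population_of_state",
]

#: Above this many frames the density clustering runs on a deterministic
#: stride subsample of this size and every frame is then assigned to the
#: nearest clustered frame (periodic KD-tree, exact toroidal metric).
MAX_EXACT = 3000


@dataclass
class TorsionCluster:
    label: int  # 1 = most populated
    means: tuple  # per-dimension circular mean, degrees
    sds: tuple  # per-dimension circular SD, degrees
    population: float  # member_count / total frames
    member_count: int


@dataclass
class KDEGrid:
    """Wrapped-kernel density on a periodic grid over (-180, 180]^d."""

    edges: tuple  # per-dimension bin edges, degrees
    density: np.ndarray  # per-degree^d density; integrates to 1 over the torus
    bandwidth: float

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    @property
    def cell_volume(self) -> float:
        return float(np.prod([e[1] - e[0] for e in self.edges]))

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_volume)

    def argmax_center(self) -> tuple:
        idx = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return tuple(float(c[i]) for c, i in zip(self.centers, idx))


@dataclass
class ConformerLandscape:
    dimension_names: tuple  # e.g. ("phi", "psi") of one linkage
    clusters: list  # list[TorsionCluster], ordered by descending population
    noise_fraction: float
    noise_count: int
    n_frames: int
    label: str = ""
    assignments: np.ndarray = field(default=None, repr=False)  # cluster label per frame, 0 = noise
    kde: KDEGrid = field(default=None, repr=False)

    def populations(self) -> dict:
        out = {c.label: c.population for c in self.clusters}
        out["noise"] = self.noise_fraction
        return out


def _as_matrix(series):
    """Stack 1 or 2 torsion series (or raw arrays) into (n, d) degrees."""
    if not isinstance(series, (list, tuple)):
        series = [series]
    cols, names = [], []
    for s in series:
        vals = getattr(s, "values", s)
        cols.append(np.asarray(vals, dtype=float))
        names.append(getattr(s, "torsion_name", f"dim{len(names)}"))
    n = len(cols[0])
    if n == 0:
        raise ValueError("empty torsion series")
    if any(len(c) != n for c in cols):
        raise ValueError("series lengths differ")
    if len(cols) > 2:
        raise ValueError("landscapes are 1D or 2D")
    return np.column_stack(cols), tuple(names)


def cluster_torsions(
    series,
    eps: float = 25.0,
    min_fraction: float = 0.01,
    min_samples: int = 10,
    label: str = "",
) -> ConformerLandscape:
    """Density-based clustering of one or two torsion series on the torus.

    Parameters
    ----------
    series : TorsionSeries or sequence of one/two of them (or raw arrays)
    eps : DBSCAN neighbourhood radius in degrees (toroidal metric)
    min_fraction : clusters holding fewer than this fraction of frames are
        folded into noise
    min_samples : DBSCAN core-point threshold

    Populations are exact member counts over all frames; cluster labels are
    1-based in descending population order and 0 marks noise.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    X, names = _as_matrix(series)
    n = X.shape[0]

    if n <= MAX_EXACT:
        sub_idx = np.arange(n)
    else:
        step = int(np.ceil(n / MAX_EXACT))
        sub_idx = np.arange(0, n, step)
    sub = X[sub_idx]
    # min_samples applies to the clustered set unscaled: inside a real mode
    # the neighbourhood counts are far above it even on the subsample, and
    # keeping it high suppresses spurious sparse bridges between modes
    ms = min(min_samples, max(2, len(sub_idx) // 4))
    dist = toroidal_distances(sub, sub)
    db = DBSCAN(eps=eps, min_samples=ms, metric="precomputed").fit(dist)
    sub_labels = db.labels_

    if len(sub_idx) == n:
        labels = sub_labels.copy()
    else:
        clustered = sub_labels >= 0
        if not clustered.any():
            labels = np.full(n, -1, dtype=int)
        else:
            # periodic KD-tree: boxsize=360 is exactly the toroidal metric
            tree = cKDTree(np.mod(sub[clustered], 360.0), boxsize=360.0)
            d, j = tree.query(np.mod(X, 360.0), k=1)
            labels = np.where(d <= eps, sub_labels[clustered][j], -1)

    # fold sub-min_fraction clusters into noise, order the rest by population
    raw = [l for l in np.unique(labels) if l >= 0]
    counts = {l: int(np.sum(labels == l)) for l in raw}
    keep = [l for l in raw if counts[l] / n >= min_fraction]
    keep.sort(key=lambda l: (-counts[l], l))

    assignments = np.zeros(n, dtype=int)
    clusters = []
    for rank, l in enumerate(keep, start=1):
        members = labels == l
        assignments[members] = rank
        means, sds = [], []
        for k in range(X.shape[1]):
            m, s, _ = circular_summary_values(X[members, k])
            means.append(m)
            sds.append(s)
        clusters.append(
            TorsionCluster(
                label=rank,
                means=tuple(means),
                sds=tuple(sds),
                population=counts[l] / n,
                member_count=counts[l],
            )
        )
    noise_count = int(np.sum(assignments == 0))
    return ConformerLandscape(
        dimension_names=names,
        clusters=clusters,
        noise_fraction=noise_count / n,
        noise_count=noise_count,
        n_frames=n,
        label=label,
        assignments=assignments,
    )


def kde_landscape(
    series, bandwidth: float = 10.0, grid_size: int = 90
) -> KDEGrid:
    """Wrapped-Gaussian kernel density estimate on a periodic grid.

    Samples are binned on the output grid and circularly convolved (FFT)
    with the wrapped Gaussian kernel discretised at the bin centers — the
    standard fast binned-KDE path, exact in its periodic treatment. The
    density is normalised so that the torus integral equals 1.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    X, _ = _as_matrix(series)
    d = X.shape[1]
    edges = tuple(np.linspace(-180.0, 180.0, grid_size + 1) for _ in range(d))
    hist, _ = np.histogramdd(np.mod(X + 180.0, 360.0) - 180.0, bins=edges)

    centers = 0.5 * (edges[0][:-1] + edges[0][1:])
    # wrapped Gaussian kernel, centred on the grid origin, summed over wraps
    delta = centers - centers[0]
    delta = np.minimum(np.abs(delta), 360.0 - np.abs(delta))
    kern1 = np.zeros(grid_size)
    for wrap in (-360.0, 0.0, 360.0):
        kern1 += np.exp(-0.5 * ((delta + wrap) / bandwidth) ** 2)
    if d == 1:
        smooth = np.real(np.fft.ifft(np.fft.fft(hist) * np.fft.fft(kern1)))
    else:
        kern2 = np.outer(kern1, kern1)
        smooth = np.real(np.fft.ifft2(np.fft.fft2(hist) * np.fft.fft2(kern2)))
    smooth = np.clip(smooth, 0.0, None)
    cell = float(np.prod([e[1] - e[0] for e in edges]))
    smooth /= smooth.sum() * cell
    return KDEGrid(edges=edges, density=smooth, bandwidth=bandwidth)


@dataclass
class ConvergenceReport:
    threshold: float
    rows: pd.DataFrame  # (trajectory, cluster, dimension, circular_sd, flag)

    @property
    def flag(self) -> str:
        return "extend" if (self.rows["flag"] == "extend").any() else "converged"

    @property
    def converged(self) -> bool:
        return self.flag == "converged"


def assess_convergence(per_trajectory_landscapes: dict, threshold: float = 15.0) -> ConvergenceReport:
    """Flag trajectories whose cluster circular SDs exceed the threshold.

    *per_trajectory_landscapes* maps a trajectory name to its
    :class:`ConformerLandscape` (clusters computed per trajectory). The flag
    is ``extend`` iff any cluster's per-dimension circular SD is strictly
    greater than *threshold* (default 15 degrees); an SD of exactly 15.0 is
    converged.
    """
    if not per_trajectory_landscapes:
        raise ValueError("at least one trajectory is required")
    rows = []
    for traj, ls in per_trajectory_landscapes.items():
        for cl in ls.clusters:
            for dim, sd in zip(ls.dimension_names, cl.sds):
                rows.append(
                    {
                        "trajectory": traj,
                        "cluster": cl.label,
                        "dimension": dim,
                        "circular_sd": sd,
                        "flag": "extend" if sd > threshold else "converged",
                    }
                )
    frame = pd.DataFrame(
        rows, columns=["trajectory", "cluster", "dimension", "circular_sd", "flag"]
    )
    return ConvergenceReport(threshold=threshold, rows=frame)


def population_of_state(landscape: ConformerLandscape, predicate) -> dict:
    """Sum cluster populations into named states.

    *predicate* maps a :class:`TorsionCluster` to a state name; returning
    ``None`` (a cluster left unassigned) is an error. Noise is reported
    under the separate key ``"noise"``.
    """
    out: dict = {}
    for cl in landscape.clusters:
        state = predicate(cl)
        if state is None:
            raise ValueError(f"predicate left cluster {cl.label} unassigned")
        out[state] = out.get(state, 0.0) + cl.population
    out["noise"] = landscape.noise_fraction
    return out
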