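"""Torsion measurement over ensembles and circular summaries.

A :class:`TorsionSeries` is the per-frame value of one glycosidic dihedral in
degrees, wrapped to (-180, 180]. Summaries use circular statistics (see
:mod:`glycoarch.circular`): the reported "mean (SD)" pairs are the circular
mean and the resultant-length SD sqrt(-2 ln R).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from glycoarch.circular import circular_summary_values, wrap_degrees
from glycoarch.geometry import GeometryError, dihedral
from glycoarch.io import AtomMap, Ensemble
from glycoarch.model import TorsionDefinition

__all__ = [
    "TorsionSeries",
    "CircularSummary",
    "torsion_series",
    "circular_summary",
    "series_frame",
]


@dataclass
class TorsionSeries:
    definition: TorsionDefinition
    values: np.ndarray  # (n_frames,), degrees in (-180, 180]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("torsion series must be one-dimensional")

    @property
    def label(self) -> str:
        return self.definition.label

    @property
    def torsion_name(self) -> str:
        return self.definition.torsion_name

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CircularSummary:
    mean: float  # degrees, (-180, 180]
    sd: float  # degrees, >= 0
    resultant_length: float  # [0, 1]

    def __post_init__(self):
        if not 0.0 <= self.resultant_length <= 1.0:
            raise ValueError("resultant length must lie in [0, 1]")
        if self.sd < 0:
            raise ValueError("circular SD must be non-negative")


def torsion_series(
    ensemble: Ensemble, atom_map: AtomMap, definitions
) -> list:
    """Measure every requested torsion across all frames.

    Returns one :class:`TorsionSeries` per definition, in input order. A
    degenerate geometry (collinear atoms) raises :class:`GeometryError`
    citing the offending frame.
    """
    quadruples = atom_map.resolve(definitions)
    out = []
    for d, (i1, i2, i3, i4) in zip(definitions, quadruples):
        try:
            vals = dihedral(
                ensemble.xyz[:, i1],
                ensemble.xyz[:, i2],
                ensemble.xyz[:, i3],
                ensemble.xyz[:, i4],
            )
        except GeometryError:
            # locate the offending frame for the error message
            for f in range(ensemble.n_frames):
                try:
                    dihedral(
                        ensemble.xyz[f, i1],
                        ensemble.xyz[f, i2],
                        ensemble.xyz[f, i3],
                        ensemble.xyz[f, i4],
                    )
                except GeometryError as exc:
                    raise GeometryError(
                        f"torsion {d.label}: degenerate geometry at frame {f}: {exc}"
                    ) from None
            raise
        out.append(TorsionSeries(definition=d, values=wrap_degrees(np.atleast_1d(vals))))
    return out


def circular_summary(series) -> CircularSummary:
    """Circular mean/SD/resultant length of a series (or raw angle array)."""
    values = series.values if isinstance(series, TorsionSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ValueError("empty torsion series")
    mean, sd, r = circular_summary_values(values)
    return CircularSummary(mean=mean, sd=sd, resultant_length=r)


def series_frame(series_list) -> pd.DataFrame:
    """Long-format table (frame, linkage, torsion, value_deg) for export."""
    rows = []
    for s in series_list:
        lk = s.definition.linkage
        linkage_label = (
            f"{lk.child_id}({lk.child_anomeric_carbon}-{lk.parent_position}){lk.parent_id}"
        )
        for f, v in enumerate(s.values):
            rows.append((f, linkage_label, s.torsion_name, v))
    return pd.DataFrame(rows, columns=["frame", "linkage", "torsion", "value_deg"])


def write_series_csv(series_list, path) -> Path:
    path = Path(path)
    series_frame(series_list).to_csv(path, index=False, float_format="%.4f")
    return path
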