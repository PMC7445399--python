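"""Ensemble I/O and atom mapping.

Reading and writing of coordinate ensembles goes through MDAnalysis, which
handles multi-model PDB, DCD, XTC and NetCDF-style trajectories and keeps
units in Angstrom. The in-memory carrier is a plain :class:`Ensemble`
(atom table + per-frame coordinates); :class:`AtomMap` resolves the atoms a
:class:`~glycoarch.model.TorsionDefinition` needs against a residue/atom
naming dialect (PDB chemical-component codes, GLYCAM linkage codes, or a
"custom" dialect where residue ids equal tree node ids).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Ensemble",
    "AtomMap",
    "EnsembleIOError",
    "AtomMappingError",
    "read_ensemble",
    "write_ensemble_pdb",
    "map_atoms",
    "write_population_table",
    "write_manifest",
]


class EnsembleIOError(IOError):
    pass


class AtomMappingError(KeyError):
    pass


@dataclass
class Ensemble:
    """Atom table plus per-frame Cartesian coordinates in Angstrom."""

    names: np.ndarray  # (n_atoms,) atom names
    resnames: np.ndarray  # (n_atoms,) residue labels
    resids: np.ndarray  # (n_atoms,) residue indices
    elements: np.ndarray  # (n_atoms,)
    xyz: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        if self.xyz.shape[0] < 1:
            raise EnsembleIOError("ensemble has zero frames")
        n = self.xyz.shape[1]
        for arr in (self.names, self.resnames, self.resids, self.elements):
            if len(arr) != n:
                raise ValueError("atom table length does not match coordinates")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def residue_order(self):
        """(resid, resname) pairs in order of first appearance."""
        seen, out = set(), []
        for rid, rname in zip(self.resids, self.resnames):
            if rid not in seen:
                seen.add(rid)
                out.append((int(rid), str(rname)))
        return out


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_ensemble(topology, frames=None, stride: int = 1, discard: int = 0) -> Ensemble:
    """Read a coordinate ensemble.

    *topology* may itself carry frames (multi-model PDB); *frames* is an
    optional trajectory path or list of paths concatenated in the given
    order. *stride*/*discard* subsample after concatenation (defaults keep
    everything).
    """
    import MDAnalysis as mda

    topology = Path(topology)
    if not topology.exists():
        raise EnsembleIOError(f"topology file not found: {topology}")
    traj_paths = None
    if frames is not None:
        traj_paths = [Path(p) for p in (frames if isinstance(frames, (list, tuple)) else [frames])]
        for p in traj_paths:
            if not p.exists():
                raise EnsembleIOError(f"trajectory file not found: {p}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if traj_paths:
                u = mda.Universe(str(topology), [str(p) for p in traj_paths])
            else:
                u = mda.Universe(str(topology))
        except Exception as exc:  # mismatched atom counts, bad formats
            raise EnsembleIOError(f"failed to read ensemble: {exc}") from exc
        coords = np.array(
            [u.atoms.positions.copy() for _ in u.trajectory], dtype=float
        )
    coords = coords[discard::stride]
    if coords.shape[0] == 0:
        raise EnsembleIOError("ensemble has zero frames after discard/stride")
    atoms = u.atoms
    try:
        elements = np.array([str(e) for e in atoms.elements])
    except Exception:
        elements = np.array([_guess_element(n) for n in atoms.names])
    return Ensemble(
        names=np.array(atoms.names, dtype=object),
        resnames=np.array(atoms.resnames, dtype=object),
        resids=np.array(atoms.resids, dtype=int),
        elements=elements,
        xyz=coords,
    )


def write_ensemble_pdb(ensemble: Ensemble, path) -> Path:
    """Write a multi-model PDB (one MODEL per frame)."""
    import MDAnalysis as mda

    path = Path(path)
    n_res = len(ensemble.residue_order())
    resid_to_idx = {rid: i for i, (rid, _) in enumerate(ensemble.residue_order())}
    atom_resindex = np.array([resid_to_idx[int(r)] for r in ensemble.resids])
    u = mda.Universe.empty(
        n_atoms=ensemble.n_atoms,
        n_residues=n_res,
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in ensemble.names])
    u.add_TopologyAttr("resnames", [rn for _, rn in ensemble.residue_order()])
    u.add_TopologyAttr("resids", [rid for rid, _ in ensemble.residue_order()])
    u.add_TopologyAttr("elements", [str(e) for e in ensemble.elements])
    u.load_new(ensemble.xyz.astype(np.float32), order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    return path


# ---------------------------------------------------------------------------
# atom mapping
# ---------------------------------------------------------------------------

_DIALECTS: dict = {}


def load_dialects() -> dict:
    if not _DIALECTS:
        with resources.files("glycoarch.data").joinpath("dialects.json").open() as fh:
            _DIALECTS.update(json.load(fh)["dialects"])
    return _DIALECTS


@dataclass
class AtomMap:
    """Injective mapping (tree node id, canonical atom name) -> atom index."""

    dialect: str
    index: dict = field(default_factory=dict)
    node_to_resid: dict = field(default_factory=dict)

    def get(self, node_id: int, atom_name: str) -> int:
        try:
            return self.index[(node_id, atom_name)]
        except KeyError:
            raise AtomMappingError(
                f"atom {atom_name!r} of residue {node_id} is not resolved"
            ) from None

    def resolve(self, definitions) -> list:
        """Indices quadruples for torsion definitions; hard error on any gap."""
        out = []
        for d in definitions:
            try:
                out.append(tuple(self.get(nid, an) for nid, an in d.atoms))
            except AtomMappingError as exc:
                raise AtomMappingError(
                    f"torsion {d.label}: {exc.args[0]}"
                ) from None
        return out

    def ring_atoms(self, node_id: int) -> list:
        """Indices of the six pyranose ring atoms O5-C1-C2-C3-C4-C5."""
        return [self.get(node_id, a) for a in ("O5", "C1", "C2", "C3", "C4", "C5")]


def map_atoms(tree, ensemble: Ensemble, dialect: str = "custom") -> AtomMap:
    """Resolve tree residues/atoms against the ensemble's naming dialect.

    * ``custom``: ensemble resids equal tree node ids.
    * ``pdb-ccd`` / ``glycam``: residue labels are translated through the
      dialect table and matched positionally (residues in resid order against
      the canonical tree walk); a composition mismatch is a hard error.
    """
    dialects = load_dialects()
    if dialect not in dialects:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(dialects)}")
    table = dialects[dialect]["resnames"]
    synonyms = dialects[dialect]["atom_synonyms"]

    residues = ensemble.residue_order()
    amap = AtomMap(dialect=dialect)

    if dialect == "custom":
        node_to_resid = {}
        for nid in tree.nodes:
            if not any(rid == nid for rid, _ in residues):
                raise AtomMappingError(
                    f"residue id {nid} of the glycan tree not found in ensemble"
                )
            node_to_resid[nid] = nid
    else:
        walk = list(tree.walk())
        if len(walk) != len(residues):
            raise AtomMappingError(
                f"residue count mismatch: tree has {len(walk)}, ensemble has {len(residues)}"
            )
        node_to_resid = {}
        for nid, (rid, rname) in zip(walk, sorted(residues)):
            mono = table.get(str(rname))
            if mono is None:
                raise AtomMappingError(
                    f"residue label {rname!r} unknown in dialect {dialect!r}"
                )
            if mono != tree.nodes[nid].name:
                raise AtomMappingError(
                    f"residue {rid} ({rname!r} -> {mono}) does not match tree node "
                    f"{nid} ({tree.nodes[nid].name})"
                )
            node_to_resid[nid] = rid

    resid_of = {}
    for i, (rid, name) in enumerate(zip(ensemble.resids, ensemble.names)):
        canonical = synonyms.get(str(name), str(name))
        resid_of.setdefault((int(rid), canonical), i)
    for nid, rid in node_to_resid.items():
        for (r, an), idx in resid_of.items():
            if r == rid:
                key = (nid, an)
                if key not in amap.index:
                    amap.index[key] = idx
    amap.node_to_resid = node_to_resid
    # injectivity check
    if len(set(amap.index.values())) != len(amap.index):
        raise AtomMappingError("atom mapping is not injective")
    return amap


# ---------------------------------------------------------------------------
# tables and manifests
# ---------------------------------------------------------------------------


def population_table(landscapes) -> pd.DataFrame:
    """One row per (landscape, cluster) with circular means/SDs and population %.

    Noise frames appear as their own ``cluster = "noise"`` row; per-landscape
    population percentages sum to 100 exactly (count-based).
    """
    rows = []
    for ls in landscapes:
        dims = list(ls.dimension_names)
        for cl in ls.clusters:
            row = {
                "landscape": ls.label,
                "dimensions": "/".join(dims),
                "cluster": cl.label,
                "population_pct": 100.0 * cl.population,
                "n_members": cl.member_count,
            }
            for k, d in enumerate(dims):
                row[f"mean_{d}"] = cl.means[k]
                row[f"sd_{d}"] = cl.sds[k]
            rows.append(row)
        rows.append(
            {
                "landscape": ls.label,
                "dimensions": "/".join(dims),
                "cluster": "noise",
                "population_pct": 100.0 * ls.noise_fraction,
                "n_members": ls.noise_count,
            }
        )
    columns = ["landscape", "dimensions", "cluster", "population_pct", "n_members"]
    extra = sorted({k for r in rows for k in r} - set(columns))
    return pd.DataFrame(rows, columns=columns + extra)


def write_population_table(landscapes, path) -> Path:
    path = Path(path)
    population_table(landscapes).to_csv(path, index=False, float_format="%.4f")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, parameters: dict, inputs=()) -> Path:
    """JSON run manifest: parameters, seeds and input-file hashes.

    Deliberately excludes wall-clock timestamps so identical runs produce
    byte-identical manifests.
    """
    from glycoarch import __version__

    path = Path(path)
    manifest = {
        "package": "glycoarch",
        "version": __version__,
        "parameters": parameters,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
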