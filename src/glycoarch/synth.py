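"""Synthetic, ground-truth-known inputs for the analysis machinery.

Microsecond MD sampling is out of desk-scale reach, so every analysis here
is validated on generated data whose truth is known by construction:

* von Mises mixtures on the torus emulate multi-modal periodic torsion
  distributions (distinct conformers with given weights and angular
  spreads);
* two-state Markov chains with geometric dwells emulate ring-flip and other
  state-exchange dynamics;
* internal-coordinate (bond/angle/torsion) chain construction builds
  Cartesian ensembles of small glycan fragments realizing requested
  glycosidic torsions exactly, and pyranose rings realizing requested
  Cremer-Pople puckering coordinates exactly.

Every generator returns its ground truth alongside the data, and all
randomness is seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glycoarch.circular import wrap_degrees
from glycoarch.geometry import dihedral, fit_plane, nerf_place
from glycoarch.io import Ensemble
from glycoarch.model import GlycanTree, parse_glycan, torsion_definitions

__all__ = [
    "EnsembleSpec",
    "SyntheticTorsions",
    "BuiltGeometry",
    "sample_torsion_mixture",
    "sample_state_sequence",
    "build_pyranose",
    "build_flip_ring_ensemble",
    "build_linked_ensemble",
    "build_arm_geometry",
]

# nominal bond lengths / angles for the bare-ring builders (Angstrom, degrees)
BOND_CC = 1.52
BOND_CO = 1.43
BOND_GLYC = 1.41  # anomeric C1 - glycosidic O
ANGLE_GLYC = 117.0  # C1-O-Cn glycosidic angle
ANGLE_TET = 109.47
CHAIR_AMPLITUDE = 0.57  # typical pyranose total puckering amplitude

_RING_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")
_CCD_RESNAMES = {
    "GlcNAc": "NAG",
    "Man": "MAN",
    "Gal": "GAL",
    "Fuc": "FUC",
    "Xyl": "XYS",
    "Glc": "GLC",
    "Sia": "SIA",
}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Generative description of a synthetic torsion ensemble.

    ``components`` is a list of ``{"mean": [deg, ...], "kappa": float,
    "weight": float}`` with one mean per dimension. ``fragment`` optionally
    names a small glycan (condensed text or registry shorthand, at most 4
    residues) whose torsions the sampled angles drive, enabling Cartesian
    ensemble construction.
    """

    dimensions: list
    components: list
    n_frames: int
    seed: int
    fragment: str = ""
    dwell: dict = field(default_factory=dict)  # {"mean_dwells": [...]} for flip series

    def validate(self) -> None:
        problems = []
        if self.n_frames < 1:
            problems.append("n_frames must be >= 1")
        if not self.components:
            problems.append("at least one mixture component is required")
        w = sum(c.get("weight", 0.0) for c in self.components)
        if abs(w - 1.0) > 1e-9:
            problems.append(f"component weights sum to {w}, not 1")
        for i, c in enumerate(self.components):
            if c.get("kappa", 0.0) <= 0:
                problems.append(f"component {i}: kappa must be positive")
            if len(c.get("mean", [])) != len(self.dimensions):
                problems.append(
                    f"component {i}: mean vector length != number of dimensions"
                )
        if problems:
            raise ValueError("invalid ensemble spec: " + "; ".join(problems))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "dimensions": list(self.dimensions),
                "components": self.components,
                "n_frames": self.n_frames,
                "seed": self.seed,
                "fragment": self.fragment,
                "dwell": self.dwell,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "EnsembleSpec":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            raw = json.loads(Path(source).read_text())
        else:
            raw = json.loads(source)
        spec = cls(
            dimensions=raw["dimensions"],
            components=raw["components"],
            n_frames=int(raw["n_frames"]),
            seed=int(raw["seed"]),
            fragment=raw.get("fragment", ""),
            dwell=raw.get("dwell", {}),
        )
        spec.validate()
        return spec


@dataclass
class SyntheticTorsions:
    """Sampled angles (n, d) in degrees plus the true component labels."""

    dimensions: tuple
    values: np.ndarray  # (n_frames, n_dims), degrees in (-180, 180]
    labels: np.ndarray  # (n_frames,) true component index
    spec: EnsembleSpec

    def column(self, name: str) -> np.ndarray:
        return self.values[:, list(self.dimensions).index(name)]

    def true_weights(self) -> np.ndarray:
        k = len(self.spec.components)
        return np.bincount(self.labels, minlength=k) / len(self.labels)

    def truth_frame(self) -> pd.DataFrame:
        data = {"frame": np.arange(len(self.labels)), "component": self.labels}
        for i, d in enumerate(self.dimensions):
            data[f"{d}_deg"] = self.values[:, i]
        return pd.DataFrame(data)


def sample_torsion_mixture(spec: EnsembleSpec) -> SyntheticTorsions:
    """Draw frames from a von Mises mixture on the torus.

    Component membership is multinomial in the spec weights; each dimension
    is an independent von Mises draw around the component's mean with the
    component's concentration. Identical seeds give identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k = len(spec.components)
    weights = np.array([c["weight"] for c in spec.components], dtype=float)
    labels = rng.choice(k, size=spec.n_frames, p=weights)
    values = np.empty((spec.n_frames, len(spec.dimensions)))
    for ci, comp in enumerate(spec.components):
        members = labels == ci
        m = int(members.sum())
        if m == 0:
            continue
        for di in range(len(spec.dimensions)):
            draws = rng.vonmises(
                np.radians(comp["mean"][di]), comp["kappa"], size=m
            )
            values[members, di] = np.degrees(draws)
    return SyntheticTorsions(
        dimensions=tuple(spec.dimensions),
        values=np.asarray(wrap_degrees(values)),
        labels=labels,
        spec=spec,
    )


def sample_state_sequence(
    n_frames: int, mean_dwells=(9.0, 3.0), seed: int = 0
) -> np.ndarray:
    """Two-state Markov chain with geometric dwell times.

    Mean dwell of state i is ``mean_dwells[i]`` frames, so the stationary
    fractions are proportional to the mean dwells (3:1 dwells give
    0.75/0.25). The initial state is drawn from the stationary distribution.
    Returns the per-frame state index array (ground truth for flip series).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    dwells = np.asarray(mean_dwells, dtype=float)
    if dwells.shape != (2,) or np.any(dwells < 1.0):
        raise ValueError("mean_dwells must be two values >= 1 frame")
    rng = np.random.default_rng(seed)
    stationary = dwells / dwells.sum()
    state = int(rng.choice(2, p=stationary))
    out = np.empty(n_frames, dtype=int)
    pos = 0
    while pos < n_frames:
        run = int(rng.geometric(1.0 / dwells[state]))
        out[pos : pos + run] = state
        pos += run
        state = 1 - state
    return out


# ---------------------------------------------------------------------------
# pyranose ring builder
# ---------------------------------------------------------------------------


@dataclass
class BuiltGeometry:
    """Coordinates plus the construction record of what was realized."""

    names: tuple
    xyz: np.ndarray  # (n_atoms, 3)
    record: dict


_PUCKER_PRESETS = {"4C1": (CHAIR_AMPLITUDE, 0.0, 0.0), "1C4": (CHAIR_AMPLITUDE, 180.0, 0.0)}


def build_pyranose(pucker="4C1", amplitude: float = None, phase: float = 0.0) -> BuiltGeometry:
    """Six-membered ring realizing requested Cremer-Pople coordinates exactly.

    *pucker* is ``"4C1"``, ``"1C4"`` or a numeric theta in degrees; the
    total amplitude defaults to 0.57 Angstrom (typical pyranose chair).
    The ring is a regular hexagon in xy with out-of-plane displacements
    built from the pure m = 2 and m = 3 puckering modes, which makes the
    recovered (Q, theta, phi) exact by the orthogonality of the modes. Bond
    lengths are near the 1.43-1.52 Angstrom nominals and recorded as
    achieved in the construction record.
    """
    if isinstance(pucker, str):
        if pucker not in _PUCKER_PRESETS:
            raise ValueError(f"unknown pucker request {pucker!r}")
        q_total, theta, phi = _PUCKER_PRESETS[pucker]
    else:
        q_total, theta, phi = CHAIR_AMPLITUDE, float(pucker), float(phase)
    if amplitude is not None:
        q_total = float(amplitude)
    if not 0.0 < q_total <= 1.0:
        raise ValueError("puckering amplitude must lie in (0, 1] Angstrom")

    j = np.arange(6)
    q2 = q_total * np.sin(np.radians(theta))
    q3 = q_total * np.cos(np.radians(theta))
    z = np.sqrt(1.0 / 3.0) * q2 * np.cos(np.radians(phi) + 4.0 * np.pi * j / 6.0)
    z += np.sqrt(1.0 / 6.0) * q3 * (-1.0) ** j
    # the analyser's mean-plane normal for a counterclockwise hexagon is -z,
    # so the displacements are built negated to realise the request exactly
    z = -z

    # hexagon radius tuned so the average bond length matches the C-C/C-O mix
    target = (4 * BOND_CC + 2 * BOND_CO) / 6.0
    dz2 = np.mean((z - np.roll(z, -1)) ** 2)
    radius = np.sqrt(max(target**2 - dz2, 0.25))
    x = radius * np.cos(2.0 * np.pi * j / 6.0)
    y = radius * np.sin(2.0 * np.pi * j / 6.0)
    xyz = np.column_stack([x, y, z])

    bonds = np.linalg.norm(xyz - np.roll(xyz, -1, axis=0), axis=1)
    record = {
        "requested": {"amplitude_A": q_total, "theta_deg": theta, "phi_deg": phi},
        "bond_lengths_A": bonds.tolist(),
        "ring_torsions_deg": [
            float(
                dihedral(
                    xyz[i], xyz[(i + 1) % 6], xyz[(i + 2) % 6], xyz[(i + 3) % 6]
                )
            )
            for i in range(6)
        ],
    }
    return BuiltGeometry(names=_RING_NAMES, xyz=xyz, record=record)


def build_flip_ring_ensemble(
    n_frames: int,
    mean_dwells=(9.0, 3.0),
    seed: int = 0,
    states=("1C4", "4C1"),
    rigid_motion: bool = True,
):
    """Ring-flip ensemble: per-frame chair chosen by a dwell-structured chain.

    State 0 of the Markov chain maps to ``states[0]`` (default the inverted
    1C4 chair, the longer-dwelling state at 3:1 dwells). Each frame is
    optionally given a random rigid rotation+translation (classification
    must not depend on pose). Returns ``(ring_xyz (n, 6, 3), state_labels)``.
    """
    from glycoarch.geometry import random_rigid_transform

    chain = sample_state_sequence(n_frames, mean_dwells=mean_dwells, seed=seed)
    templates = {s: build_pyranose(s).xyz for s in set(states)}
    rng = np.random.default_rng(seed + 1)
    xyz = np.empty((n_frames, 6, 3))
    for f in range(n_frames):
        ring = templates[states[chain[f]]]
        if rigid_motion:
            rot, trans = random_rigid_transform(rng, max_shift=20.0)
            ring = ring @ rot.T + trans
        xyz[f] = ring
    labels = np.array([states[s] for s in chain], dtype=object)
    return xyz, labels


# ---------------------------------------------------------------------------
# linked-fragment builder
# ---------------------------------------------------------------------------

_TEMPLATE = build_pyranose("4C1")
_T_XYZ = _TEMPLATE.xyz
_T_IDX = {n: i for i, n in enumerate(_RING_NAMES)}

# exocyclic placement torsions (fixed, recorded); values only shape the
# scaffold, never the measured glycosidic torsions
_CHI_EXO = -120.0
_CHI_C6 = -60.0


def _ring_internal(name_a, name_b, name_c, name_d):
    """Template bond/angle/torsion for placing name_d after a, b, c."""
    a, b, c, d = (_T_XYZ[_T_IDX[n]] for n in (name_a, name_b, name_c, name_d))
    bond = float(np.linalg.norm(d - c))
    v1 = b - c
    v2 = d - c
    angle = float(
        np.degrees(
            np.arccos(
                np.clip(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                    -1.0,
                    1.0,
                )
            )
        )
    )
    torsion = float(dihedral(a, b, c, d))
    return bond, angle, torsion


def _place_child_ring(cn, on, c1c, o5c):
    """Complete a child ring given its placed C1 and O5 (vectorized).

    C2 is placed on the circle of rigid-ring geometry around the O5-C1 axis
    at the rotation that brings the glycosidic oxygen closest to a
    tetrahedral angle at C1; C3-C5 then follow by rigid completion from the
    template's internal coordinates.
    """
    t_o5, t_c1, t_c2 = (_T_XYZ[_T_IDX[n]] for n in ("O5", "C1", "C2"))
    lc = np.linalg.norm(t_c2 - t_c1)
    cosb = np.dot(t_o5 - t_c1, t_c2 - t_c1) / (
        np.linalg.norm(t_o5 - t_c1) * lc
    )
    sinb = np.sqrt(1.0 - cosb**2)

    u = o5c - c1c
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    ref = np.where(
        (np.abs(u[..., :1]) < 0.9), [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
    )
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = np.cross(u, e1)
    w = on - c1c
    w /= np.linalg.norm(w, axis=-1, keepdims=True)

    A = sinb * np.sum(e1 * w, axis=-1)
    B = sinb * np.sum(e2 * w, axis=-1)
    C = np.cos(np.radians(ANGLE_TET)) - cosb * np.sum(u * w, axis=-1)
    amp = np.hypot(A, B)
    t = np.arctan2(B, A) + np.arccos(np.clip(C / np.maximum(amp, 1e-12), -1.0, 1.0))
    c2c = c1c + lc * (
        cosb * u + sinb * (np.cos(t)[..., None] * e1 + np.sin(t)[..., None] * e2)
    )

    ring = {"O5": o5c, "C1": c1c, "C2": c2c}
    for prev3, prev2, prev1, name in (
        ("O5", "C1", "C2", "C3"),
        ("C1", "C2", "C3", "C4"),
        ("C2", "C3", "C4", "C5"),
    ):
        bond, angle, torsion = _ring_internal(prev3, prev2, prev1, name)
        ring[name] = nerf_place(
            ring[prev3], ring[prev2], ring[prev1], bond, angle, torsion
        )
    return ring


def build_linked_ensemble(fragment, torsion_values: dict, n_frames: int = None):
    """Cartesian ensemble of a small glycan fragment at prescribed torsions.

    Parameters
    ----------
    fragment : GlycanTree, condensed text or registry shorthand (<= 4 residues)
    torsion_values : maps torsion keys to per-frame values in degrees. Keys
        may be a :class:`TorsionDefinition` label, a ``(child_id,
        torsion_name)`` pair, or a bare torsion name when the fragment has a
        single linkage. Unspecified torsions default to -60 (phi/omega) and
        120 (psi), recorded in the truth table.
    n_frames : frame count; inferred from the value arrays when omitted.

    Returns ``(ensemble, truth)`` where *truth* is a DataFrame of the
    realized per-frame torsion targets. Measured dihedrals on the output
    equal the targets to construction precision (< 1e-6 degrees). Frames
    where construction brings atoms closer than 0.5 Angstrom are kept, with
    a warning recorded in ``ensemble_clash_frames`` of the truth attrs.
    """
    tree = fragment if isinstance(fragment, GlycanTree) else parse_glycan(fragment)
    if len(tree) > 4:
        raise ValueError("fragment builder supports at most 4 residues")
    defs = torsion_definitions(tree)

    def lookup(d):
        for key in (
            d.label,
            (d.linkage.child_id, d.torsion_name),
            d.torsion_name if len(tree.edges) == 1 else None,
        ):
            if key is not None and key in torsion_values:
                return np.atleast_1d(np.asarray(torsion_values[key], dtype=float))
        return None

    sizes = [len(v) for v in map(lookup, defs) if v is not None]
    if n_frames is None:
        n_frames = max(sizes) if sizes else 1
    targets = {}
    for d in defs:
        v = lookup(d)
        if v is None:
            v = np.full(n_frames, -60.0 if d.torsion_name in ("phi", "omega") else 120.0)
        elif len(v) == 1:
            v = np.full(n_frames, v[0])
        elif len(v) != n_frames:
            raise ValueError(f"torsion {d.label}: {len(v)} values for {n_frames} frames")
        targets[(d.linkage.child_id, d.torsion_name)] = v

    # rings[node_id] = dict name -> (n_frames, 3); root ring fixed
    rings = {
        tree.root_id: {
            n: np.tile(_T_XYZ[i], (n_frames, 1)) for i, n in enumerate(_RING_NAMES)
        }
    }
    extra = {tree.root_id: {}}  # exocyclic atoms per node

    for node_id in tree.walk():
        parent_ring = rings[node_id]
        for e in tree.children(node_id):
            n = e.parent_position
            phi = targets[(e.child_id, "phi")]
            psi = targets[(e.child_id, "psi")]
            if n == 6:
                omega = targets[(e.child_id, "omega")]
                c6 = nerf_place(
                    parent_ring["C3"], parent_ring["C4"], parent_ring["C5"],
                    BOND_CC, ANGLE_TET, _CHI_C6,
                )
                o6 = nerf_place(
                    parent_ring["O5"], parent_ring["C5"], c6,
                    BOND_CO, ANGLE_TET, omega,
                )
                extra[node_id]["C6"] = c6
                extra[node_id]["O6"] = o6
                on, cn, cprev = o6, c6, parent_ring["C5"]
            else:
                refs = {
                    2: ("O5", "C1", "C2"),
                    3: ("C1", "C2", "C3"),
                    4: ("C2", "C3", "C4"),
                }[n]
                on = nerf_place(
                    parent_ring[refs[0]], parent_ring[refs[1]], parent_ring[refs[2]],
                    BOND_CO, ANGLE_TET, _CHI_EXO,
                )
                extra[node_id][f"O{n}"] = on
                cn = parent_ring[f"C{n}"]
                cprev = parent_ring[refs[1]]
            c1c = nerf_place(cprev, cn, on, BOND_GLYC, ANGLE_GLYC, psi)
            o5c = nerf_place(cn, on, c1c, BOND_CO, 108.0, phi)
            rings[e.child_id] = _place_child_ring(cn, on, c1c, o5c)
            extra.setdefault(e.child_id, {})

    # assemble the atom table in canonical walk order
    names, resnames, resids, frames = [], [], [], []
    clash_frames: set = set()
    for node_id in tree.walk():
        atoms = dict(rings[node_id])
        atoms.update(extra.get(node_id, {}))
        for an in sorted(atoms, key=lambda a: (_T_IDX.get(a, 99), a)):
            names.append(an)
            resnames.append(_CCD_RESNAMES[tree.nodes[node_id].name])
            resids.append(node_id)
            frames.append(atoms[an])
    xyz = np.stack(frames, axis=1)  # (n_frames, n_atoms, 3)

    # clash scan (recorded, frames kept)
    for f in range(n_frames):
        d2 = np.sum((xyz[f, :, None] - xyz[f, None, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 < 0.25):
            clash_frames.add(f)

    ensemble = Ensemble(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        elements=np.array([a[0] for a in names], dtype=object),
        xyz=xyz,
    )
    truth_cols = {"frame": np.arange(n_frames)}
    for d in defs:
        truth_cols[d.label] = targets[(d.linkage.child_id, d.torsion_name)]
    truth = pd.DataFrame(truth_cols)
    truth.attrs["clash_frames"] = sorted(clash_frames)
    return ensemble, truth


# ---------------------------------------------------------------------------
# arm-state scaffold builder
# ---------------------------------------------------------------------------


def build_arm_geometry(
    state: str,
    distance: float,
    n_frames: int = 1,
    seed: int = 0,
    jitter: float = 0.0,
):
    """Minimal core+arm scaffold with the arm centroid at a known position.

    The root-GlcNAc ring sits at the origin; the arm-terminus ring centroid
    is placed at the requested *distance* along the oriented core-plane
    normal (``front_fold``), against it (``back_fold``), or in-plane
    (``open``). Returns ``(ensemble, core_index, arm_index)`` where the
    indices are the six ring-atom columns of each residue.
    """
    if state not in ("open", "front_fold", "back_fold"):
        raise ValueError(f"invalid arm state token {state!r}")
    if distance <= 2.0:
        raise ValueError("distance must exceed 2 Angstrom")
    core = build_pyranose("4C1").xyz
    centroid, normal = fit_plane(core)
    if np.dot(normal, core[1] - core[0]) < 0:  # orient by O5 -> C1
        normal = -normal
    in_plane = np.cross(normal, [0.0, 0.0, 1.0])
    if np.linalg.norm(in_plane) < 1e-6:
        in_plane = np.array([1.0, 0.0, 0.0])
    in_plane /= np.linalg.norm(in_plane)

    direction = {
        "open": in_plane,
        "front_fold": normal,
        "back_fold": -normal,
    }[state]
    arm_template = build_pyranose("4C1").xyz
    arm = arm_template - arm_template.mean(axis=0) + centroid + distance * direction

    rng = np.random.default_rng(seed)
    xyz = np.empty((n_frames, 12, 3))
    for f in range(n_frames):
        noise = rng.normal(scale=jitter, size=(12, 3)) if jitter > 0 else 0.0
        xyz[f] = np.vstack([core, arm]) + noise

    names = np.array(list(_RING_NAMES) * 2, dtype=object)
    ensemble = Ensemble(
        names=names,
        resnames=np.array(["NAG"] * 6 + ["MAN"] * 6, dtype=object),
        resids=np.array([1] * 6 + [2] * 6, dtype=int),
        elements=np.array([a[0] for a in names], dtype=object),
        xyz=xyz,
    )
    return ensemble, list(range(6)), list(range(6, 12))
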