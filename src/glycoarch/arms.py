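"""(1-6)-arm conformational state classification.

Per frame, the arm of an N-glycan is labelled one of four states:

* ``open`` — the arm terminus is outstretched, far from the chitobiose core;
* ``front_fold`` / ``back_fold`` — the arm is folded over the core, on the
  front or back side of the chitobiose reference plane;
* ``rotated_core`` — the trimannose group is rotated relative to the
  chitobiose through the core Man-b(1-4)-GlcNAc psi torsion, a distinct
  conformer that takes precedence over the distance-based labels.

The geometric rule: open iff the arm-terminus ring centroid is farther than
``d_open`` (default 8 Angstrom) from the root-GlcNAc ring centroid; folded
frames split front/back by the signed distance of the arm centroid from the
least-squares plane of the root GlcNAc ring, whose normal is oriented by
the ring's O5 -> C1 vector. rotated_core fires when the core psi deviates
more than 90 degrees from its reference mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from glycoarch.circular import angular_difference
from glycoarch.geometry import fit_plane

__all__ = [
    "ArmStateSeries",
    "ArmParams",
    "classify_arm_frames",
    "classify_arm_state",
    "find_arm_terminus",
]

STATES = ("open", "front_fold", "back_fold", "rotated_core")


@dataclass
class ArmParams:
    d_open: float = 8.0  # Angstrom, centroid-centroid open/folded boundary
    psi_deviation: float = 90.0  # degrees, rotated-core rule
    psi_reference: float = None  # reference mode of core psi; None disables


@dataclass
class ArmStateSeries:
    states: np.ndarray  # per-frame state string
    distance: np.ndarray  # arm-terminus <-> root-GlcNAc ring centroid, Angstrom
    signed_plane_distance: np.ndarray  # Angstrom; >0 = front side
    core_psi: np.ndarray = None  # degrees, when a core psi series was given
    params: ArmParams = None

    def __len__(self) -> int:
        return len(self.states)

    def fractions(self) -> dict:
        n = len(self.states)
        return {
            s: int(np.sum(self.states == s)) / n
            for s in STATES
            if np.any(self.states == s)
        }

    def frame(self) -> pd.DataFrame:
        data = {
            "frame": np.arange(len(self.states)),
            "state": self.states,
            "centroid_distance_A": self.distance,
            "signed_plane_distance_A": self.signed_plane_distance,
        }
        if self.core_psi is not None:
            data["core_psi_deg"] = self.core_psi
        return pd.DataFrame(data)


def classify_arm_frames(
    core_ring_xyz,
    arm_ring_xyz,
    params: ArmParams = None,
    core_psi=None,
) -> ArmStateSeries:
    """Classify arm states from ring coordinates.

    *core_ring_xyz*: ``(n, 6, 3)`` root-GlcNAc ring atoms O5-C1-C2-C3-C4-C5
    (the chitobiose reference); *arm_ring_xyz*: ``(n, 6, 3)`` ring atoms of
    the (1-6)-arm terminal residue. *core_psi* is the optional per-frame
    core Man-b(1-4)-GlcNAc psi series in degrees for the rotated-core rule.
    """
    params = params or ArmParams()
    core = np.asarray(core_ring_xyz, dtype=float)
    arm = np.asarray(arm_ring_xyz, dtype=float)
    if core.ndim == 2:
        core = core[None]
    if arm.ndim == 2:
        arm = arm[None]
    if core.shape[0] != arm.shape[0]:
        raise ValueError("core and arm ring series have different frame counts")
    n = core.shape[0]

    arm_centroid = arm.mean(axis=1)
    core_centroid = core.mean(axis=1)
    distance = np.linalg.norm(arm_centroid - core_centroid, axis=1)

    signed = np.empty(n)
    for f in range(n):
        centroid, normal = fit_plane(core[f])
        # orient the normal by the O5 -> C1 vector of the root ring
        o5c1 = core[f, 1] - core[f, 0]
        if np.dot(normal, o5c1) < 0:
            normal = -normal
        signed[f] = float(np.dot(arm_centroid[f] - centroid, normal))

    states = np.where(
        distance > params.d_open,
        "open",
        np.where(signed > 0.0, "front_fold", "back_fold"),
    ).astype(object)

    psi_arr = None
    if core_psi is not None and params.psi_reference is not None:
        psi_arr = np.asarray(
            getattr(core_psi, "values", core_psi), dtype=float
        )
        if len(psi_arr) != n:
            raise ValueError("core psi series length does not match frames")
        rotated = angular_difference(psi_arr, params.psi_reference) > params.psi_deviation
        states[np.asarray(rotated, bool)] = "rotated_core"

    return ArmStateSeries(
        states=states,
        distance=distance,
        signed_plane_distance=signed,
        core_psi=psi_arr,
        params=params,
    )


def find_arm_terminus(tree) -> int:
    """Node id of the terminal residue of the (1-6) arm.

    Walks from the beta-Man of the trimannose core down the alpha(1-6)
    branch, always continuing along the chain (positions 3/4, i.e. the
    backbone extension) to the deepest residue. Raises ValueError when the
    tree has no Man-a(1-6)-Man linkage.
    """
    # beta-Man: the Man child of the non-root chitobiose GlcNAc
    man6 = None
    for e in tree.edges:
        if (
            tree.nodes[e.child_id].name == "Man"
            and tree.nodes[e.parent_id].name == "Man"
            and e.parent_position == 6
        ):
            man6 = e.child_id
            break
    if man6 is None:
        raise ValueError("tree has no Man-a(1-6)-Man linkage: no (1-6) arm")
    node = man6
    while True:
        children = [
            e for e in tree.children(node) if e.parent_position in (2, 3, 4)
        ]
        if not children:
            return node
        # continue along the backbone: lowest-position extension first
        children.sort(key=lambda e: e.parent_position)
        node = children[0].child_id


def classify_arm_state(
    ensemble, atom_map, tree, params: ArmParams = None, core_psi=None
) -> ArmStateSeries:
    """High-level arm classification from an ensemble and its atom map.

    Locates the root-GlcNAc and (1-6)-arm-terminus rings through the tree
    and atom map, then applies :func:`classify_arm_frames`. *core_psi* may
    be a measured core Man-b(1-4)-GlcNAc psi :class:`TorsionSeries` for the
    rotated-core rule (requires ``params.psi_reference``).
    """
    terminus = find_arm_terminus(tree)
    core_idx = atom_map.ring_atoms(tree.root_id)
    arm_idx = atom_map.ring_atoms(terminus)
    return classify_arm_frames(
        ensemble.xyz[:, core_idx],
        ensemble.xyz[:, arm_idx],
        params=params,
        core_psi=core_psi,
    )
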