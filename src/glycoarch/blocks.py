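"""Glycoblock decomposition and qualitative propensity prediction.

A "glycoblock" is a self-contained 3D unit of monosaccharides and their
linkages whose local structure and dynamics compose the whole N-glycan's
architecture: the chitobiose core (optionally carrying core fucoses), the
trimannose core (optionally carrying b(1-2)-Xyl), arm GlcNAc units,
terminal galactoses and the branched Lewis A / Lewis X termini. The
decomposition partitions every residue of a tree into exactly one block;
the propensity engine then fires an ordered, data-driven rule base over the
block multiset to predict the qualitative (1-6)-arm behaviour (open/closed/
mixed/restrained) together with a full rule trace. Reference population
percentages from microsecond-MD characterisations ride along as annotation
metadata only — they are never recomputed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from glycoarch.model import GlycanTree, parse_glycan

__all__ = [
    "Glycoblock",
    "PropensityReport",
    "DecompositionError",
    "decompose",
    "predict_propensity",
    "compare_decompositions",
    "load_rules",
]

BLOCK_TYPES = (
    "chitobiose_core",
    "trimannose_core",
    "arm_GlcNAc",
    "terminal_Gal_1_3",
    "terminal_Gal_1_4",
    "LeA_terminus",
    "LeX_terminus",
)

#: Legal modifier attachment: core fucoses decorate the chitobiose,
#: b(1-2)-Xyl decorates the trimannose.
MODIFIER_HOSTS = {
    "Fuc_a1_3": "chitobiose_core",
    "Fuc_a1_6": "chitobiose_core",
    "Xyl_b1_2": "trimannose_core",
}


class DecompositionError(ValueError):
    pass


@dataclass(frozen=True)
class Glycoblock:
    block_type: str
    members: tuple  # residue node ids (sorted), including modifier residues
    modifiers: tuple = ()  # sorted modifier tokens
    arm: str = ""  # "1-3" / "1-6" for arm-attached blocks, else ""
    descriptor: str = ""  # conformational note filled from the rule base

    def __post_init__(self):
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block type {self.block_type!r}")
        for m in self.modifiers:
            if MODIFIER_HOSTS.get(m) != self.block_type:
                raise ValueError(
                    f"modifier {m} cannot attach to {self.block_type}"
                )

    @property
    def signature(self) -> str:
        mods = "+".join(self.modifiers)
        return self.block_type + (f"{{{mods}}}" if mods else "")


@dataclass
class PropensityReport:
    arm_1_6: str  # open_dominant | closed_dominant | mixed | restrained_interacting
    chitobiose_psi_shift: float  # degrees (0 or about -20 vs the unmodified mode)
    flexibility_notes: list
    trace: list  # fired rules in firing order: dicts with id/evidence/metadata
    reference_populations: dict  # annotation only
    features: dict = field(default_factory=dict)

    def fired(self) -> list:
        return [t["id"] for t in self.trace]

    def to_text(self) -> str:
        lines = [
            f"(1-6) arm propensity : {self.arm_1_6}",
            f"chitobiose psi shift : {self.chitobiose_psi_shift:+.0f} deg",
            "fired rules:",
        ]
        for t in self.trace:
            lines.append(f"  [{t['id']}] {t['evidence']}")
            if t["reference_populations"]:
                refs = ", ".join(
                    f"{k}={v}" for k, v in sorted(t["reference_populations"].items())
                )
                lines.append(f"        reference metadata: {refs}")
        if self.flexibility_notes:
            lines.append("flexibility notes:")
            lines.extend(f"  - {n}" for n in self.flexibility_notes)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------


def _child_of(tree, node_id, name, position, anomer=None):
    for e in tree.children(node_id):
        c = tree.nodes[e.child_id]
        if c.name == name and e.parent_position == position:
            if anomer is None or c.anomer == anomer:
                return e.child_id
    return None


def decompose(tree) -> list:
    """Partition an N-glycan tree into glycoblocks.

    Precedence: (1) chitobiose core absorbing core fucoses; (2) trimannose
    core absorbing b(1-2)-Xyl; (3) branched Lewis A/X termini absorbing
    their arm GlcNAc; (4) remaining arm GlcNAc; (5) unbranched terminal
    galactoses. A residue no rule can place is a hard error; the result
    always covers every residue exactly once.
    """
    if isinstance(tree, str):
        tree = parse_glycan(tree)
    tree.validate()
    assigned: dict = {}
    blocks: list = []

    root = tree.root_id
    if tree.nodes[root].name != "GlcNAc":
        raise DecompositionError("tree is not rooted at a reducing-end GlcNAc")
    glcnac2 = _child_of(tree, root, "GlcNAc", 4)
    if glcnac2 is None:
        raise DecompositionError("no chitobiose: missing GlcNAc-b(1-4)-GlcNAc")
    bman = _child_of(tree, glcnac2, "Man", 4)
    if bman is None:
        raise DecompositionError("no trimannose core: missing Man-b(1-4)")
    man3 = _child_of(tree, bman, "Man", 3)
    man6 = _child_of(tree, bman, "Man", 6)
    if man3 is None or man6 is None:
        raise DecompositionError("no trimannose core: missing an arm mannose")

    # (1) chitobiose + core fucoses
    members = [root, glcnac2]
    mods = []
    for pos, token in ((3, "Fuc_a1_3"), (6, "Fuc_a1_6")):
        fuc = _child_of(tree, root, "Fuc", pos)
        if fuc is not None:
            members.append(fuc)
            mods.append(token)
    blocks.append(
        Glycoblock(
            block_type="chitobiose_core",
            members=tuple(sorted(members)),
            modifiers=tuple(sorted(mods)),
        )
    )

    # (2) trimannose + Xyl
    members = [bman, man3, man6]
    mods = []
    xyl = _child_of(tree, bman, "Xyl", 2)
    if xyl is not None:
        members.append(xyl)
        mods.append("Xyl_b1_2")
    blocks.append(
        Glycoblock(
            block_type="trimannose_core",
            members=tuple(sorted(members)),
            modifiers=tuple(mods),
        )
    )

    # (3, 4, 5) the arms
    for arm_label, arm_man in (("1-3", man3), ("1-6", man6)):
        glcnac = _child_of(tree, arm_man, "GlcNAc", 2)
        if glcnac is None:
            continue
        gal3 = _child_of(tree, glcnac, "Gal", 3)
        gal4 = _child_of(tree, glcnac, "Gal", 4)
        fuc4 = _child_of(tree, glcnac, "Fuc", 4)
        fuc3 = _child_of(tree, glcnac, "Fuc", 3)
        if gal3 is not None and fuc4 is not None:
            blocks.append(
                Glycoblock(
                    block_type="LeA_terminus",
                    members=tuple(sorted((glcnac, gal3, fuc4))),
                    arm=arm_label,
                )
            )
        elif gal4 is not None and fuc3 is not None:
            blocks.append(
                Glycoblock(
                    block_type="LeX_terminus",
                    members=tuple(sorted((glcnac, gal4, fuc3))),
                    arm=arm_label,
                )
            )
        else:
            blocks.append(
                Glycoblock(
                    block_type="arm_GlcNAc", members=(glcnac,), arm=arm_label
                )
            )
            if gal3 is not None:
                blocks.append(
                    Glycoblock(
                        block_type="terminal_Gal_1_3", members=(gal3,), arm=arm_label
                    )
                )
            if gal4 is not None:
                blocks.append(
                    Glycoblock(
                        block_type="terminal_Gal_1_4", members=(gal4,), arm=arm_label
                    )
                )

    for b in blocks:
        for m in b.members:
            if m in assigned:
                raise DecompositionError(
                    f"residue {m} assigned to both {assigned[m]} and {b.block_type}"
                )
            assigned[m] = b.block_type
    unassigned = set(tree.nodes) - set(assigned)
    if unassigned:
        detail = ", ".join(
            f"{i} ({tree.nodes[i].name})" for i in sorted(unassigned)
        )
        raise DecompositionError(f"residues not assignable to any block: {detail}")
    return blocks


# ---------------------------------------------------------------------------
# propensity rules
# ---------------------------------------------------------------------------

_RULES_CACHE: list = []


def load_rules() -> list:
    if not _RULES_CACHE:
        with resources.files("glycoarch.data").joinpath("rules.json").open() as fh:
            _RULES_CACHE.extend(json.load(fh)["rules"])
    return _RULES_CACHE


def _features(blocks) -> dict:
    by_type: dict = {}
    for b in blocks:
        by_type.setdefault(b.block_type, []).append(b)

    def terminus(arm):
        for t, label in (
            ("LeA_terminus", "LeA"),
            ("LeX_terminus", "LeX"),
            ("terminal_Gal_1_3", "Gal_1_3"),
            ("terminal_Gal_1_4", "Gal_1_4"),
        ):
            if any(b.arm == arm for b in by_type.get(t, [])):
                return label
        if any(b.arm == arm for b in by_type.get("arm_GlcNAc", [])):
            return "GlcNAc"
        return "Man"

    chitobiose = by_type.get("chitobiose_core", [None])[0]
    trimannose = by_type.get("trimannose_core", [None])[0]
    arm16, arm13 = terminus("1-6"), terminus("1-3")
    return {
        "chitobiose_modifiers": list(chitobiose.modifiers) if chitobiose else [],
        "trimannose_modifiers": list(trimannose.modifiers) if trimannose else [],
        "arm16_terminus": arm16,
        "arm13_terminus": arm13,
        "both_arms_terminus": arm16 if arm16 == arm13 else "",
    }


def _rule_applies(rule, feats, fired_ids) -> bool:
    req = rule.get("requires", {})
    for key, expected in req.items():
        if key == "chitobiose_modifiers_include":
            if not set(expected) <= set(feats["chitobiose_modifiers"]):
                return False
        elif key == "chitobiose_modifiers_exclude":
            if set(expected) & set(feats["chitobiose_modifiers"]):
                return False
        elif key == "trimannose_modifiers_include":
            if not set(expected) <= set(feats["trimannose_modifiers"]):
                return False
        elif key == "trimannose_modifiers_exclude":
            if set(expected) & set(feats["trimannose_modifiers"]):
                return False
        elif key == "arm16_terminus":
            if feats["arm16_terminus"] != expected:
                return False
        elif key == "both_arms_terminus":
            if feats["both_arms_terminus"] != expected:
                return False
        elif key == "any_fired":
            if not set(expected) & set(fired_ids):
                return False
        else:
            raise ValueError(f"unknown rule predicate {key!r}")
    return True


def predict_propensity(blocks) -> PropensityReport:
    """Fire the rule base over a decomposition.

    Rules fire in ascending priority so higher-priority rules may depend on
    lower ones having fired; the highest-priority fired rule that sets the
    (1-6)-arm state wins, with conflicts recorded in the trace. Always
    returns a report with at least one fired rule (the default scaffold
    rule fires when nothing else does).
    """
    feats = _features(blocks)
    rules = sorted(load_rules(), key=lambda r: (r["priority"], r["id"]))
    fired, fired_ids = [], []
    for rule in rules:
        if rule["id"] == "R0":
            continue  # default considered last
        if _rule_applies(rule, feats, fired_ids):
            fired.append(rule)
            fired_ids.append(rule["id"])
    if not any("arm_1_6" in r["effects"] for r in fired):
        default = next(r for r in load_rules() if r["id"] == "R0")
        fired.append(default)
        fired_ids.append("R0")

    psi_shift = 0.0
    notes: list = []
    arm_setters = []
    for rule in fired:
        eff = rule["effects"]
        psi_shift += eff.get("chitobiose_psi_shift_deg", 0.0)
        notes.extend(eff.get("notes", []))
        if "arm_1_6" in eff:
            arm_setters.append(rule)
    winner = max(arm_setters, key=lambda r: r["priority"])

    trace = []
    for rule in fired:
        entry = {
            "id": rule["id"],
            "priority": rule["priority"],
            "evidence": rule["evidence"],
            "reference_populations": dict(rule["reference_populations"]),
        }
        if "arm_1_6" in rule["effects"] and rule is not winner:
            entry["overridden_by"] = winner["id"]
        trace.append(entry)

    refs: dict = {}
    for rule in fired:
        refs.update(rule["reference_populations"])
    return PropensityReport(
        arm_1_6=winner["effects"]["arm_1_6"],
        chitobiose_psi_shift=psi_shift,
        flexibility_notes=notes,
        trace=trace,
        reference_populations=refs,
        features=feats,
    )


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


def compare_decompositions(tree_a, tree_b) -> dict:
    """Block-level diff between two glycans.

    Singleton core blocks are compared by modifier set ("modified" entries);
    multi-instance block types by count ("added"/"removed" entries).
    """
    blocks_a = decompose(tree_a) if not isinstance(tree_a, list) else tree_a
    blocks_b = decompose(tree_b) if not isinstance(tree_b, list) else tree_b

    def census(blocks):
        singleton, counts = {}, {}
        for b in blocks:
            if b.block_type in ("chitobiose_core", "trimannose_core"):
                singleton[b.block_type] = set(b.modifiers)
            else:
                counts[b.block_type] = counts.get(b.block_type, 0) + 1
        return singleton, counts

    sa, ca = census(blocks_a)
    sb, cb = census(blocks_b)
    diff = {"added": [], "removed": [], "modified": []}
    for t in sorted(set(sa) | set(sb)):
        ma, mb = sa.get(t), sb.get(t)
        if ma is None:
            diff["added"].append({"block_type": t, "count": 1})
        elif mb is None:
            diff["removed"].append({"block_type": t, "count": 1})
        elif ma != mb:
            diff["modified"].append(
                {
                    "block_type": t,
                    "modifiers_removed": sorted(ma - mb),
                    "modifiers_added": sorted(mb - ma),
                }
            )
    for t in sorted(set(ca) | set(cb)):
        na, nb = ca.get(t, 0), cb.get(t, 0)
        if nb > na:
            diff["added"].append({"block_type": t, "count": nb - na})
        elif na > nb:
            diff["removed"].append({"block_type": t, "count": na - nb})
    diff["identical"] = not (diff["added"] or diff["removed"] or diff["modified"])
    return diff
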