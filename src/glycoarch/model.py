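"""Rooted-tree model of N-glycans and the condensed-sequence dialect.

An N-glycan is represented as a labelled rooted tree: nodes are
monosaccharides, edges are glycosidic linkages annotated with the child's
anomeric carbon and the substituted parent position. The root is the
reducing-end GlcNAc. Sequences are written in a condensed IUPAC-like text
dialect, e.g.::

    Gal(b1-3)GlcNAc(b1-2)Man(a1-3)[Gal(b1-3)GlcNAc(b1-2)Man(a1-6)]
        [Xyl(b1-2)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-3)]GlcNAc

reading child-to-parent left to right, with bracketed branches immediately
preceding the residue they substitute. Short glycoform names (ng, gfx, lea,
xFA2G2, ...) are expanded through a data-driven registry shipped with the
package.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

__all__ = [
    "Monosaccharide",
    "Linkage",
    "GlycanTree",
    "TorsionDefinition",
    "GlycanParseError",
    "parse_glycan",
    "serialize_glycan",
    "torsion_definitions",
    "load_registry",
    "registry_names",
]

#: Controlled residue vocabulary. ``Sia`` is accepted by the parser but
#: flagged unsupported for conformational analysis.
VOCABULARY = ("GlcNAc", "Man", "Gal", "Fuc", "Xyl", "Glc", "Sia")
UNSUPPORTED = frozenset({"Sia"})

#: Residues that are L-series by default (everything else is D).
_L_SERIES = frozenset({"Fuc"})

_NAME_ALIASES = {
    "GlcNAc": "GlcNAc",
    "Man": "Man",
    "Gal": "Gal",
    "Fuc": "Fuc",
    "Xyl": "Xyl",
    "Glc": "Glc",
    "Sia": "Sia",
    "Neu5Ac": "Sia",
    "NeuAc": "Sia",
}


class GlycanParseError(ValueError):
    """Sequence text could not be parsed; carries token and offset."""

    def __init__(self, message: str, token: str = "", offset: int = -1):
        self.token = token
        self.offset = offset
        loc = f" (token {token!r} at offset {offset})" if offset >= 0 else ""
        super().__init__(message + loc)


@dataclass(frozen=True)
class Monosaccharide:
    id: int
    name: str
    anomer: str  # "a" (alpha) or "b" (beta)
    series: str = ""  # "D" or "L"; default derived from name
    ring: str = "p"  # pyranose

    def __post_init__(self):
        if self.name not in VOCABULARY:
            raise ValueError(f"unknown monosaccharide name {self.name!r}")
        if self.anomer not in ("a", "b", ""):
            raise ValueError(f"anomer must be 'a' or 'b', got {self.anomer!r}")
        if not self.series:
            object.__setattr__(
                self, "series", "L" if self.name in _L_SERIES else "D"
            )

    @property
    def supported(self) -> bool:
        return self.name not in UNSUPPORTED


@dataclass(frozen=True)
class Linkage:
    parent_id: int
    child_id: int
    child_anomeric_carbon: int  # 1, or 2 for sialic acids
    parent_position: int  # 2, 3, 4 or 6

    def __post_init__(self):
        if self.child_anomeric_carbon not in (1, 2):
            raise ValueError("child anomeric carbon must be 1 or 2")
        if self.parent_position not in (2, 3, 4, 6):
            raise ValueError(
                f"unsupported attachment position {self.parent_position}"
            )

    @property
    def torsion_names(self) -> tuple:
        """phi/psi for every linkage; omega only for 1->6."""
        return ("phi", "psi", "omega") if self.parent_position == 6 else ("phi", "psi")


@dataclass(frozen=True)
class TorsionDefinition:
    """One dihedral of one linkage: four (residue id, atom name) pairs.

    The atom convention for X(1->n)Y is:

    * phi   = O5(X) - C1(X) - On(Y) - Cn(Y)
    * psi   = C1(X) - On(Y) - Cn(Y) - C(n-1)(Y)   (C1 for n = 2)
    * omega = O6(Y) - C6(Y) - C5(Y) - O5(Y)        (1->6 only; gg = -60,
      gt = +60, tg = 180)
    """

    linkage: Linkage
    torsion_name: str
    atoms: tuple  # four (residue_id, atom_name) pairs

    @property
    def label(self) -> str:
        lk = self.linkage
        return f"{lk.child_id}-{lk.child_anomeric_carbon}_{lk.parent_position}-{lk.parent_id}:{self.torsion_name}"


@dataclass
class GlycanTree:
    nodes: dict = field(default_factory=dict)  # id -> Monosaccharide
    edges: list = field(default_factory=list)  # list[Linkage]
    root_id: int = 0

    # -- construction ------------------------------------------------------
    def add_node(self, node: Monosaccharide) -> int:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node
        return node.id

    def add_edge(self, link: Linkage) -> None:
        self.edges.append(link)

    # -- queries -----------------------------------------------------------
    def children(self, node_id: int) -> list:
        return [e for e in self.edges if e.parent_id == node_id]

    def parent_edge(self, node_id: int):
        for e in self.edges:
            if e.child_id == node_id:
                return e
        return None

    def node(self, node_id: int) -> Monosaccharide:
        return self.nodes[node_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def walk(self, start=None) -> Iterator[int]:
        """Depth-first node ids in canonical order (see serialize_glycan)."""
        start = self.root_id if start is None else start
        yield start
        for e in _canonical_child_order(self, start):
            yield from self.walk(e.child_id)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.root_id not in self.nodes:
            raise ValueError("root id not among nodes")
        parents: dict = {}
        for e in self.edges:
            if e.parent_id not in self.nodes or e.child_id not in self.nodes:
                raise ValueError("edge references unknown node")
            if e.child_id in parents:
                raise ValueError(f"node {e.child_id} has two parents")
            parents[e.child_id] = e.parent_id
        if self.root_id in parents:
            raise ValueError("root has a parent")
        # one substituent per (parent, position)
        seen = set()
        for e in self.edges:
            key = (e.parent_id, e.parent_position)
            if key in seen:
                raise ValueError(
                    f"duplicate substitution at position {e.parent_position} "
                    f"of residue {e.parent_id}"
                )
            seen.add(key)
        # connected and acyclic: every non-root reachable exactly once
        reached = set(self.walk())
        if reached != set(self.nodes):
            raise ValueError("tree is not connected")
        if len(self.edges) != len(self.nodes) - 1:
            raise ValueError("edge count inconsistent with a tree")

    def isomorphic_to(self, other: "GlycanTree") -> bool:
        """Structural equality ignoring node ids (canonical serialization)."""
        return serialize_glycan(self) == serialize_glycan(other)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"(?P<name>Neu5Ac|NeuAc|GlcNAc|Man|Gal|Fuc|Xyl|Glc|Sia)"
    r"|(?P<link>\((?P<anomer>[ab])(?P<acarbon>[12])-(?P<pos>[2346])\))"
    r"|(?P<lb>\[)"
    r"|(?P<rb>\])"
)


def _tokenize(text: str):
    tokens = []
    i = 0
    while i < len(text):
        if text[i].isspace():
            i += 1
            continue
        m = _TOKEN_RE.match(text, i)
        if m is None:
            raise GlycanParseError(
                "unknown residue or malformed token", text[i : i + 8], i
            )
        kind = m.lastgroup if m.lastgroup in ("name", "lb", "rb") else "link"
        if m.group("name"):
            tokens.append(("name", _NAME_ALIASES[m.group("name")], i))
        elif m.group("lb"):
            tokens.append(("lb", "[", i))
        elif m.group("rb"):
            tokens.append(("rb", "]", i))
        else:
            tokens.append(
                (
                    "link",
                    (m.group("anomer"), int(m.group("acarbon")), int(m.group("pos"))),
                    i,
                )
            )
        i = m.end()
    return tokens


def _parse_tokens(tokens, tree: GlycanTree, next_id: list) -> int:
    """Parse a token slice into a subtree; return the subtree root node id.

    The rightmost token must be a residue name; everything to its left is
    either bracketed branches or the continuing chain, each ending in a
    linkage descriptor.
    """
    if not tokens:
        raise GlycanParseError("empty (sub)sequence")
    kind, value, off = tokens[-1]
    if kind != "name":
        raise GlycanParseError("expected residue name", str(value), off)
    # anomer of this residue comes from the linkage that attaches it (set by
    # caller); placeholder resolved below.
    node_id = next_id[0]
    next_id[0] += 1

    i = len(tokens) - 2
    pending = []  # (child token slice, link tuple, offset)
    while i >= 0 and tokens[i][0] == "rb":
        depth = 1
        j = i - 1
        while j >= 0 and depth:
            if tokens[j][0] == "rb":
                depth += 1
            elif tokens[j][0] == "lb":
                depth -= 1
            j -= 1
        if depth:
            raise GlycanParseError("unbalanced brackets", "]", tokens[i][2])
        inner = tokens[j + 2 : i]
        if not inner or inner[-1][0] != "link":
            raise GlycanParseError(
                "branch must end with a linkage descriptor", "]", tokens[i][2]
            )
        pending.append((inner[:-1], inner[-1][1], inner[-1][2]))
        i = j
    chain = tokens[: i + 1]
    if chain:
        if chain[-1][0] != "link":
            raise GlycanParseError(
                "chain must end with a linkage descriptor",
                str(chain[-1][1]),
                chain[-1][2],
            )
        pending.append((chain[:-1], chain[-1][1], chain[-1][2]))

    # create the node; anomer is attached later by the caller via _set_anomer
    tree.nodes[node_id] = Monosaccharide(id=node_id, name=value, anomer="")

    taken_positions = {}
    for child_tokens, (anomer, acarbon, pos), loff in pending:
        if pos in taken_positions:
            raise GlycanParseError(
                f"duplicate substitution at position {pos}", f"(-{pos})", loff
            )
        taken_positions[pos] = True
        child_id = _parse_tokens(child_tokens, tree, next_id)
        child = tree.nodes[child_id]
        tree.nodes[child_id] = Monosaccharide(
            id=child_id, name=child.name, anomer=anomer
        )
        tree.add_edge(
            Linkage(
                parent_id=node_id,
                child_id=child_id,
                child_anomeric_carbon=acarbon,
                parent_position=pos,
            )
        )
    return node_id


def parse_glycan(text: str) -> GlycanTree:
    """Parse condensed sequence text or a registry shorthand into a tree.

    Shorthand names (case-insensitive, e.g. ``"gfx"``, ``"xFA2G2"``) are
    expanded through the packaged registry; anything else is treated as
    condensed IUPAC-like text.
    """
    registry = load_registry()
    key = text.strip()
    lowered = key.lower()
    if lowered in registry:
        key = registry[lowered]["sequence"]
    tokens = _tokenize(key)
    # catch stray '[' early for a clear message
    depth = 0
    for kind, value, off in tokens:
        if kind == "lb":
            depth += 1
        elif kind == "rb":
            depth -= 1
            if depth < 0:
                raise GlycanParseError("unbalanced brackets", "]", off)
    if depth != 0:
        raise GlycanParseError("unbalanced brackets", "[", tokens[-1][2])
    tree = GlycanTree()
    next_id = [1]
    tree.root_id = _parse_tokens(tokens, tree, next_id)
    # root carries no linkage: mark beta (reducing-end GlcNAc convention)
    root = tree.nodes[tree.root_id]
    tree.nodes[tree.root_id] = Monosaccharide(
        id=root.id, name=root.name, anomer=root.anomer or "b"
    )
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _subtree_stats(tree: GlycanTree, node_id: int):
    """(height, size) of the subtree rooted at node_id."""
    ch = tree.children(node_id)
    if not ch:
        return 1, 1
    stats = [_subtree_stats(tree, e.child_id) for e in ch]
    return 1 + max(h for h, _ in stats), 1 + sum(s for _, s in stats)


def _canonical_child_order(tree: GlycanTree, node_id: int):
    """Children ordered: the backbone chain child first, then branches by
    descending parent position.

    The chain child (written unbracketed, leftmost) is the one with the
    tallest/largest subtree, ties broken towards the lowest attachment
    position -- this reproduces conventional condensed-IUPAC layout where
    the (1-3)/(1-4) backbone continues the chain and e.g. the (1-6) arm and
    Xyl are bracketed.
    """
    ch = tree.children(node_id)
    if not ch:
        return []
    keyed = []
    for e in ch:
        h, s = _subtree_stats(tree, e.child_id)
        keyed.append(((h, s, -e.parent_position), e))
    keyed.sort(key=lambda t: t[0], reverse=True)
    chain = keyed[0][1]
    branches = sorted(
        (e for _, e in keyed[1:]), key=lambda e: -e.parent_position
    )
    return [chain] + branches


def _serialize_node(tree: GlycanTree, node_id: int) -> str:
    node = tree.nodes[node_id]
    ordered = _canonical_child_order(tree, node_id)
    parts = []
    for rank, e in enumerate(ordered):
        sub = _serialize_node(tree, e.child_id)
        link = f"({tree.nodes[e.child_id].anomer}{e.child_anomeric_carbon}-{e.parent_position})"
        if rank == 0:
            parts.append(sub + link)
        else:
            parts.append("[" + sub + link + "]")
    return "".join(parts) + node.name


def serialize_glycan(tree: GlycanTree) -> str:
    """Canonical condensed text; isomorphic trees serialize identically."""
    tree.validate()
    return _serialize_node(tree, tree.root_id)


# ---------------------------------------------------------------------------
# torsion definitions
# ---------------------------------------------------------------------------


def torsion_definitions(tree: GlycanTree) -> list:
    """Phi/psi per linkage plus omega for every 1->6 linkage.

    Linkages are emitted in canonical tree-walk order. Residues flagged
    unsupported (sialic acid placeholder) raise a ValueError.
    """
    defs = []
    for node_id in tree.walk():
        for e in _canonical_child_order(tree, node_id):
            child = tree.nodes[e.child_id]
            parent = tree.nodes[e.parent_id]
            if not child.supported or not parent.supported:
                raise ValueError(
                    f"residue {child.name if not child.supported else parent.name} "
                    "is unsupported for torsion analysis"
                )
            n = e.parent_position
            ac = e.child_anomeric_carbon
            on = f"O{n}"
            cn = f"C{n}"
            cprev = f"C{n - 1}" if n > 2 else "C1"
            defs.append(
                TorsionDefinition(
                    linkage=e,
                    torsion_name="phi",
                    atoms=(
                        (e.child_id, "O5"),
                        (e.child_id, f"C{ac}"),
                        (e.parent_id, on),
                        (e.parent_id, cn),
                    ),
                )
            )
            defs.append(
                TorsionDefinition(
                    linkage=e,
                    torsion_name="psi",
                    atoms=(
                        (e.child_id, f"C{ac}"),
                        (e.parent_id, on),
                        (e.parent_id, cn),
                        (e.parent_id, cprev),
                    ),
                )
            )
            if n == 6:
                defs.append(
                    TorsionDefinition(
                        linkage=e,
                        torsion_name="omega",
                        atoms=(
                            (e.parent_id, "O6"),
                            (e.parent_id, "C6"),
                            (e.parent_id, "C5"),
                            (e.parent_id, "O5"),
                        ),
                    )
                )
    return defs


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY_CACHE: dict = {}


def load_registry() -> dict:
    """The shorthand registry: lowercase name -> entry dict.

    Entries carry the condensed sequence, a description, reference
    population metadata from microsecond-MD studies (annotation only, never
    recomputed here) and ambiguity notes where residue-level detail was not
    fully determinable.
    """
    if not _REGISTRY_CACHE:
        with resources.files("glycoarch.data").joinpath("registry.json").open() as fh:
            raw = json.load(fh)
        for entry in raw["glycoforms"]:
            _REGISTRY_CACHE[entry["name"].lower()] = entry
    return _REGISTRY_CACHE


def registry_names() -> list:
    """Registered shorthand names in file order."""
    return [e["name"] for e in load_registry().values()]
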