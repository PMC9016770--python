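"""Rooted ultrametric phylogeny: Newick I/O, branching times, clades, LTT.

Every likelihood in this package consumes a time-calibrated, rooted, strictly
bifurcating, ultrametric tree with branch lengths in millions of years (Myr).
Ages are measured in Ma before the present; t = 0 is the present everywhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Node",
    "Phylogeny",
    "TreeError",
    "parse_newick",
    "branching_times",
    "ltt_points",
]

#: relative (to crown age) tolerance for ultrametricity checks
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or unsupported trees."""


@dataclass
class Node:
    label: str | None = None
    length: float = 0.0          # branch length above this node (Myr)
    age: float = 0.0             # Ma before present
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted binary ultrametric tree.

    Construct via :func:`parse_newick` or from a root :class:`Node` whose
    branch lengths are set; node ages are (re)derived from path lengths.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._assign_ages()
        if validate:
            self._validate()

    # -- construction helpers ------------------------------------------------

    def _assign_ages(self) -> None:
        # depth from root, then age = max depth - depth; tips snapped to 0
        depths: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depths[id(node)] = depths[id(node.parent)] + node.length
        tips = self.tips()
        if not tips:
            raise TreeError("empty tree")
        maxdepth = max(depths[id(t)] for t in tips)
        self._tip_depths = {t.label: depths[id(t)] for t in tips}
        for node in self.preorder():
            node.age = maxdepth - depths[id(node)]
            if node.is_tip and abs(node.age) <= ULTRAMETRIC_RTOL * max(maxdepth, 1e-12):
                node.age = 0.0

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.preorder():
            if node.is_tip:
                if not node.label:
                    raise TreeError("tip with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            elif len(node.children) != 2:
                raise TreeError(
                    f"non-binary: internal node with {len(node.children)} children"
                )
        T = self.crown_age
        tol = ULTRAMETRIC_RTOL * max(T, 1e-12)
        for tip in self.tips():
            if abs(tip.age) > tol:
                raise TreeError(
                    f"non-ultrametric: tip {tip.label!r} ends {tip.age:.6g} Myr "
                    f"from the present (tolerance {tol:.3g})"
                )
        for node in self.preorder():
            if node.length < 0:
                raise TreeError(f"negative branch length at {node.label or 'internal'}")

    # -- traversal -----------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def crown_age(self) -> float:
        return self.root.age

    # -- operations ----------------------------------------------------------

    def branching_times(self) -> np.ndarray:
        """Internal-node ages, sorted descending (crown age first)."""
        ages = np.array([n.age for n in self.internal_nodes()], dtype=float)
        return np.sort(ages)[::-1]

    def mrca(self, labels) -> Node:
        labels = set(labels)
        missing = labels - set(self.tip_labels)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        # postorder: smallest node containing all labels
        cover: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                cover[id(node)] = {node.label} & labels
            else:
                cover[id(node)] = set().union(*(cover[id(c)] for c in node.children))
            if cover[id(node)] == labels:
                return node
        raise TreeError("MRCA not found")  # pragma: no cover

    def extract_clade(self, tip_subset) -> "Phylogeny":
        """Subtree rooted at the MRCA of ``tip_subset``.

        The subset must be monophyletic; intruding tips are reported otherwise.
        """
        tip_subset = set(tip_subset)
        if not tip_subset:
            raise TreeError("empty tip subset")
        node = self.mrca(tip_subset)
        under = {t.label for t in _subtree_tips(node)}
        intruders = under - tip_subset
        if intruders:
            raise TreeError(
                f"tip subset not monophyletic; MRCA also contains {sorted(intruders)}"
            )
        clone = _copy_subtree(node)
        clone.length = 0.0
        clone.parent = None
        return Phylogeny(clone)

    def ltt_points(self) -> list[tuple[float, int]]:
        """Lineage-through-time series: (age, count), crown first, present last."""
        bt = self.branching_times()
        pts = [(float(bt[0]), 2)]
        count = 2
        for age in bt[1:]:
            count += 1
            pts.append((float(age), count))
        pts.append((0.0, count))
        return pts

    # -- I/O -----------------------------------------------------------------

    def write_newick(self) -> str:
        buf = io.StringIO()
        _write_node(buf, self.root, with_length=False)
        buf.write(";")
        return buf.getvalue()


def _subtree_tips(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            yield n
        else:
            stack.extend(n.children)


def _copy_subtree(node: Node) -> Node:
    clone = Node(label=node.label, length=node.length)
    for child in node.children:
        cc = _copy_subtree(child)
        cc.parent = clone
        clone.children.append(cc)
    return clone


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_node(buf, node: Node, with_length: bool = True) -> None:
    if node.children:
        buf.write("(")
        for i, child in enumerate(node.children):
            if i:
                buf.write(",")
            _write_node(buf, child)
        buf.write(")")
        if node.label:
            buf.write(_quote(node.label))
    else:
        buf.write(_quote(node.label or ""))
    if with_length:
        buf.write(f":{node.length:.9g}")


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths mandatory) into a Phylogeny.

    Rejects polytomies, missing branch lengths, and non-ultrametric trees.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise TreeError(f"Newick parse error: {exc}") from exc
    droot = dtree.seed_node
    if droot is None or not droot.child_nodes():
        raise TreeError("Newick parse error: no tree content")

    def convert(dnode, is_root: bool) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if not is_root:
                raise TreeError("missing branch length")
            length = 0.0
        node = Node(label=label, length=float(length))
        for dchild in dnode.child_nodes():
            child = convert(dchild, False)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(droot, True)
    return Phylogeny(root)


def branching_times(tree: Phylogeny) -> np.ndarray:
    """Internal-node ages in Ma, sorted descending; the sufficient statistic
    for every trait-free birth-death likelihood in this package."""
    return tree.branching_times()


def ltt_points(tree: Phylogeny) -> list[tuple[float, int]]:
    return tree.ltt_points()
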