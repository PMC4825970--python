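"""Rooted, ultrametric dated trees and clade algebra.

The central object is :class:`DatedTree`: a strictly bifurcating rooted tree
with branch durations in Myr and derived node ages in Ma (tips at age 0).
Clades are identified across topologies by :class:`CladeKey`, the sorted
tuple of subtended tip labels, which is what makes "the same clade in every
topology" a well-defined criterion when tree shapes differ.

Newick/NEXUS deserialisation is delegated to dendropy; validation
(ultrametricity, bifurcation, label uniqueness) happens here.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "CladeKey",
    "DatedTree",
    "TreeNode",
    "TreeSample",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "parse_nexus_trees",
    "mrca",
    "clade_set",
    "discordant_taxa",
]

#: relative tolerance (fraction of tree height) for tip-depth equality
ULTRAMETRIC_RTOL = 1e-6

CladeKey = tuple  # sorted tuple of tip labels


class NewickParseError(ValueError):
    """Malformed Newick/NEXUS input; carries the character offset if known."""


class TreeValidationError(ValueError):
    """Structurally valid tree that violates a DatedTree invariant."""


@dataclass
class TreeNode:
    label: Optional[str] = None
    length: float = 0.0          # duration of the branch above, Myr
    children: list["TreeNode"] = field(default_factory=list)
    age: float = 0.0             # Ma, derived; 0 at tips
    clade: CladeKey = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class DatedTree:
    """Strictly bifurcating rooted tree with node ages in Ma.

    Parameters
    ----------
    root : TreeNode
        Root of an already-built node structure with branch lengths set.
    validate : bool
        Check bifurcation, label uniqueness and ultrametricity (default).
    """

    def __init__(self, root: TreeNode, validate: bool = True):
        self.root = root
        self._index_and_date()
        if validate:
            self._validate()

    # -- construction ------------------------------------------------------

    def _index_and_date(self) -> None:
        # depths by preorder, ages from max depth
        depth = {id(self.root): 0.0}
        order = list(self.root.walk())
        for node in order:
            for child in node.children:
                depth[id(child)] = depth[id(node)] + child.length
        self.height = max(depth[id(n)] for n in order if n.is_leaf) if order else 0.0
        for node in order:
            node.age = self.height - depth[id(node)]
        # clade keys bottom-up
        for node in reversed(order):
            if node.is_leaf:
                node.clade = (node.label,)
            else:
                tips: list[str] = []
                for child in node.children:
                    tips.extend(child.clade)
                node.clade = tuple(sorted(tips))
        self._nodes = order
        self.tip_labels = tuple(sorted(self.root.clade))
        self._clade_to_node = {}
        for node in order:
            self._clade_to_node[node.clade] = node

    def _validate(self) -> None:
        labels = [n.label for n in self._nodes if n.is_leaf]
        if any(not lab for lab in labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for node in self._nodes:
            if node.children and len(node.children) != 2:
                raise TreeValidationError(
                    f"node {node.clade or node.label} has {len(node.children)} "
                    "children; trees must be strictly bifurcating "
                    "(resolve polytomies before loading)"
                )
            if node.length < 0:
                raise TreeValidationError(f"negative branch length above {node.clade}")
        tol = max(self.height, 1.0) * ULTRAMETRIC_RTOL
        worst = max((n for n in self._nodes if n.is_leaf), key=lambda n: abs(n.age))
        if abs(worst.age) > tol:
            raise TreeValidationError(
                f"tree is not ultrametric: tip {worst.label!r} sits at age "
                f"{worst.age:.6g} Ma (tolerance {tol:.3g})"
            )
        for node in self._nodes:
            for child in node.children:
                if not node.age > child.age - tol:
                    raise TreeValidationError(
                        f"parent age {node.age} not greater than child age "
                        f"{child.age} at clade {child.clade}"
                    )

    # -- queries -----------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def nodes(self) -> Sequence[TreeNode]:
        """Preorder node list (root first)."""
        return self._nodes

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self._nodes if n.children]

    def tips(self) -> list[TreeNode]:
        return [n for n in self._nodes if n.is_leaf]

    def node_for(self, clade: CladeKey) -> TreeNode:
        try:
            return self._clade_to_node[tuple(sorted(clade))]
        except KeyError:
            raise KeyError(f"no node subtends exactly {clade}") from None

    def has_clade(self, clade: CladeKey) -> bool:
        return tuple(sorted(clade)) in self._clade_to_node

    def mrca(self, taxa: Iterable[str]) -> CladeKey:
        """CladeKey of the smallest clade containing all named taxa."""
        wanted = set(taxa)
        unknown = wanted - set(self.tip_labels)
        if unknown:
            raise KeyError(f"unknown taxa: {sorted(unknown)}")
        if len(wanted) < 2:
            raise ValueError("mrca needs at least 2 taxa")
        best = self.root
        improved = True
        while improved:
            improved = False
            for child in best.children:
                if wanted <= set(child.clade):
                    best = child
                    improved = True
                    break
        return best.clade

    def clade_set(self) -> set[CladeKey]:
        """All clades, tips included: 2n − 1 keys for n tips."""
        return set(self._clade_to_node)

    # -- serialisation -----------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = _quote_label(node.label)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            return f"{core}:{node.length:.{precision}g}"

        inner = "(" + ",".join(fmt(c) for c in self.root.children) + ")"
        return inner + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DatedTree n_tips={self.n_tips} height={self.height:.4g} Ma>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# -- parsing ---------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> DatedTree:
    def convert(dnode) -> TreeNode:
        label = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = TreeNode(label=label, length=float(length))
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0  # root edge length is ignored
    return DatedTree(root)


def parse_newick(text: str) -> DatedTree:
    """Parse a single Newick string with branch lengths into a DatedTree.

    Raises
    ------
    NewickParseError
        On malformed input, naming the character offset when known.
    TreeValidationError
        When the tree parses but is non-ultrametric or non-bifurcating.
    """
    if ";" not in text:
        raise NewickParseError(
            f"missing terminating ';' (offset {len(text.rstrip())})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        col = getattr(exc, "col_num", None)
        loc = f" at offset {col}" if col is not None else ""
        raise NewickParseError(f"malformed Newick{loc}: {exc}") from exc
    missing = [
        e.head_node.taxon.label if e.head_node.taxon else "<internal>"
        for e in dtree.edges()
        if e.tail_node is not None and e.length is None
    ]
    if missing:
        raise NewickParseError(f"branch lengths missing above: {missing[:5]}")
    return _from_dendropy(dtree)


def parse_nexus_trees(text: str, burn_in: float = 0.25) -> "TreeSample":
    """Read the TREES block of a NEXUS file (translate tables honoured)."""
    try:
        trees = dendropy.TreeList.get(
            data=text, schema="nexus", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise NewickParseError(f"malformed NEXUS trees block: {exc}") from exc
    return TreeSample([_from_dendropy(t) for t in trees], burn_in=burn_in)


# -- tree samples ----------------------------------------------------------


class TreeSample:
    """An ordered posterior sample of trees over one tip set.

    The first ``burn_in`` fraction (by count, rounded down) is excluded from
    every statistic, mirroring the usual MCMC discard protocol.
    """

    def __init__(self, trees: Sequence[DatedTree], burn_in: float = 0.25):
        if not trees:
            raise TreeValidationError("empty tree sample")
        if not 0.0 <= burn_in < 1.0:
            raise ValueError("burn_in must be in [0, 1)")
        tip_set = set(trees[0].tip_labels)
        for i, t in enumerate(trees[1:], start=2):
            if set(t.tip_labels) != tip_set:
                diff = tip_set ^ set(t.tip_labels)
                raise TreeValidationError(
                    f"tree {i} has a different tip set (difference: {sorted(diff)})"
                )
        self.all_trees = list(trees)
        self.burn_in = burn_in

    @property
    def n_burned(self) -> int:
        return int(len(self.all_trees) * self.burn_in)

    @property
    def trees(self) -> list[DatedTree]:
        """Post-burn-in trees."""
        return self.all_trees[self.n_burned:]

    def __len__(self) -> int:
        return len(self.trees)


# -- module-level wrappers (match the documented operation surface) --------


def mrca(tree: DatedTree, taxa: Iterable[str]) -> CladeKey:
    return tree.mrca(taxa)


def clade_set(tree: DatedTree) -> set[CladeKey]:
    return tree.clade_set()


def _restricted(clades: set[CladeKey], keep: set[str]) -> frozenset:
    out = set()
    for c in clades:
        r = tuple(sorted(set(c) & keep))
        if r:
            out.add(r)
    return frozenset(out)


def discordant_taxa(t1: DatedTree, t2: DatedTree) -> set[str]:
    """Smallest taxon set (greedy) whose removal reconciles two topologies.

    Repeatedly removes the single taxon whose removal maximally reduces the
    symmetric difference of the two trees' clade sets (ties broken
    alphabetically) until the difference vanishes.  This approximates the
    taxon list reported by the Disagree topology-comparison approach.
    """
    s1, s2 = set(t1.tip_labels), set(t2.tip_labels)
    if s1 != s2:
        raise TreeValidationError(
            f"tip sets differ (symmetric difference: {sorted(s1 ^ s2)})"
        )
    c1, c2 = t1.clade_set(), t2.clade_set()
    keep = set(s1)
    removed: set[str] = set()
    while True:
        r1, r2 = _restricted(c1, keep), _restricted(c2, keep)
        if r1 == r2:
            return removed
        best_taxon, best_size = None, math.inf
        for taxon in sorted(keep):
            trial = keep - {taxon}
            size = len(_restricted(c1, trial) ^ _restricted(c2, trial))
            if size < best_size:
                best_taxon, best_size = taxon, size
        assert best_taxon is not None
        removed.add(best_taxon)
        keep.discard(best_taxon)
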