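"""Rooted-topology data model, Newick/NEXUS tree I/O, pruning, clade extraction.

Trees are modelled as rooted, possibly multifurcating topologies with
labelled tips.  Branch lengths and support annotations are parsed and
carried along but ignored by every computation in this package, which is
purely topological.  Parsing is delegated to :mod:`dendropy`; the
lightweight :class:`RootedTopology` wrapper guarantees a canonical form
(no unary nodes, children ordered by smallest contained tip label) so
that serialisation is deterministic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

from .errors import DomainError, NewickParseError, ValidationError

__all__ = [
    "Clade",
    "Node",
    "RootedTopology",
    "TreeSample",
    "parse_newick",
    "write_newick",
    "read_trees_nexus",
    "read_tree_sample",
    "normalize_label",
]

#: A clade is simply the frozen set of tip labels descended from a node.
Clade = frozenset

_QUOTE_NEEDED = re.compile(r"[\s()\[\]{},;:=*'\"`+<>]")


def normalize_label(label: str, underscores_to_spaces: bool = True) -> str:
    """Optional tip-label normalisation helper (off by default everywhere).

    Trims surrounding whitespace and, optionally, converts underscores to
    spaces.  Comparisons in this package are otherwise exact,
    case-sensitive string matches.
    """
    label = label.strip()
    if underscores_to_spaces:
        label = label.replace("_", " ")
    return label


class Node:
    """A node of a rooted topology."""

    __slots__ = ("parent", "children", "label", "length", "support")

    def __init__(self, label=None, length=None, support=None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.label: str | None = label
        self.length: float | None = length
        self.support: float | None = support

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return iter(reversed(out))


class RootedTopology:
    """A canonical rooted tree over uniquely labelled tips.

    Canonical form: no internal node has exactly one child, and children
    are ordered by the smallest tip label they contain.  Constructing a
    topology canonicalises and validates the node structure handed in.
    """

    def __init__(self, root: Node):
        self.root = root
        self._canonicalize()
        self._validate()

    # -- construction helpers ------------------------------------------------

    def _canonicalize(self) -> None:
        self.root = _suppress_unary(self.root)
        self.root.parent = None
        _sort_children(self.root)

    def _validate(self) -> None:
        labels = [nd.label for nd in self.root.preorder() if nd.is_tip]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise ValidationError("every tip must carry a nonempty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")

    # -- basic queries -------------------------------------------------------

    @property
    def taxa(self) -> frozenset:
        return frozenset(nd.label for nd in self.root.preorder() if nd.is_tip)

    @property
    def n_tips(self) -> int:
        return sum(1 for nd in self.root.preorder() if nd.is_tip)

    def tips(self) -> Iterator[Node]:
        return (nd for nd in self.root.preorder() if nd.is_tip)

    def internal_nodes(self, exclude_root: bool = True) -> Iterator[Node]:
        for nd in self.root.preorder():
            if nd.is_tip:
                continue
            if exclude_root and nd is self.root:
                continue
            yield nd

    @property
    def is_resolved(self) -> bool:
        return all(len(nd.children) == 2
                   for nd in self.root.preorder() if not nd.is_tip)

    def clade_map(self) -> dict:
        """Map every node to the frozenset of tip labels below it."""
        clades: dict[Node, frozenset] = {}
        for nd in self.root.postorder():
            if nd.is_tip:
                clades[nd] = frozenset((nd.label,))
            else:
                acc = frozenset()
                for ch in nd.children:
                    acc |= clades[ch]
                clades[nd] = acc
        return clades

    def nontrivial_clades(self) -> set:
        """All clades of internal non-root nodes, sizes in [2, n-1].

        For a fully resolved rooted tree on n tips this returns exactly
        n - 2 clades.  Requires n >= 3.
        """
        n = self.n_tips
        if n < 3:
            raise DomainError(f"need at least 3 tips, got {n}")
        cm = self.clade_map()
        return {cm[nd] for nd in self.internal_nodes(exclude_root=True)}

    # -- transformations -----------------------------------------------------

    def copy(self) -> "RootedTopology":
        return RootedTopology(_clone(self.root))

    def prune_to_taxa(self, keep) -> "RootedTopology":
        """Restrict the topology to the tips in ``keep``.

        Unary nodes created by the pruning are suppressed; the resulting
        clade set is the intersect-then-filter image of the original.
        """
        keep = frozenset(keep)
        unknown = keep - self.taxa
        if unknown:
            raise ValidationError(f"labels not in tree: {sorted(unknown)}")
        if len(keep) < 2:
            raise DomainError("pruning must retain at least 2 tips")
        pruned = _prune(self.root, keep)
        assert pruned is not None
        return RootedTopology(pruned)

    def same_topology(self, other: "RootedTopology") -> bool:
        return (self.taxa == other.taxa
                and self.nontrivial_clades() == other.nontrivial_clades())

    # -- serialisation -------------------------------------------------------

    def to_newick(self, lengths: bool = False, supports: bool = False) -> str:
        return write_newick(self, lengths=lengths, supports=supports)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<RootedTopology n_tips={self.n_tips}>"


def _suppress_unary(node: Node) -> Node:
    node.children = [_suppress_unary(ch) for ch in node.children]
    for ch in node.children:
        ch.parent = node
    if len(node.children) == 1:
        child = node.children[0]
        if node.length is not None or child.length is not None:
            child.length = (node.length or 0.0) + (child.length or 0.0)
        return child
    return node


def _sort_children(node: Node) -> str:
    if node.is_tip:
        return node.label
    keyed = sorted((( _sort_children(ch)), ch) for ch in node.children)
    node.children = [ch for _, ch in keyed]
    return keyed[0][0]


def _clone(node: Node) -> Node:
    nn = Node(node.label, node.length, node.support)
    for ch in node.children:
        nn.add(_clone(ch))
    return nn


def _prune(node: Node, keep: frozenset) -> Node | None:
    if node.is_tip:
        return Node(node.label, node.length, node.support) if node.label in keep else None
    kept = [sub for ch in node.children if (sub := _prune(ch, keep)) is not None]
    if not kept:
        return None
    nn = Node(node.label, node.length, node.support)
    for ch in kept:
        nn.add(ch)
    return nn


# ---------------------------------------------------------------------------
# I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> RootedTopology:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise ValidationError("tip without label in input tree")
            return Node(dnode.taxon.label, dnode.edge.length)
        nn = Node(length=dnode.edge.length)
        raw = dnode.label
        if raw is not None:
            try:
                nn.support = float(raw)
            except (TypeError, ValueError):
                nn.label = raw
        for ch in dnode.child_nodes():
            nn.add(convert(ch))
        return nn

    return RootedTopology(convert(dtree.seed_node))


def parse_newick(text: str) -> RootedTopology:
    """Parse a (possibly multifurcating) Newick string into a topology."""
    if ";" not in text:
        raise NewickParseError("Newick string lacks terminating ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _quote(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: RootedTopology, lengths: bool = False,
                 supports: bool = False) -> str:
    """Serialise a topology; canonical order makes output deterministic."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            s = _quote(node.label)
        else:
            s = "(" + ",".join(fmt(ch) for ch in node.children) + ")"
            if supports and node.support is not None:
                s += format(node.support, "g")
        if lengths and node.length is not None:
            s += f":{node.length:g}"
        return s

    return fmt(tree.root) + ";"


@dataclass
class TreeSample:
    """An ordered, optionally weighted multiset of topologies on one taxon set."""

    trees: list
    weights: list = field(default=None)  # type: ignore[assignment]
    source: str = "unknown"

    def __post_init__(self):
        if not self.trees:
            raise ValidationError("tree sample is empty")
        if self.weights is None:
            self.weights = [1.0] * len(self.trees)
        if len(self.weights) != len(self.trees):
            raise ValidationError("one weight per tree required")
        if any(w <= 0 for w in self.weights):
            raise ValidationError("weights must be positive")
        taxa = self.trees[0].taxa
        for t in self.trees[1:]:
            if t.taxa != taxa:
                raise ValidationError("all trees in a sample must share one tip set")

    @property
    def taxa(self) -> frozenset:
        return self.trees[0].taxa

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights))


def read_trees_nexus(text: str, burnin_frac: float = 0.0,
                     source: str = "unknown") -> TreeSample:
    """Read all trees from a NEXUS TREES block (TRANSLATE table honoured).

    Trees flagged ``[&U]`` are accepted but interpreted as rooted, with a
    warning; MrBayes ``.t`` files routinely carry that flag.  ``burnin_frac``
    drops the given leading fraction of the sample before returning.
    """
    if not 0.0 <= burnin_frac < 1.0:
        raise DomainError("burnin_frac must be in [0, 1)")
    try:
        tl = dendropy.TreeList.get(data=text, schema="nexus",
                                   preserve_underscores=True)
    except Exception as exc:
        raise NewickParseError(f"cannot read NEXUS trees: {exc}") from exc
    if len(tl) == 0:
        raise ValidationError("no trees found (missing or empty TREES block)")
    if any(t.is_rooted is False for t in tl):
        warnings.warn("input contains trees flagged as unrooted ([&U]); "
                      "interpreting them as rooted", stacklevel=2)
    trees = [_from_dendropy(t) for t in tl]
    start = int(len(trees) * burnin_frac)
    trees = trees[start:] or trees[-1:]
    return TreeSample(trees=trees, source=source)


def read_tree_sample(text: str, burnin_frac: float = 0.0,
                     source: str = "unknown") -> TreeSample:
    """Sniff NEXUS vs Newick and return a TreeSample.

    Newick input may hold several semicolon-terminated trees, one per line.
    """
    if text.lstrip().upper().startswith("#NEXUS"):
        return read_trees_nexus(text, burnin_frac=burnin_frac, source=source)
    trees = [parse_newick(chunk + ";")
             for chunk in text.split(";") if chunk.strip()]
    if not trees:
        raise ValidationError("no trees found in input")
    start = int(len(trees) * burnin_frac)
    return TreeSample(trees=trees[start:] or trees[-1:], source=source)
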