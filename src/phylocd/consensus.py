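"""Summary-tree construction: clade frequencies and majority-rule consensus.

The majority-rule consensus of a tree sample ("half-compatibility" tree
when the sample is a Bayesian posterior) contains exactly the clades
whose weighted frequency strictly exceeds the threshold.  Strictly
greater than 0.5 guarantees pairwise compatibility; clades at exactly
the threshold can be mutually incompatible, so including them is opt-in
(``include_ties``) and resolved greedily by frequency, then first
occurrence, adding only clades compatible with those already accepted.
"""

from __future__ import annotations

from .errors import DomainError
from .trees import Node, RootedTopology, TreeSample

__all__ = ["clade_frequencies", "majority_rule", "tree_from_clades"]

_EPS = 1e-9


def clade_frequencies(sample: TreeSample) -> dict:
    """Weighted frequency of every nontrivial clade seen in the sample."""
    total = sample.total_weight
    counts: dict = {}
    order: dict = {}
    for idx, (tree, w) in enumerate(zip(sample.trees, sample.weights)):
        for clade in tree.nontrivial_clades():
            counts[clade] = counts.get(clade, 0.0) + w
            order.setdefault(clade, idx)
    freqs = {clade: c / total for clade, c in counts.items()}
    # deterministic order: first occurrence in the sample, then labels
    # (guards against per-run set/hash iteration differences)
    freqs = dict(sorted(freqs.items(),
                        key=lambda kv: (order[kv[0]], sorted(kv[0]))))
    return freqs


def _compatible(c1: frozenset, c2: frozenset) -> bool:
    return not (c1 & c2) or c1 <= c2 or c2 <= c1


def tree_from_clades(taxa, clades, supports=None) -> RootedTopology:
    """Build the rooted topology containing exactly the given clades.

    Clades must be pairwise compatible, nontrivial, and proper subsets of
    ``taxa``.  ``supports`` optionally maps clade -> frequency annotation.
    """
    taxa = frozenset(taxa)
    clades = list(clades)
    for c in clades:
        if not 2 <= len(c) < len(taxa):
            raise DomainError(f"clade of size {len(c)} is trivial here")
        if not c <= taxa:
            raise DomainError("clade not a subset of the taxon set")
    for i, c1 in enumerate(clades):
        for c2 in clades[i + 1:]:
            if not _compatible(c1, c2):
                raise DomainError("clades are not pairwise compatible")

    ordered = sorted(set(clades), key=lambda c: (-len(c), sorted(c)))
    root = Node()
    node_for = {taxa: root}
    placed = [taxa]
    for clade in ordered:
        parent_clade = min((p for p in placed if clade < p), key=len)
        nd = node_for[parent_clade].add(Node())
        if supports is not None and clade in supports:
            nd.support = float(supports[clade])
        node_for[clade] = nd
        placed.append(clade)
    for tip in taxa:
        parent_clade = min((p for p in placed if tip in p), key=len)
        node_for[parent_clade].add(Node(tip))
    return RootedTopology(root)


def majority_rule(sample: TreeSample, threshold: float = 0.5,
                  include_ties: bool = False) -> RootedTopology:
    """Majority-rule consensus of a sample of rooted topologies.

    Keeps clades with frequency strictly greater than ``threshold``
    (>= 0.5).  With ``include_ties`` clades at exactly the threshold are
    greedily admitted when compatible, mimicking half-compatibility
    conventions of common inference software.  Clade frequencies are
    attached to the consensus nodes as support annotations.
    """
    if threshold < 0.5:
        raise DomainError("threshold must be at least 0.5")
    freqs = clade_frequencies(sample)
    kept = [c for c, f in freqs.items() if f > threshold + _EPS]
    if include_ties:
        ties = [c for c, f in freqs.items()
                if abs(f - threshold) <= _EPS and c not in kept]
        # order: frequency desc, then first occurrence in the sample
        for c in sorted(ties, key=lambda c: -freqs[c]):
            if all(_compatible(c, k) for k in kept):
                kept.append(c)
    return tree_from_clades(sample.taxa, kept, supports=freqs)
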