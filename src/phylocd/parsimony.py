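"""Parsimony lengths on (possibly polytomous) rooted trees, consistency
indices, and a small-instance exhaustive maximum-parsimony oracle.

Lengths are exact minima over all internal-node state assignments,
computed by unit-cost dynamic programming over the given tree — the
multifurcation-safe generalisation of the classic two-pass method.
Polytomies are treated as hard: changes are counted on the tree as
given.  Tips with absent data carry the full state set and never force
changes, which is also why heavily incomplete characters can show
artificially inflated consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .characters import CharacterMatrix, INAPPLICABLE, MISSING
from .errors import DomainError, ValidationError
from .trees import Node, RootedTopology

__all__ = ["parsimony_length", "min_steps", "consistency_index",
           "CIReport", "ci_report", "exhaustive_mp_search",
           "enumerate_rooted_topologies"]

_INF = float("inf")


def _observed_states(values: Mapping[str, str]) -> list:
    return sorted({v for v in values.values()
                   if v not in (MISSING, INAPPLICABLE)})


def parsimony_length(tree: RootedTopology, values: Mapping[str, str],
                     strict: bool = False) -> int:
    """Minimum number of unordered state changes for one character.

    ``values`` maps taxon label -> state symbol (``?``/``-`` = absent).
    Tips of the tree not present in ``values`` are treated as absent
    data; taxa in ``values`` missing from the tree are ignored unless
    ``strict`` is set.
    """
    if strict:
        extra = set(values) - tree.taxa
        if extra:
            raise ValidationError(
                f"taxa not on the tree: {sorted(extra)}")
    states = _observed_states(values)
    if len(states) <= 1:
        return 0
    index = {s: k for k, s in enumerate(states)}
    nstates = len(states)

    cost: dict[Node, list] = {}
    for nd in tree.root.postorder():
        if nd.is_tip:
            v = values.get(nd.label, MISSING)
            if v in (MISSING, INAPPLICABLE) or v not in index:
                cost[nd] = [0.0] * nstates
            else:
                cost[nd] = [0.0 if k == index[v] else _INF
                            for k in range(nstates)]
        else:
            acc = [0.0] * nstates
            for ch in nd.children:
                c = cost[ch]
                best = min(c)
                for k in range(nstates):
                    acc[k] += min(c[k], best + 1.0)
            cost[nd] = acc
    return int(min(cost[tree.root]))


def min_steps(values: Mapping[str, str]) -> int:
    """Minimum conceivable steps for a character on any tree:
    (number of distinct observed states) - 1, floored at 0."""
    return max(0, len(_observed_states(values)) - 1)


def consistency_index(tree: RootedTopology, values: Mapping[str, str]):
    """ci = m / s for one character; None when s = 0 (undefined)."""
    s = parsimony_length(tree, values)
    if s == 0:
        return None
    return min_steps(values) / s


@dataclass
class CIReport:
    """Per-character and ensemble consistency on a fixed topology.

    ``rows`` holds ``(id, m, s, ci)`` tuples (ci None when s = 0);
    ``ensemble_ci`` is sum(m)/sum(s) over the characters with s > 0.
    ``autapomorphic`` and ``uninformative_excluded`` flag columns whose
    high/undefined consistency is structural rather than evidential.
    """

    rows: list = field(default_factory=list)
    ensemble_ci: float | None = None
    autapomorphic: list = field(default_factory=list)
    uninformative_excluded: list = field(default_factory=list)

    def per_character(self) -> dict:
        return {cid: ci for cid, _, _, ci in self.rows}

    def to_tsv(self) -> str:
        lines = ["character\tm\ts\tci"]
        for cid, m, s, ci in self.rows:
            lines.append(f"{cid}\t{m}\t{s}\t"
                         + ("NA" if ci is None else f"{ci:.4f}"))
        if self.ensemble_ci is not None:
            lines.append(f"ensemble\t\t\t{self.ensemble_ci:.4f}")
        return "\n".join(lines) + "\n"


def ci_report(tree: RootedTopology, matrix: CharacterMatrix,
              subset: Iterable[int] | None = None,
              exclude_ids: Iterable[int] = ()) -> CIReport:
    """Consistency-index profile of a matrix on one topology.

    ``subset`` selects character ids (1-based, default all);
    ``exclude_ids`` removes listed ids from the selection.  Characters
    with s = 0 (at most one observed state on the tree) are excluded
    from the ensemble sums and flagged.
    """
    wanted = set(subset) if subset is not None \
        else {c.id for c in matrix.columns}
    wanted -= set(exclude_ids)
    positions = [j for j, c in enumerate(matrix.columns) if c.id in wanted]
    if not positions:
        raise DomainError("empty character subset")
    report = CIReport()
    sum_m = sum_s = 0
    for j in positions:
        cid = matrix.columns[j].id
        vals = {t: v for t, v in matrix.to_mapping(j).items() if t in tree.taxa}
        m = min_steps(vals)
        s = parsimony_length(tree, vals)
        ci = None if s == 0 else m / s
        report.rows.append((cid, m, s, ci))
        if s == 0:
            report.uninformative_excluded.append(cid)
        else:
            sum_m += m
            sum_s += s
            counts: dict = {}
            for v in vals.values():
                if v not in (MISSING, INAPPLICABLE):
                    counts[v] = counts.get(v, 0) + 1
            if sum(1 for c in counts.values() if c >= 2) < 2:
                report.autapomorphic.append(cid)
    if sum_s == 0:
        raise DomainError("no character in the subset has observed steps")
    report.ensemble_ci = sum_m / sum_s
    return report


# ---------------------------------------------------------------------------
# exhaustive search oracle
# ---------------------------------------------------------------------------

def _insertions(shape, label) -> Iterator:
    """All ways to attach ``label`` on an edge of (or above) ``shape``.

    Shapes are nested tuples; a leaf is its label string.
    """
    yield (shape, label)
    if isinstance(shape, tuple):
        for i, child in enumerate(shape):
            for sub in _insertions(child, label):
                yield shape[:i] + (sub,) + shape[i + 1:]


def _shapes(labels: Sequence[str]) -> Iterator:
    if len(labels) == 1:
        yield labels[0]
        return
    for smaller in _shapes(labels[:-1]):
        yield from _insertions(smaller, labels[-1])


def _shape_to_tree(shape) -> RootedTopology:
    def build(s) -> Node:
        if isinstance(s, str):
            return Node(s)
        nd = Node()
        for child in s:
            nd.add(build(child))
        return nd

    return RootedTopology(build(shape))


def enumerate_rooted_topologies(labels: Iterable[str]) -> Iterator[RootedTopology]:
    """Yield every fully resolved rooted topology on the given tips
    ((2n-3)!! of them)."""
    labels = sorted(labels)
    if len(labels) < 2:
        raise DomainError("need at least 2 labels")
    for shape in _shapes(labels):
        yield _shape_to_tree(shape)


def matrix_length(tree: RootedTopology, matrix: CharacterMatrix) -> int:
    """Total parsimony length of a matrix on a tree."""
    return sum(parsimony_length(tree, matrix.to_mapping(j))
               for j in range(matrix.n_columns))


def exhaustive_mp_search(matrix: CharacterMatrix, max_tips: int = 7):
    """Global maximum-parsimony search by complete enumeration.

    Returns ``(best_length, optima)`` where ``optima`` lists every
    fully resolved rooted topology attaining the optimum.  Guarded by
    ``max_tips`` — this is a test oracle, not an inference tool.
    """
    if matrix.n_taxa > max_tips:
        raise DomainError(
            f"{matrix.n_taxa} taxa exceeds max_tips={max_tips}")
    if matrix.n_taxa < 3:
        raise DomainError("need at least 3 taxa")
    best = None
    optima: list = []
    for tree in enumerate_rooted_topologies(matrix.taxa):
        length = matrix_length(tree, matrix)
        if best is None or length < best:
            best, optima = length, [tree]
        elif length == best:
            optima.append(tree)
    return best, optima
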