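"""Contradiction-difference (CD): conflict between two summary topologies.

CD counts, after pruning both trees to their shared tips, how many
nontrivial clades of each tree are contradicted by at least one clade of
the other, and normalises by ``2 * (n_shared - 2)`` — the largest number
of conflicts two fully resolved rooted trees on ``n_shared`` tips can
show.  CD is symmetric, lies in [0, 1], and deliberately ignores
differences that are due only to lack of resolution: a star tree is at
CD 0 from every topology on the same taxa.  It is not a metric (the
triangle inequality fails by design).

Two conflict readings are offered.  ``rooted`` (default) treats clades
as rooted: two clades conflict iff they overlap and neither nests inside
the other.  ``unrooted`` treats them as splits: conflict additionally
requires taxa outside the union, so complementary nestings are
compatible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DomainError, ValidationError
from .trees import RootedTopology

__all__ = ["CDResult", "CDMatrix", "clades_conflict",
           "contradiction_difference", "cd_matrix"]

_MODES = ("rooted", "unrooted")


@dataclass(frozen=True)
class CDResult:
    """Outcome of one pairwise CD computation."""

    n_shared: int
    n_ab: int
    n_ba: int
    denominator: int
    cd: float
    mode: str

    def __post_init__(self):
        assert self.denominator == 2 * (self.n_shared - 2)
        assert math.isclose(self.cd, (self.n_ab + self.n_ba) / self.denominator)

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.cd, ndigits)


def clades_conflict(c1: frozenset, c2: frozenset, full_taxa: frozenset,
                    mode: str = "rooted") -> bool:
    """Do two nontrivial clades actively contradict each other?"""
    if mode not in _MODES:
        raise DomainError(f"mode must be one of {_MODES}")
    full_taxa = frozenset(full_taxa)
    for c in (c1, c2):
        if not c <= full_taxa:
            raise ValidationError("clade is not a subset of the taxon set")
        if not 2 <= len(c) <= len(full_taxa) - 1:
            raise ValidationError("clade is trivial for this taxon set")
    if not (c1 & c2):
        return False
    if c1 <= c2 or c2 <= c1:
        return False
    if mode == "unrooted":
        # as splits, conflict additionally needs taxa outside both
        return bool(full_taxa - (c1 | c2))
    return True


def _conflicting_count(clades_a, clades_b, full_taxa, mode) -> int:
    return sum(
        1 for ca in clades_a
        if any(clades_conflict(ca, cb, full_taxa, mode) for cb in clades_b)
    )


def contradiction_difference(tree_a: RootedTopology, tree_b: RootedTopology,
                             mode: str = "rooted") -> CDResult:
    """CD between two rooted topologies (pruned to their shared tips)."""
    if mode not in _MODES:
        raise DomainError(f"mode must be one of {_MODES}")
    shared = tree_a.taxa & tree_b.taxa
    n = len(shared)
    if n < 3:
        raise DomainError(
            f"CD requires at least 3 shared tips, got {n}")
    if shared != tree_a.taxa:
        tree_a = tree_a.prune_to_taxa(shared)
    if shared != tree_b.taxa:
        tree_b = tree_b.prune_to_taxa(shared)
    clades_a = tree_a.nontrivial_clades()
    clades_b = tree_b.nontrivial_clades()
    n_ab = _conflicting_count(clades_a, clades_b, shared, mode)
    n_ba = _conflicting_count(clades_b, clades_a, shared, mode)
    denom = 2 * (n - 2)
    return CDResult(n_shared=n, n_ab=n_ab, n_ba=n_ba, denominator=denom,
                    cd=(n_ab + n_ba) / denom, mode=mode)


class CDMatrix:
    """Symmetric matrix of pairwise CD results over labelled topologies.

    Pairs sharing fewer than 3 tips are *undefined* (NaN in renderings),
    never silently 0.
    """

    def __init__(self, labels: Sequence[str], results: dict, mode: str):
        self.labels = list(labels)
        self.results = results  # (i, j) i<j -> CDResult | None
        self.mode = mode

    def cd(self, a: str, b: str):
        if a == b:
            return 0.0
        i, j = sorted((self.labels.index(a), self.labels.index(b)))
        res = self.results[(i, j)]
        return None if res is None else res.cd

    def to_dataframe(self, ndigits: int | None = None) -> pd.DataFrame:
        k = len(self.labels)
        df = pd.DataFrame(0.0, index=self.labels, columns=self.labels)
        for (i, j), res in self.results.items():
            v = float("nan") if res is None else res.cd
            df.iat[i, j] = v
            df.iat[j, i] = v
        if ndigits is not None:
            df = df.round(ndigits)
        return df

    def to_tsv(self, ndigits: int = 2) -> str:
        """Upper-triangle rendering, values rounded (2 decimals by default)."""
        lines = ["\t".join([""] + self.labels[1:])]
        for i, lab in enumerate(self.labels[:-1]):
            row = [lab]
            for j in range(1, len(self.labels)):
                if j <= i:
                    row.append("")
                else:
                    res = self.results[(i, j)]
                    row.append("NA" if res is None
                               else f"{res.cd:.{ndigits}f}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def cd_matrix(trees, mode: str = "rooted",
              strict: bool = False) -> CDMatrix:
    """Pairwise CD over a labelled collection of topologies.

    ``trees`` is a mapping label -> RootedTopology or a sequence of
    ``(label, tree)`` pairs.  With ``strict=True`` a pair sharing fewer
    than 3 tips raises instead of being recorded as undefined.
    """
    if hasattr(trees, "items"):
        items = list(trees.items())
    else:
        items = list(trees)
    if len(items) < 2:
        raise DomainError("need at least 2 labelled trees")
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValidationError("tree labels must be unique")
    results: dict = {}
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            try:
                results[(i, j)] = contradiction_difference(
                    items[i][1], items[j][1], mode=mode)
            except DomainError:
                if strict:
                    raise
                results[(i, j)] = None
    return CDMatrix(labels, results, mode)
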