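"""Homoplasy-free binary characters that perfectly support a topology.

For sensitivity analyses: every internal, non-root node whose clade is
parsimony-informative as a binary character (size 2 .. n-2) is eligible
to receive single-shift characters.  ``n_chars`` characters are spread
as evenly as possible over the eligible nodes; the remainder that cannot
be placed evenly is allocated to nodes drawn uniformly without
replacement, which is the only stochastic step.  Each character scores
one state change (ci = 1) on the generating tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .characters import CharacterMatrix, Column, combine_partitions, write_nexus
from .errors import DomainError, ValidationError
from .trees import RootedTopology

__all__ = ["AllocationPlan", "eligible_clades", "plan_allocation",
           "generate_perfect_matrix", "sensitivity_workflow"]


def eligible_clades(tree: RootedTopology) -> list:
    """Clades of internal non-root nodes with size in [2, n-2], in
    deterministic (size, labels) order.

    Size n-1 is excluded: the corresponding binary character would be
    autapomorphic for the lone outside taxon, hence uninformative.
    """
    n = tree.n_tips
    clades = [c for c in tree.nontrivial_clades() if len(c) <= n - 2]
    return sorted(clades, key=lambda c: (len(c), sorted(c)))


@dataclass(frozen=True)
class AllocationPlan:
    """How many single-shift characters each eligible node receives."""

    eligible: tuple
    counts: tuple  # aligned with `eligible`
    n_chars: int
    seed: int

    @property
    def even_quota(self) -> int:
        return self.n_chars // len(self.eligible)

    @property
    def even_total(self) -> int:
        return self.even_quota * len(self.eligible)

    @property
    def remainder(self) -> int:
        return self.n_chars - self.even_total

    def __post_init__(self):
        assert sum(self.counts) == self.n_chars
        q = self.even_quota
        assert all(c in (q, q + 1) for c in self.counts)
        assert sum(1 for c in self.counts if c == q + 1) == self.remainder


def plan_allocation(tree: RootedTopology, n_chars: int,
                    seed: int) -> AllocationPlan:
    """Spread ``n_chars`` characters over the eligible nodes of ``tree``.

    Even phase: each node gets ``n_chars // k``.  The remaining
    ``n_chars mod k`` characters go to distinct nodes chosen uniformly
    without replacement (seeded).  Deterministic in (tree, n_chars, seed).
    """
    if n_chars < 1:
        raise DomainError("n_chars must be >= 1")
    eligible = eligible_clades(tree)
    if not eligible:
        raise DomainError("tree has no eligible internal nodes (star tree?)")
    k = len(eligible)
    q, r = divmod(n_chars, k)
    counts = [q] * k
    if r:
        rng = np.random.default_rng(seed)
        for idx in rng.choice(k, size=r, replace=False):
            counts[idx] += 1
    return AllocationPlan(eligible=tuple(eligible), counts=tuple(counts),
                          n_chars=n_chars, seed=seed)


def generate_perfect_matrix(tree: RootedTopology,
                            plan: AllocationPlan,
                            partition: str = "morphological"
                            ) -> CharacterMatrix:
    """Binary matrix realising an allocation plan: per character, tips
    inside the node's clade are '1', all others '0'; no missing cells."""
    taxa = sorted(tree.taxa)
    for clade in plan.eligible:
        if not clade <= tree.taxa:
            raise ValidationError("allocation plan does not match this tree")
    cols: list = []
    for clade, count in zip(plan.eligible, plan.counts):
        cols.extend([clade] * count)
    cells = [["1" if t in clade else "0" for clade in cols] for t in taxa]
    columns = [Column(i + 1, partition) for i in range(len(cols))]
    return CharacterMatrix(taxa, cells, columns, {partition: "01"})


def sensitivity_workflow(base_tree: RootedTopology, n_chars: int,
                         molecular: CharacterMatrix, n_replicates: int,
                         seed: int) -> list:
    """Generate the combined datasets for a perfect-character sensitivity
    analysis: per replicate, a fresh remainder placement (seed + index),
    a perfect binary matrix on ``base_tree``, combined with the molecular
    partition.  Downstream inference is external; returns the list of
    combined matrices (export with :func:`to_nexus_files`).
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    missing_taxa = base_tree.taxa - set(molecular.taxa)
    if missing_taxa:
        raise ValidationError(
            f"tree tips absent from the molecular matrix: "
            f"{sorted(missing_taxa)}")
    combined = []
    for rep in range(n_replicates):
        plan = plan_allocation(base_tree, n_chars, seed + rep)
        morph = generate_perfect_matrix(base_tree, plan)
        combined.append(combine_partitions(morph, molecular))
    return combined


def to_nexus_files(matrices: Sequence[CharacterMatrix], directory,
                   stem: str = "replicate",
                   mrbayes_block: bool = True) -> list:
    """Write one analysis-ready NEXUS file per matrix; returns paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, m in enumerate(matrices, start=1):
        p = directory / f"{stem}_{i:02d}.nex"
        p.write_text(write_nexus(m, mrbayes_block=mrbayes_block))
        paths.append(p)
    return paths
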