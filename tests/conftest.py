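"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities from first principles
(exhaustive assignment enumeration, raw set algebra) so the package's
algorithms are checked against code that shares none of their logic.
"""

from itertools import product

import pytest

from phylocd import (RootedTopology, make_study_like_dataset, parse_newick,
                     simulate_tree)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

ABSENT = {"?", "-"}


def brute_force_length(tree: RootedTopology, values: dict) -> int:
    """Minimum changes over ALL internal-node state assignments."""
    states = sorted({v for v in values.values() if v not in ABSENT})
    if len(states) <= 1:
        return 0
    internal = [nd for nd in tree.root.preorder() if not nd.is_tip]
    best = None
    for assign in product(states, repeat=len(internal)):
        amap = dict(zip(internal, assign))
        total = 0
        for nd in tree.root.preorder():
            if nd.parent is None:
                continue
            parent_state = amap[nd.parent]
            if nd.is_tip:
                v = values.get(nd.label, "?")
                if v in ABSENT:
                    continue  # absent tip never forces a change
                total += v != parent_state
            else:
                total += amap[nd] != parent_state
        if best is None or total < best:
            best = total
    return best


def oracle_conflict_rooted(c1: frozenset, c2: frozenset) -> bool:
    inter = c1 & c2
    return bool(inter) and bool(c1 - c2) and bool(c2 - c1)


def oracle_conflict_unrooted(c1, c2, taxa) -> bool:
    return (bool(c1 & c2) and bool(c1 - c2) and bool(c2 - c1)
            and bool(frozenset(taxa) - (c1 | c2)))


def oracle_cd(tree_a: RootedTopology, tree_b: RootedTopology,
              mode: str = "rooted"):
    """CD recomputed with raw set algebra (prune via clade intersection,
    not the package's tree surgery)."""
    shared = tree_a.taxa & tree_b.taxa
    n = len(shared)
    assert n >= 3

    def pruned_clades(tree):
        out = set()
        for c in tree.nontrivial_clades():
            cc = c & shared
            if 2 <= len(cc) <= n - 1:
                out.add(cc)
        return out

    ca, cb = pruned_clades(tree_a), pruned_clades(tree_b)
    if mode == "rooted":
        conflict = oracle_conflict_rooted
        n_ab = sum(1 for x in ca if any(conflict(x, y) for y in cb))
        n_ba = sum(1 for y in cb if any(conflict(y, x) for x in ca))
    else:
        n_ab = sum(1 for x in ca
                   if any(oracle_conflict_unrooted(x, y, shared) for y in cb))
        n_ba = sum(1 for y in cb
                   if any(oracle_conflict_unrooted(y, x, shared) for x in ca))
    return (n_ab + n_ba) / (2 * (n - 2))


def random_resolved_tree(n_tips: int, seed: int,
                         labels=None) -> RootedTopology:
    return simulate_tree(n_tips, model="uniform", seed=seed, labels=labels)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def caterpillar6():
    return parse_newick("(1,(2,(3,(4,(5,6)))));")


@pytest.fixture
def caterpillar6_reversed():
    return parse_newick("(6,(5,(4,(3,(2,1)))));")


@pytest.fixture(scope="session")
def study_dataset():
    """Small-but-structured study-like dataset shared across tests.

    The molecular partition is shortened (300 sites instead of 3435) to
    keep the suite fast; structural counts (taxa, coverage) are intact.
    """
    from phylocd import SyntheticConfig

    config = SyntheticConfig()
    config.n_mol_sites = 300
    return make_study_like_dataset(config, seed=42)
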