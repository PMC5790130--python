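"""Synthetic trees, tree samples, and character matrices.

Everything here exists so that the full analysis pipeline — summary
trees, contradiction differences, informativeness filtering, consistency
profiling, sensitivity workflows — can be exercised end to end without
any external download or inference software.  The study-like preset
mirrors the structure of the empirical dataset: 26 taxa of which 4 are
distant outgroups with sparse morphology, a 66-character multistate
morphological partition coded at genus level (one congeneric species
pair shares an identical morphological row), and a 3435-site nucleotide
partition available for only 18 taxa, with realistic per-taxon
missingness.

All stochastic operations require an explicit seed and are fully
reproducible from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .characters import (CharacterMatrix, Column, MISSING,
                         combine_partitions, expand_genus_to_species,
                         is_parsimony_informative)
from .errors import DomainError, ValidationError
from .trees import Node, RootedTopology, TreeSample

__all__ = ["simulate_tree", "random_nni", "perturb_tree_sample",
           "simulate_mk_matrix", "apply_missingness",
           "SyntheticConfig", "StudyLikeDataset", "make_study_like_dataset"]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, model: str = "yule", seed: int | None = None,
                  labels=None) -> RootedTopology:
    """Simulate a fully resolved rooted topology.

    ``yule``: grow by splitting a uniformly chosen extant tip.
    ``uniform``: draw uniformly over all rooted resolved topologies
    (sequential insertion on a uniformly chosen edge).
    """
    if n_tips < 3:
        raise DomainError("need at least 3 tips")
    if labels is None:
        width = len(str(n_tips))
        labels = [f"t{i + 1:0{width}d}" for i in range(n_tips)]
    labels = list(labels)
    if len(labels) != n_tips:
        raise ValidationError("label count must equal n_tips")
    rng = np.random.default_rng(seed)
    perm = [labels[i] for i in rng.permutation(n_tips)]

    if model == "yule":
        root = Node()
        tips = [root.add(Node(perm[0])), root.add(Node(perm[1]))]
        for nxt in perm[2:]:
            tip = tips[rng.integers(len(tips))]
            tips.remove(tip)
            tip.children = []
            left, right = tip.add(Node(tip.label)), tip.add(Node(nxt))
            tip.label = None
            tips += [left, right]
        return RootedTopology(root)
    if model == "uniform":
        shape = (perm[0], perm[1])
        for nxt in perm[2:]:
            edges = _count_positions(shape)
            pick = int(rng.integers(edges))
            shape = _insert_at(shape, nxt, pick)[1]
        return _shape_to_topology(shape)
    raise DomainError(f"unknown model {model!r}")


def _count_positions(shape) -> int:
    if isinstance(shape, str):
        return 1
    return 1 + sum(_count_positions(c) for c in shape)


def _insert_at(shape, label, pick):
    """Attach above the ``pick``-th position (preorder); returns
    (positions_consumed, new_shape_or_None)."""
    if pick == 0:
        return 1, (shape, label)
    used = 1
    if isinstance(shape, tuple):
        out = list(shape)
        for i, child in enumerate(shape):
            consumed, new = _insert_at(child, label, pick - used)
            used += consumed
            if new is not None:
                out[i] = new
                return used, tuple(out)
    return used, None


def _shape_to_topology(shape) -> RootedTopology:
    def build(s):
        if isinstance(s, str):
            return Node(s)
        nd = Node()
        for c in s:
            nd.add(build(c))
        return nd

    return RootedTopology(build(shape))


def random_nni(tree: RootedTopology, rng: np.random.Generator
               ) -> RootedTopology:
    """One random nearest-neighbour interchange on a resolved rooted tree:
    swap a uniformly chosen child of a non-root internal node with a
    uniformly chosen sibling of that node."""
    root = tree.copy().root
    candidates = [nd for nd in root.preorder()
                  if not nd.is_tip and nd.parent is not None]
    if not candidates:
        raise DomainError("no internal non-root nodes to rearrange")
    v = candidates[rng.integers(len(candidates))]
    p = v.parent
    siblings = [c for c in p.children if c is not v]
    s = siblings[rng.integers(len(siblings))]
    c = v.children[rng.integers(len(v.children))]
    v.children[v.children.index(c)] = s
    p.children[p.children.index(s)] = c
    s.parent, c.parent = v, p
    return RootedTopology(root)


def perturb_tree_sample(tree: RootedTopology, sample_size: int, n_nni: int,
                        seed: int | None = None, strict: bool = True
                        ) -> TreeSample:
    """Emulate a posterior/MP tree sample: each tree is the input after
    ``n_nni`` random rearrangements (0 = exact copies)."""
    if sample_size < 1:
        raise DomainError("sample_size must be >= 1")
    if n_nni < 0:
        raise DomainError("n_nni must be >= 0")
    if strict and not tree.is_resolved:
        raise ValidationError("input tree must be fully resolved")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(sample_size):
        t = tree.copy()
        for _ in range(n_nni):
            t = random_nni(t, rng)
        trees.append(t)
    return TreeSample(trees=trees, source="simulated")


# ---------------------------------------------------------------------------
# characters
# ---------------------------------------------------------------------------

def _evolve_column(tree: RootedTopology, n_states: int, rate: float,
                   rng: np.random.Generator) -> dict:
    """One character under a symmetric (Mk-style) jump process: Poisson
    change counts per edge, each change to a uniformly chosen different
    state.  Returns taxon -> state index."""
    state: dict = {}
    out: dict = {}
    for nd in tree.root.preorder():
        if nd.parent is None:
            s = int(rng.integers(n_states))
        else:
            s = state[nd.parent]
            for _ in range(rng.poisson(rate)):
                s = (s + 1 + int(rng.integers(n_states - 1))) % n_states
        state[nd] = s
        if nd.is_tip:
            out[nd.label] = s
    return out


def simulate_mk_matrix(tree: RootedTopology, n_chars: int,
                       n_states: int | Mapping[int, float] = 2,
                       expected_changes: float = 1.0,
                       seed: int | None = None,
                       condition_informative: bool = True,
                       partition: str = "morphological",
                       alphabet: str | None = None,
                       rejection_cap: int = 10000) -> CharacterMatrix:
    """Evolve unordered characters along a topology.

    The symmetric per-edge rate is scaled so the expected total number
    of changes per character is ``expected_changes``.  ``n_states`` may
    be an int or a {state_count: probability} mapping sampled per
    character.  With ``condition_informative`` (ascertainment to
    parsimony-informative characters) uninformative draws are rejected
    and redrawn, up to ``rejection_cap`` attempts per character.
    """
    if n_chars < 1:
        raise DomainError("n_chars must be >= 1")
    if expected_changes <= 0:
        raise DomainError("expected_changes must be positive")
    rng = np.random.default_rng(seed)
    n_edges = sum(1 for nd in tree.root.preorder() if nd.parent is not None)
    rate = expected_changes / n_edges

    if isinstance(n_states, Mapping):
        ks = sorted(n_states)
        probs = np.array([n_states[k] for k in ks], dtype=float)
        probs /= probs.sum()
        per_char = [int(ks[i]) for i in
                    rng.choice(len(ks), size=n_chars, p=probs)]
    else:
        per_char = [int(n_states)] * n_chars
    if min(per_char) < 2:
        raise DomainError("n_states must be >= 2")
    max_states = max(per_char)
    if alphabet is None:
        if max_states > 10:
            raise DomainError("provide an explicit alphabet for >10 states")
        alphabet = "0123456789"[:max_states]
    if len(alphabet) < max_states:
        raise DomainError("alphabet smaller than requested state count")

    taxa = sorted(tree.taxa)
    rows = {t: [] for t in taxa}
    for k in per_char:
        for attempt in range(rejection_cap):
            col = _evolve_column(tree, k, rate, rng)
            vals = [alphabet[col[t]] for t in taxa]
            if not condition_informative or is_parsimony_informative(vals):
                break
        else:
            raise DomainError(
                "rejection cap exceeded while conditioning on "
                "parsimony-informative characters (rate too low?)")
        for t, v in zip(taxa, vals):
            rows[t].append(v)
    columns = [Column(i + 1, partition) for i in range(n_chars)]
    return CharacterMatrix(taxa, [rows[t] for t in taxa], columns,
                           {partition: alphabet})


def apply_missingness(matrix: CharacterMatrix, fractions: Mapping,
                      seed: int | None = None,
                      mode: str = "iid") -> CharacterMatrix:
    """Mask cells to MISSING at per-taxon (optionally per-partition) rates.

    ``fractions`` maps taxon -> fraction, or taxon -> {partition:
    fraction}.  ``iid`` masks cells independently; ``block`` deletes one
    contiguous run of the partition's columns per taxon (emulating e.g.
    a large deletion in an alignment).
    """
    if mode not in ("iid", "block"):
        raise DomainError("mode must be 'iid' or 'block'")
    unknown = set(fractions) - set(matrix.taxa)
    if unknown:
        raise ValidationError(f"unknown taxa in profile: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cells = [list(row) for row in matrix.cells]
    part_pos = {p: [j for j, c in enumerate(matrix.columns)
                    if c.partition == p] for p in matrix.partitions}
    for taxon, frac in fractions.items():
        i = matrix.taxa.index(taxon)
        per_part = frac if isinstance(frac, Mapping) \
            else {p: frac for p in matrix.partitions}
        for part, f in per_part.items():
            if part not in part_pos:
                raise ValidationError(f"unknown partition {part!r}")
            if not 0.0 <= f <= 1.0:
                raise DomainError("missingness fraction outside [0, 1]")
            pos = part_pos[part]
            if f == 0.0:
                continue
            if mode == "iid":
                mask = rng.random(len(pos)) < f
                for j, hit in zip(pos, mask):
                    if hit:
                        cells[i][j] = MISSING
            else:
                run = int(round(f * len(pos)))
                if run == 0:
                    continue
                start = int(rng.integers(len(pos) - run + 1))
                for j in pos[start:start + run]:
                    cells[i][j] = MISSING
    return CharacterMatrix(matrix.taxa, cells, matrix.columns,
                           matrix.alphabets)


# ---------------------------------------------------------------------------
# study-like preset
# ---------------------------------------------------------------------------

def _default_genera():
    inarticulates = [f"inart{i}" for i in range(1, 5)]
    terebratulides = ["tereb1", "tereb2"]
    rhynchonellides = [f"rhyn{i:02d}" for i in range(1, 20)]
    return inarticulates, terebratulides, rhynchonellides


@dataclass
class SyntheticConfig:
    """Shape of a study-like synthetic dataset (defaults mirror the
    empirical study: 26 taxa, 66 morphological characters, 3435 sites
    for 18 taxa, one congeneric pair with identical morphology)."""

    n_morph_chars: int = 66
    morph_state_distribution: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.65, 3: 0.25, 4: 0.10})
    n_mol_sites: int = 3435
    morph_expected_changes: float = 2.5
    mol_expected_changes: float = 0.6
    condition_morph_informative: bool = True
    sample_size: int = 25
    sample_n_nni: Mapping[str, int] = field(
        default_factory=lambda: {"morphology": 3, "molecular": 1,
                                 "combined": 1})
    genera: tuple = field(default_factory=_default_genera)
    congeneric_genus: str = "rhyn01"
    congeneric_species: tuple = ("rhyn01_spA", "rhyn01_spB")
    #: per-genus morphological missingness (applied before the congeneric
    #: expansion, so both species inherit one identical row)
    morph_missing: Mapping[str, float] = field(default_factory=lambda: {
        "inart1": 0.72, "inart2": 0.77, "inart3": 0.71, "inart4": 0.68,
        "tereb1": 0.12, "tereb2": 0.17,
        "rhyn01": 0.11, "rhyn02": 0.12,
        "rhyn03": 0.17, "rhyn04": 0.05, "rhyn05": 0.08, "rhyn06": 0.06,
        "rhyn07": 0.00, "rhyn08": 0.05, "rhyn09": 0.06, "rhyn10": 0.00,
        "rhyn11": 0.18, "rhyn12": 0.11, "rhyn13": 0.06, "rhyn14": 0.00,
        "rhyn15": 0.11, "rhyn16": 0.08, "rhyn17": 0.06, "rhyn18": 0.11,
        "rhyn19": 0.06})
    mol_missing: Mapping[str, float] = field(default_factory=lambda: {
        "inart1": 0.00, "inart2": 0.26, "inart3": 0.26, "inart4": 0.26,
        "tereb1": 0.00, "tereb2": 0.00,
        "rhyn01_spA": 0.41, "rhyn01_spB": 0.46, "rhyn02": 0.51,
        "rhyn03": 0.00, "rhyn04": 0.66, "rhyn05": 0.01, "rhyn06": 0.26,
        "rhyn07": 0.51, "rhyn08": 0.00, "rhyn09": 0.26, "rhyn10": 0.27,
        "rhyn11": 0.42})

    @property
    def genus_labels(self) -> list:
        inart, tereb, rhyn = self.genera
        return list(inart) + list(tereb) + list(rhyn)

    @property
    def species_map(self) -> dict:
        return {self.congeneric_genus: list(self.congeneric_species)}

    @property
    def species_labels(self) -> list:
        out = []
        for g in self.genus_labels:
            out.extend(self.species_map.get(g, [g]))
        return out

    @property
    def molecular_taxa(self) -> list:
        return sorted(self.mol_missing)

    def validate(self) -> None:
        if not set(self.molecular_taxa) <= set(self.species_labels):
            raise ValidationError("molecular coverage is not a taxon subset")
        if self.congeneric_genus not in self.genus_labels:
            raise ValidationError("congeneric genus not among genera")
        if not set(self.morph_missing) <= set(self.genus_labels):
            raise ValidationError("morph_missing must be keyed by genera")
        for prof in (self.morph_missing, self.mol_missing):
            if any(not 0 <= f <= 1 for f in prof.values()):
                raise ValidationError("missingness fractions outside [0, 1]")


@dataclass
class StudyLikeDataset:
    """Everything downstream modules need, generated from one seed."""

    species_tree: RootedTopology
    genus_tree: RootedTopology
    morphological: CharacterMatrix   # species rows, genus-level coding
    molecular: CharacterMatrix       # molecular-coverage taxa only
    combined: CharacterMatrix
    samples: dict                    # analysis tag -> TreeSample
    config: SyntheticConfig
    seed: int


def make_study_like_dataset(config: SyntheticConfig | None = None,
                            seed: int = 0) -> StudyLikeDataset:
    """Build a full synthetic dataset with the study's data structure."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    seeds = iter(rng.integers(0, 2**31 - 1, size=16))

    genus_tree = simulate_tree(len(config.genus_labels), "yule",
                               int(next(seeds)), labels=config.genus_labels)
    # species tree: replace the congeneric genus tip by a cherry
    species_root = genus_tree.copy().root
    for nd in species_root.preorder():
        if nd.is_tip and nd.label == config.congeneric_genus:
            nd.label = None
            for sp in config.congeneric_species:
                nd.add(Node(sp))
            break
    species_tree = RootedTopology(species_root)

    morph_genus = simulate_mk_matrix(
        genus_tree, config.n_morph_chars,
        n_states=dict(config.morph_state_distribution),
        expected_changes=config.morph_expected_changes,
        seed=int(next(seeds)),
        condition_informative=config.condition_morph_informative,
        partition="morphological")
    morph_genus = apply_missingness(morph_genus, dict(config.morph_missing),
                                    seed=int(next(seeds)))
    morph = expand_genus_to_species(morph_genus, config.species_map)

    mol_tree = species_tree.prune_to_taxa(config.molecular_taxa)
    mol = simulate_mk_matrix(
        mol_tree, config.n_mol_sites, n_states=4,
        expected_changes=config.mol_expected_changes,
        seed=int(next(seeds)), condition_informative=False,
        partition="molecular", alphabet="ACGT")
    mol = apply_missingness(mol, dict(config.mol_missing),
                            seed=int(next(seeds)))

    combined = combine_partitions(morph, mol)

    samples = {}
    for tag, n_nni in config.sample_n_nni.items():
        base = mol_tree if tag == "molecular" else species_tree
        samples[tag] = perturb_tree_sample(
            base, config.sample_size, n_nni, seed=int(next(seeds)))

    return StudyLikeDataset(species_tree=species_tree, genus_tree=genus_tree,
                            morphological=morph, molecular=mol,
                            combined=combined, samples=samples,
                            config=config, seed=seed)
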