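# phylocd

Tools for quantifying *active* disagreement between phylogenetic summary
topologies, and for the character-level analyses that usually accompany
that question.

The centrepiece is the **contradiction difference (CD)**: after pruning
two rooted trees to their shared tips, CD counts how many nontrivial
clades of each tree are contradicted by at least one clade of the other,
normalised by `2·(n_shared − 2)` — the maximum possible number of
conflicts between two fully resolved rooted trees. Unlike
Robinson–Foulds, CD deliberately ignores differences that are due only
to lack of resolution: a star tree is at distance 0 from everything, so
poorly resolved consensus trees are not penalised for what they decline
to say. CD is symmetric and bounded in [0, 1], but intentionally not a
metric (the triangle inequality fails).

Around this, the package provides:

- **`phylocd.trees`** — rooted-topology model (polytomies allowed,
  branch lengths ignored), Newick and NEXUS `TREES` I/O (TRANSLATE
  tables, MrBayes/PAUP dialects), pruning, clade extraction.
- **`phylocd.contradiction`** — pairwise CD and labelled CD matrices
  with upper-triangle TSV rendering; a rooted-clade conflict reading
  (default) and an unrooted-split reading.
- **`phylocd.consensus`** — clade frequencies and majority-rule
  ("half-compatibility") consensus of weighted tree samples, with a
  greedy tie-inclusion option at the threshold.
- **`phylocd.characters`** — NEXUS `DATA`/`CHARACTERS` matrices with
  `?`/`-` handling, CHARSET partitions, parsimony-informativeness
  filtering (stable 1-based character ids), missing-data percentage
  reports, column replication (integer weighting), genus→species row
  expansion, and partition combination for total-evidence exports.
- **`phylocd.parsimony`** — exact parsimony lengths on multifurcating
  trees (unit-cost DP), per-character and ensemble consistency indices,
  and an exhaustive maximum-parsimony oracle for small taxon sets.
- **`phylocd.perfect`** — homoplasy-free, parsimony-informative binary
  characters that perfectly support a chosen topology, allocated as
  evenly as possible over the eligible nodes (seeded random placement of
  the remainder), plus the combined-dataset sensitivity workflow.
- **`phylocd.simulate`** — Yule/uniform topology simulation, NNI
  perturbation samples standing in for posterior/MP samples, symmetric
  Mk-style character simulation with optional ascertainment to
  informative characters, per-taxon missingness profiles, and a
  `make_study_like_dataset` preset (26 taxa, 66 morphological
  characters, 3435 sites for 18 taxa, one congeneric pair with identical
  morphology) so every pipeline stage runs fully offline.

## Command line

All functionality is exposed through one entry point:

```sh
phylocd cd a.nwk b.nwk                    # one CD value (add --json for detail)
phylocd cd-matrix trees/*.nwk -o cd.tsv   # upper-triangle table, 2 decimals
phylocd consensus posterior.t --burnin-frac 0.25 --include-ties
phylocd informative matrix.nex --taxa A,B,C
phylocd matrix-info matrix.nex -o missing.tsv
phylocd ci summary.nwk matrix.nex --chars 1,3,6-8
phylocd perfect-chars base.nwk -n 54 --seed 1 --replicates 10 -o out/
phylocd sensitivity base.nwk molecular.nex --seed 1 -o out/
phylocd simulate --preset study-like --seed 1 -o synth/
```

Stochastic subcommands require `--seed`. Runs can write a JSON manifest
(`--manifest run.json`) recording inputs with SHA-256 hashes,
parameters, seed, and package version, sufficient to reproduce the run.

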