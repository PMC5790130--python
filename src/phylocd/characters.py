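"""Discrete character matrices: NEXUS I/O, informativeness filtering,
missing-data accounting, replication weighting, and partition handling.

Cells hold single state symbols, ``?`` (MISSING) or ``-`` (INAPPLICABLE).
The two non-state codes are preserved distinctly for round-tripping but
are treated identically — as absent data — by every computation here and
downstream (informativeness, parsimony, missingness percentages).
Symbols outside a partition's declared state alphabet (IUPAC ambiguity
codes in nucleotide data, for instance) are stored verbatim but likewise
count as missing.

Character ids are 1-based and stable: filtering reports dropped ids and
survivors keep their original ids, so published per-character lists stay
addressable after any amount of subsetting.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import DomainError, ValidationError

__all__ = [
    "MISSING", "INAPPLICABLE", "Column", "CharacterMatrix",
    "read_nexus_matrix", "write_nexus", "is_parsimony_informative",
    "filter_informative", "missing_percentages", "replicate_columns",
    "expand_genus_to_species", "combine_partitions",
]

MISSING = "?"
INAPPLICABLE = "-"

#: symbols tolerated (and treated as missing) in nucleotide partitions
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVNX")

_DNA_TYPES = {"dna", "rna", "nucleotide"}


@dataclass(frozen=True)
class Column:
    """Per-column metadata.  ``source_id`` tracks provenance through
    replication/combination; characters are always unordered here."""

    id: int
    partition: str = "morphological"
    source_id: int | None = None


class CharacterMatrix:
    """Rectangular taxa x characters matrix of discrete states."""

    def __init__(self, taxa: Sequence[str], cells: Sequence[Sequence[str]],
                 columns: Sequence[Column] | None = None,
                 alphabets: Mapping[str, str] | None = None):
        self.taxa = list(taxa)
        self.cells = [list(map(str, row)) for row in cells]
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels in matrix")
        if len(self.cells) != len(self.taxa):
            raise ValidationError("one row per taxon required")
        ncol = len(self.cells[0]) if self.cells else 0
        if any(len(r) != ncol for r in self.cells):
            raise ValidationError("ragged matrix: rows differ in length")
        if columns is None:
            columns = [Column(i + 1) for i in range(ncol)]
        self.columns = list(columns)
        if len(self.columns) != ncol:
            raise ValidationError("column metadata does not match width")
        if len({c.id for c in self.columns}) != len(self.columns):
            raise ValidationError("column ids must be unique")
        if alphabets is None:
            alphabets = {}
            for part in {c.partition for c in self.columns}:
                observed = {
                    self.cells[i][j]
                    for j, c in enumerate(self.columns) if c.partition == part
                    for i in range(len(self.taxa))
                }
                observed -= {MISSING, INAPPLICABLE}
                alphabets[part] = "".join(sorted(observed))
        self.alphabets = dict(alphabets)
        self._validate_symbols()

    def _validate_symbols(self):
        for j, col in enumerate(self.columns):
            allowed = set(self.alphabets.get(col.partition, ""))
            allowed |= {MISSING, INAPPLICABLE}
            if self.alphabets.get(col.partition, "").upper() in ("ACGT", "ACGU"):
                allowed |= IUPAC_AMBIGUITY
            for i in range(len(self.taxa)):
                sym = self.cells[i][j]
                if len(sym) != 1 or sym not in allowed:
                    raise ValidationError(
                        f"undeclared symbol {sym!r} at taxon "
                        f"{self.taxa[i]!r}, character {col.id}")

    # -- shape and access ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def partitions(self) -> list:
        seen = []
        for c in self.columns:
            if c.partition not in seen:
                seen.append(c.partition)
        return seen

    def row(self, taxon: str) -> list:
        return self.cells[self.taxa.index(taxon)]

    def column_values(self, pos: int) -> list:
        return [self.cells[i][pos] for i in range(self.n_taxa)]

    def column_states(self, pos: int) -> list:
        """Column values with non-state symbols collapsed to MISSING."""
        part = self.columns[pos].partition
        states = set(self.alphabets.get(part, ""))
        return [v if v in states else MISSING for v in self.column_values(pos)]

    def column_by_id(self, cid: int, partition: str | None = None) -> int:
        for pos, c in enumerate(self.columns):
            if c.id == cid and (partition is None or c.partition == partition):
                return pos
        raise KeyError(f"no character with id {cid}")

    # -- derived matrices ----------------------------------------------------

    def subset_taxa(self, keep: Iterable[str]) -> "CharacterMatrix":
        keep = list(keep)
        unknown = set(keep) - set(self.taxa)
        if unknown:
            raise ValidationError(f"taxa not in matrix: {sorted(unknown)}")
        keepset = set(keep)
        idx = [i for i, t in enumerate(self.taxa) if t in keepset]
        return CharacterMatrix(
            [self.taxa[i] for i in idx],
            [self.cells[i] for i in idx],
            self.columns, self.alphabets)

    def subset_columns(self, positions: Iterable[int]) -> "CharacterMatrix":
        positions = list(positions)
        return CharacterMatrix(
            self.taxa,
            [[row[p] for p in positions] for row in self.cells],
            [self.columns[p] for p in positions],
            self.alphabets)

    def by_partition(self, partition: str) -> "CharacterMatrix":
        pos = [j for j, c in enumerate(self.columns) if c.partition == partition]
        if not pos:
            raise KeyError(f"no partition named {partition!r}")
        return self.subset_columns(pos)

    def to_mapping(self, pos: int) -> dict:
        """taxon -> effective state symbol (missing collapsed), one column."""
        vals = self.column_states(pos)
        return dict(zip(self.taxa, vals))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<CharacterMatrix {self.n_taxa} taxa x "
                f"{self.n_columns} characters>")


# ---------------------------------------------------------------------------
# informativeness / missingness
# ---------------------------------------------------------------------------

def is_parsimony_informative(values: Sequence[str],
                             state_symbols: Iterable[str] | None = None) -> bool:
    """Standard unordered-character criterion: at least two distinct
    states must each occur in at least two taxa; everything else
    (missing, inapplicable, undeclared/ambiguous symbols) is excluded
    from the counts."""
    if state_symbols is None:
        observed = [v for v in values if v not in (MISSING, INAPPLICABLE)]
    else:
        allowed = set(state_symbols)
        observed = [v for v in values if v in allowed]
    counts: dict = {}
    for v in observed:
        counts[v] = counts.get(v, 0) + 1
    return sum(1 for c in counts.values() if c >= 2) >= 2


def filter_informative(matrix: CharacterMatrix,
                       gap_as_state: bool = False):
    """Keep exactly the parsimony-informative columns.

    Returns ``(filtered_matrix, dropped)`` where ``dropped`` lists the
    (1-based) ids of removed columns.  ``gap_as_state`` optionally counts
    INAPPLICABLE as an extra state (fifth state for nucleotides).
    Idempotent, and re-filtering after taxon subsetting may drop more.
    """
    keep, dropped = [], []
    for pos, col in enumerate(matrix.columns):
        vals = matrix.column_states(pos)
        if gap_as_state:
            raw = matrix.column_values(pos)
            vals = [INAPPLICABLE if r == INAPPLICABLE else v
                    for v, r in zip(vals, raw)]
            ok = is_parsimony_informative(
                vals, set(matrix.alphabets[col.partition]) | {INAPPLICABLE})
        else:
            ok = is_parsimony_informative(vals)
        (keep if ok else dropped).append(pos)
    return matrix.subset_columns(keep), [matrix.columns[p].id for p in dropped]


def missing_percentages(matrix: CharacterMatrix,
                        treat_inapplicable_as_missing: bool = True,
                        ndigits: int | None = None) -> pd.DataFrame:
    """Per-taxon, per-partition percentage of absent cells.

    Full precision by default; pass ``ndigits=1`` for report rendering.
    """
    absent = {MISSING, INAPPLICABLE} if treat_inapplicable_as_missing \
        else {MISSING}
    data = {}
    for part in matrix.partitions:
        pos = [j for j, c in enumerate(matrix.columns) if c.partition == part]
        col = []
        for i in range(matrix.n_taxa):
            eff = [matrix.cells[i][j] for j in pos]
            n_abs = sum(1 for v in eff if v in absent)
            col.append(100.0 * n_abs / len(pos))
        data[part] = col
    df = pd.DataFrame(data, index=matrix.taxa)
    if ndigits is not None:
        df = df.round(ndigits)
    return df


# ---------------------------------------------------------------------------
# weighting / combination
# ---------------------------------------------------------------------------

def replicate_columns(matrix: CharacterMatrix, k: int) -> CharacterMatrix:
    """Repeat every column ``k`` times contiguously (integer weighting)."""
    if k < 1:
        raise DomainError("replication factor must be >= 1")
    cells = [[v for v in row for _ in range(k)] for row in matrix.cells]
    columns = []
    nid = 1
    for col in matrix.columns:
        for _ in range(k):
            columns.append(Column(nid, col.partition,
                                  col.source_id if col.source_id is not None
                                  else col.id))
            nid += 1
    return CharacterMatrix(matrix.taxa, cells, columns, matrix.alphabets)


def expand_genus_to_species(morph: CharacterMatrix,
                            species_map: Mapping[str, Sequence[str]]
                            ) -> CharacterMatrix:
    """Replace genus rows by one identical row per mapped species."""
    for genus, species in species_map.items():
        if genus not in morph.taxa:
            raise ValidationError(f"genus {genus!r} is not a matrix row")
        if not species:
            raise ValidationError(f"empty species list for genus {genus!r}")
    taxa, cells = [], []
    for i, taxon in enumerate(morph.taxa):
        if taxon in species_map:
            for sp in species_map[taxon]:
                taxa.append(sp)
                cells.append(list(morph.cells[i]))
        else:
            taxa.append(taxon)
            cells.append(list(morph.cells[i]))
    return CharacterMatrix(taxa, cells, morph.columns, morph.alphabets)


def combine_partitions(first: CharacterMatrix,
                       second: CharacterMatrix) -> CharacterMatrix:
    """Concatenate two matrices column-wise over the union of their taxa.

    Taxa absent from one input get MISSING for all of its columns.  The
    inputs must use disjoint partition names.
    """
    if set(first.partitions) & set(second.partitions):
        raise ValidationError(
            "partitions must be disjoint between the matrices being combined")
    taxa = list(first.taxa) + [t for t in second.taxa if t not in first.taxa]
    cells = []
    for t in taxa:
        left = first.row(t) if t in first.taxa else [MISSING] * first.n_columns
        right = second.row(t) if t in second.taxa \
            else [MISSING] * second.n_columns
        cells.append(list(left) + list(right))
    columns = []
    nid = 1
    for col in list(first.columns) + list(second.columns):
        columns.append(Column(nid, col.partition,
                              col.source_id if col.source_id is not None
                              else col.id))
        nid += 1
    alphabets = dict(first.alphabets)
    alphabets.update(second.alphabets)
    return CharacterMatrix(taxa, cells, columns, alphabets)


# ---------------------------------------------------------------------------
# NEXUS I/O
# ---------------------------------------------------------------------------

def _sniff_datatype(text: str) -> str:
    m = re.search(r"\bdatatype\s*=\s*(\w+)", text, re.IGNORECASE)
    return m.group(1).lower() if m else "standard"


def _declared_symbols(text: str) -> str | None:
    m = re.search(r'\bsymbols\s*=\s*"([^"]*)"', text, re.IGNORECASE)
    if m:
        return "".join(m.group(1).split())
    return None


def read_nexus_matrix(text: str) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block (interleaved or not).

    The MISSING symbol maps to ``?``, the GAP symbol to ``-``; CHARSET
    definitions (CHARACTERS/SETS or ASSUMPTIONS blocks) become partition
    tags.  Polymorphic cells like ``(01)`` are not modelled and collapse
    to MISSING with a warning.
    """
    datatype = _sniff_datatype(text)
    cls = (dendropy.DnaCharacterMatrix if datatype in _DNA_TYPES
           else dendropy.StandardCharacterMatrix)
    try:
        dm = cls.get(data=text, schema="nexus", preserve_underscores=True)
    except Exception as exc:
        raise ValidationError(f"cannot read NEXUS matrix: {exc}") from exc
    if len(dm) == 0:
        raise ValidationError("matrix contains no taxa")

    taxa = [t.label for t in dm.taxon_namespace if t in dm]
    rows = []
    saw_poly = False
    for t in dm.taxon_namespace:
        if t not in dm:
            continue
        row = []
        for state in dm[t]:
            sym = state.symbol
            if sym is None or len(str(sym)) != 1:
                saw_poly = True
                sym = MISSING
            sym = str(sym)
            if datatype in _DNA_TYPES:
                sym = sym.upper()
            row.append(sym)
        rows.append(row)
    if saw_poly:
        warnings.warn("polymorphic cells collapsed to MISSING", stacklevel=2)
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValidationError("ragged matrix: rows differ in length")
    ncol = widths.pop() if widths else 0

    default_part = "molecular" if datatype in _DNA_TYPES else "morphological"
    part_of = [default_part] * ncol
    for name, subset in (dm.character_subsets or {}).items():
        for idx in subset.character_indices:
            if 0 <= idx < ncol:
                part_of[idx] = name
    columns = [Column(j + 1, part_of[j]) for j in range(ncol)]

    alphabets: dict = {}
    for part in set(part_of):
        if datatype in _DNA_TYPES:
            alphabets[part] = "ACGU" if datatype == "rna" else "ACGT"
        else:
            declared = _declared_symbols(text)
            if declared:
                alphabets[part] = declared
            else:
                observed = {rows[i][j] for j in range(ncol)
                            if part_of[j] == part for i in range(len(rows))}
                alphabets[part] = "".join(
                    sorted(observed - {MISSING, INAPPLICABLE}))
    return CharacterMatrix(taxa, rows, columns, alphabets)


def _nexus_name(label: str) -> str:
    if re.search(r"[\s()\[\]{},;:=*'\"`+<>]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus(matrix: CharacterMatrix, include_charsets: bool = True,
                mrbayes_block: bool = False) -> str:
    """Serialise to a NEXUS DATA block (+ SETS block with CHARSETs)."""
    symbols = "".join(sorted(set("".join(matrix.alphabets.values()))))
    dna_only = symbols in ("ACGT", "ACGU") and len(matrix.partitions) == 1
    fmt = ("datatype=dna" if dna_only
           else f'datatype=standard symbols="{symbols}"')
    width = max((len(_nexus_name(t)) for t in matrix.taxa), default=0)
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_columns};",
        f"    FORMAT {fmt} missing=? gap=-;",
        "    MATRIX",
    ]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        lines.append(f"        {_nexus_name(taxon):<{width}}  {''.join(row)}")
    lines += ["    ;", "END;"]

    ranges = {}
    if include_charsets and len(matrix.partitions) >= 1:
        lines += ["", "BEGIN SETS;"]
        for part in matrix.partitions:
            pos = [j + 1 for j, c in enumerate(matrix.columns)
                   if c.partition == part]
            ranges[part] = _ranges(pos)
            lines.append(f"    CHARSET {_nexus_name(part)} = {ranges[part]};")
        lines.append("END;")
    if mrbayes_block and ranges:
        # inert skeleton for external inference software
        lines += ["", "BEGIN MRBAYES;"]
        for part, rng in ranges.items():
            lines.append(f"    charset {part} = {rng};")
        names = ", ".join(ranges)
        lines.append(f"    partition combined = {len(ranges)}: {names};")
        lines.append("    set partition = combined;")
        lines.append("END;")
    return "\n".join(lines) + "\n"


def _ranges(positions: list) -> str:
    """Compress sorted 1-based positions into NEXUS range notation."""
    out = []
    start = prev = positions[0]
    for p in positions[1:] + [None]:
        if p is not None and p == prev + 1:
            prev = p
            continue
        out.append(f"{start}" if start == prev else f"{start}-{prev}")
        if p is not None:
            start = prev = p
    return " ".join(out)
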