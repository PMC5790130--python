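import itertools

import pytest

from conftest import brute_force_length, random_resolved_tree
from phylocd import (CharacterMatrix, Column, DomainError, ValidationError,
                     combine_partitions, expand_genus_to_species,
                     filter_informative, is_parsimony_informative,
                     missing_percentages, read_nexus_matrix,
                     replicate_columns, write_nexus)

TOY = """#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=3 NCHAR=2;
    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
    MATRIX
        ta 01
        tb 0?
        tc 1-
    ;
END;
"""


class TestReadNexus:
    def test_toy_dimensions(self):
        m = read_nexus_matrix(TOY)
        assert (m.n_taxa, m.n_columns) == (3, 2)
        assert m.taxa == ["ta", "tb", "tc"]

    def test_missing_and_gap_mapping(self):
        m = read_nexus_matrix(TOY)
        assert m.row("tb") == ["0", "?"]
        assert m.row("tc") == ["1", "-"]

    def test_interleaved_equals_flat(self):
        inter = """#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=3 NCHAR=4;
    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=- INTERLEAVE;
    MATRIX
        ta 01
        tb 00
        tc 11

        ta 10
        tb 0?
        tc 1-
    ;
END;
"""
        flat = """#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=3 NCHAR=4;
    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
    MATRIX
        ta 0110
        tb 000?
        tc 111-
    ;
END;
"""
        assert read_nexus_matrix(inter).cells == read_nexus_matrix(flat).cells

    def test_charsets_become_partitions(self):
        nex = """#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=2 NCHAR=4;
    FORMAT DATATYPE=STANDARD SYMBOLS="01";
    MATRIX
        ta 0101
        tb 1010
    ;
END;
BEGIN SETS;
    CHARSET morph = 1-2;
    CHARSET mol = 3-4;
END;
"""
        m = read_nexus_matrix(nex)
        assert [c.partition for c in m.columns] == ["morph"] * 2 + ["mol"] * 2

    def test_dna_datatype(self):
        nex = """#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=2 NCHAR=4;
    FORMAT DATATYPE=DNA MISSING=? GAP=-;
    MATRIX
        s1 ACG-
        s2 acrt
    ;
END;
"""
        m = read_nexus_matrix(nex)
        assert m.row("s2") == ["A", "C", "R", "T"]
        # ambiguity code collapses to missing for state counting
        assert m.column_states(2) == ["G", "?"]

    def test_round_trip(self):
        m = read_nexus_matrix(TOY)
        again = read_nexus_matrix(write_nexus(m))
        assert again.cells == m.cells
        assert again.taxa == m.taxa
        assert [c.partition for c in again.columns] == \
            [c.partition for c in m.columns]

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(ValidationError):
            CharacterMatrix(["a", "a"], [["0"], ["1"]])

    def test_ragged_matrix_rejected(self):
        with pytest.raises(ValidationError):
            CharacterMatrix(["a", "b"], [["0", "1"], ["0"]])

    def test_undeclared_symbol_rejected(self):
        with pytest.raises(ValidationError):
            CharacterMatrix(["a", "b"], [["0"], ["9"]],
                            alphabets={"morphological": "01"})


class TestInformativeness:
    def test_basic_cases(self):
        assert is_parsimony_informative(list("0011"))
        assert not is_parsimony_informative(list("0111"))
        assert not is_parsimony_informative(list("001?"))
        assert not is_parsimony_informative(list("0000"))

    def test_multistate_cases_against_length_variation_oracle(self):
        """Informative iff the minimum tree length varies across
        topologies (checked by exhaustive assignment minimisation)."""
        for pattern in ("0012", "001122", "0112", "001122"):
            taxa = [f"x{i}" for i in range(len(pattern))]
            values = dict(zip(taxa, pattern))
            lengths = set()
            for seed in range(40):
                tree = random_resolved_tree(len(taxa), seed=seed,
                                            labels=taxa)
                lengths.add(brute_force_length(tree, values))
            assert is_parsimony_informative(list(pattern)) \
                == (len(lengths) > 1)

    def test_filter_keeps_only_informative(self):
        m = CharacterMatrix(list("abcd"),
                            [list("0000?"), list("01010"),
                             list("00111"), list("1110-")])
        kept, dropped = filter_informative(m)
        assert kept.n_columns == 3
        assert dropped == [1, 5]
        # survivors keep their original 1-based ids
        assert [c.id for c in kept.columns] == [2, 3, 4]

    def test_all_invariant_matrix_drops_everything(self):
        m = CharacterMatrix(list("abc"), [list("00"), list("00"),
                                          list("00")])
        kept, dropped = filter_informative(m)
        assert kept.n_columns == 0
        assert dropped == [1, 2]

    def test_filter_idempotent(self, study_dataset):
        kept, _ = filter_informative(study_dataset.morphological)
        again, dropped = filter_informative(kept)
        assert dropped == []
        assert again.cells == kept.cells

    def test_taxon_subsetting_can_drop_more(self, study_dataset):
        morph = study_dataset.morphological
        kept_all, _ = filter_informative(morph)
        sub = kept_all.subset_taxa(morph.taxa[:10])
        _, dropped_after = filter_informative(sub)
        assert isinstance(dropped_after, list)  # may or may not be empty
        # re-filtering never *adds* characters
        kept_sub, _ = filter_informative(sub)
        assert kept_sub.n_columns <= kept_all.n_columns

    def test_gap_as_state_mode(self):
        m = CharacterMatrix(list("abcd"), [["0"], ["0"], ["-"], ["-"]])
        assert filter_informative(m)[0].n_columns == 0
        assert filter_informative(m, gap_as_state=True)[0].n_columns == 1


class TestMissingPercentages:
    def test_table_like_percentage(self):
        cells = [["?"] * 45 + ["0"] * 21]
        m = CharacterMatrix(["dis"], cells)
        pct = missing_percentages(m, ndigits=1)
        assert pct.loc["dis", "morphological"] == 68.2

    def test_zero_and_full(self):
        m = CharacterMatrix(["a", "b"], [["0", "1"], ["?", "?"]])
        pct = missing_percentages(m)
        assert pct.loc["a", "morphological"] == 0.0
        assert pct.loc["b", "morphological"] == 100.0

    def test_inapplicable_toggle(self):
        m = CharacterMatrix(["a"], [["-", "0"]])
        assert missing_percentages(m).loc["a", "morphological"] == 50.0
        assert missing_percentages(
            m, treat_inapplicable_as_missing=False
        ).loc["a", "morphological"] == 0.0


class TestReplicateColumns:
    def test_54_times_53_is_2862(self):
        m = CharacterMatrix(["a", "b", "c", "d"],
                            [list("01") * 27, list("10") * 27,
                             list("00") * 27, list("11") * 27])
        assert m.n_columns == 54
        rep = replicate_columns(m, 53)
        assert rep.n_columns == 2862

    def test_identity_and_contiguity(self):
        m = CharacterMatrix(["a", "b"], [["0", "1"], ["1", "0"]])
        assert replicate_columns(m, 1).cells == m.cells
        rep = replicate_columns(m, 3)
        assert rep.row("a") == ["0", "0", "0", "1", "1", "1"]
        assert [c.source_id for c in rep.columns] == [1, 1, 1, 2, 2, 2]

    def test_invalid_factor(self):
        m = CharacterMatrix(["a"], [["0"]])
        with pytest.raises(DomainError):
            replicate_columns(m, 0)

    def test_missingness_invariant_under_replication(self, study_dataset):
        m = study_dataset.morphological
        assert missing_percentages(replicate_columns(m, 3)).equals(
            missing_percentages(m))

    def test_informativeness_preserved_per_copy(self):
        m = CharacterMatrix(list("abcd"),
                            [list("01"), list("01"),
                             list("10"), list("1?")])
        rep = replicate_columns(m, 2)
        for j in range(rep.n_columns):
            src = rep.columns[j].source_id - 1
            assert is_parsimony_informative(rep.column_values(j)) \
                == is_parsimony_informative(m.column_values(src))


class TestGenusExpansion:
    def test_congeneric_duplication(self):
        m = CharacterMatrix(["gA", "gB"], [["0", "1"], ["1", "0"]])
        out = expand_genus_to_species(m, {"gA": ["gA_sp1", "gA_sp2"]})
        assert out.taxa == ["gA_sp1", "gA_sp2", "gB"]
        assert out.row("gA_sp1") == out.row("gA_sp2") == ["0", "1"]

    def test_single_species_genus(self):
        m = CharacterMatrix(["gA"], [["0"]])
        out = expand_genus_to_species(m, {"gA": ["gA_only"]})
        assert out.taxa == ["gA_only"]

    def test_absent_genus_rejected(self):
        m = CharacterMatrix(["gA"], [["0"]])
        with pytest.raises(ValidationError):
            expand_genus_to_species(m, {"gZ": ["gZ_sp1"]})

    def test_empty_species_list_rejected(self):
        m = CharacterMatrix(["gA"], [["0"]])
        with pytest.raises(ValidationError):
            expand_genus_to_species(m, {"gA": []})


class TestCombinePartitions:
    def make_pair(self):
        morph = CharacterMatrix(
            ["a", "b", "c"], [["0", "1"], ["1", "1"], ["0", "0"]],
            [Column(1, "morphological"), Column(2, "morphological")])
        mol = CharacterMatrix(
            ["b", "c"], [list("ACG"), list("A-G")],
            [Column(i, "molecular") for i in (1, 2, 3)],
            {"molecular": "ACGT"})
        return morph, mol

    def test_union_with_missing_fill(self):
        morph, mol = self.make_pair()
        comb = combine_partitions(morph, mol)
        assert comb.n_taxa == 3 and comb.n_columns == 5
        assert comb.row("a") == ["0", "1", "?", "?", "?"]

    def test_split_recovers_inputs(self):
        morph, mol = self.make_pair()
        comb = combine_partitions(morph, mol)
        assert comb.by_partition("morphological").cells == morph.cells
        back = comb.by_partition("molecular").subset_taxa(["b", "c"])
        assert back.cells == mol.cells

    def test_disjoint_taxa_block_diagonal(self):
        left = CharacterMatrix(["a"], [["0"]], [Column(1, "p1")])
        right = CharacterMatrix(["z"], [["1"]], [Column(1, "p2")])
        comb = combine_partitions(left, right)
        assert comb.row("a") == ["0", "?"]
        assert comb.row("z") == ["?", "1"]

    def test_overlapping_partition_names_rejected(self):
        morph, _ = self.make_pair()
        with pytest.raises(ValidationError):
            combine_partitions(morph, morph)

    def test_study_dataset_shape(self, study_dataset):
        comb = study_dataset.combined
        assert comb.n_taxa == 26
        mol_cols = [j for j, c in enumerate(comb.columns)
                    if c.partition == "molecular"]
        all_missing = [
            t for t in comb.taxa
            if all(comb.cells[comb.taxa.index(t)][j] == "?"
                   for j in mol_cols)]
        assert len(all_missing) == 8

    def test_mrbayes_block_written_on_request(self):
        morph, mol = self.make_pair()
        text = write_nexus(combine_partitions(morph, mol),
                           mrbayes_block=True)
        assert "BEGIN MRBAYES;" in text
        assert "partition combined" in text
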