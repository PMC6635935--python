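"""Alignment, haplotype-spectrum and genotype-table containers and I/O."""

import numpy as np
import pytest

from armipop.data import (
    Alignment,
    AlignmentError,
    GenotypeTable,
    HaplotypeSpectrum,
    InputError,
    Partition,
    collapse_haplotypes,
    concatenate_loci,
    read_fasta,
    read_genotype_table,
    read_haplotype_table,
    write_fasta,
    write_genotype_table,
    write_haplotype_table,
    _parse_cell,
)


class TestAlignment:
    def test_case_normalisation_and_shapes(self):
        aln = Alignment.from_strings(["x", "y"], ["acgt", "ACGT"])
        assert aln.n == 2 and aln.length == 4
        assert aln.sequence(0) == "ACGT"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            Alignment.from_strings(["x", "y"], ["ACG", "ACGT"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError):
            Alignment.from_strings(["x", "x"], ["ACG", "ACG"])

    def test_complete_deletion_drops_gap_and_ambiguity_columns(self):
        aln = Alignment.from_strings(["x", "y"], ["A-GN", "ACGT"])
        clean = aln.complete_deletion()
        assert clean.length == 2  # columns 0 and 2 survive

    def test_locus_bounds_must_tile(self):
        with pytest.raises(AlignmentError):
            Alignment.from_strings(
                ["x"], ["ACGT"], locus_bounds={"a": (0, 2), "b": (3, 4)}
            )

    def test_fasta_round_trip(self, tmp_path, toy_alignment):
        path = tmp_path / "aln.fasta"
        write_fasta(toy_alignment, path)
        back = read_fasta(path)
        assert back.ids == toy_alignment.ids
        assert back.pop_labels == toy_alignment.pop_labels
        assert back.region_labels == toy_alignment.region_labels
        assert np.array_equal(back.seqs, toy_alignment.seqs)

    def test_metadata_sidecar_wins(self, tmp_path, toy_alignment):
        fasta = tmp_path / "aln.fasta"
        write_fasta(toy_alignment, fasta)
        meta = tmp_path / "meta.tsv"
        meta.write_text("id\tsite\tregion\na\tZZ\tRZ\n")
        back = read_fasta(fasta, meta)
        assert back.pop_labels[0] == "ZZ" and back.region_labels[0] == "RZ"
        assert back.pop_labels[1] == "s1"  # untouched


class TestConcatenate:
    def test_lengths_add_and_bounds_recorded(self):
        parts = [
            Alignment.from_strings(["a", "b"], ["A" * 658] * 2),
            Alignment.from_strings(["a", "b"], ["C" * 554] * 2),
            Alignment.from_strings(["a", "b"], ["G" * 434] * 2),
        ]
        cat = concatenate_loci(parts, names=["COI", "COII", "Cytb"])
        assert cat.length == 1646
        assert cat.locus_bounds == {
            "COI": (0, 658), "COII": (658, 1212), "Cytb": (1212, 1646)
        }

    def test_single_input_is_identity(self, toy_alignment):
        cat = concatenate_loci([toy_alignment])
        assert np.array_equal(cat.seqs, toy_alignment.seqs)

    def test_row_order_follows_first_alignment(self):
        a = Alignment.from_strings(["a", "b"], ["AA", "CC"])
        b_rev = Alignment.from_strings(["b", "a"], ["TT", "GG"])
        cat = concatenate_loci([a, b_rev])
        assert cat.sequence(0) == "AAGG" and cat.sequence(1) == "CCTT"

    def test_id_mismatch_reports_ids(self):
        a = Alignment.from_strings(["a"], ["AA"])
        b = Alignment.from_strings(["z"], ["TT"])
        with pytest.raises(InputError, match="z"):
            concatenate_loci([a, b])


class TestCollapse:
    def test_basic_counts(self):
        aln = Alignment.from_strings(
            ["a", "b", "c", "d"], ["AAA", "AAA", "AAT", "AAT"]
        )
        spec = collapse_haplotypes(aln, by="all")
        assert spec.n_haplotypes == 2
        assert sorted(spec.column(None).tolist()) == [2, 2]

    def test_all_distinct_gives_singletons(self):
        aln = Alignment.from_strings(["a", "b", "c"], ["AAA", "AAT", "ATT"])
        spec = collapse_haplotypes(aln, by="all")
        assert spec.n_haplotypes == 3
        assert spec.column(None).tolist() == [1, 1, 1]

    def test_ids_ordered_by_descending_frequency_then_first_seen(self):
        aln = Alignment.from_strings(
            ["a", "b", "c", "d", "e"], ["TTT", "AAA", "AAA", "CCC", "TTT"]
        )
        spec = collapse_haplotypes(aln, by="all")
        # TTT and AAA both have 2 copies; TTT seen first -> H1
        assert spec.haplotype_ids == ["H1", "H2", "H3"]
        assert spec.column(None).tolist() == [2, 2, 1]

    def test_conserves_n_per_population(self, toy_alignment):
        spec = collapse_haplotypes(toy_alignment, by="pop")
        assert spec.counts.sum() == toy_alignment.n
        assert spec.sample_size("s1") == 2 and spec.sample_size("s2") == 2

    def test_empty_alignment(self):
        spec = collapse_haplotypes(
            Alignment.from_strings([], []), by="all"
        )
        assert spec.n_haplotypes == 0


class TestHaplotypeTableParsing:
    def test_count_notation(self):
        assert _parse_cell("H1(3); H2(2); H3", "AM", "haplotypes") == {
            "H1": 3, "H2": 2, "H3": 1
        }

    @pytest.mark.parametrize("cell", ["H24-H28", "H24‐H28", "H24–H28"])
    def test_ranges_expand_to_singletons(self, cell):
        parsed = _parse_cell(cell, "CE/CA", "haplotypes")
        assert parsed == {f"H{i}": 1 for i in range(24, 29)}

    def test_malformed_cell_reports_position(self):
        with pytest.raises(InputError, match="AM"):
            _parse_cell("H1((3)", "AM", "haplotypes")

    def test_spectrum_table_round_trip(self, tmp_path):
        spec = HaplotypeSpectrum(
            ["H1", "H2"], np.array([[3, 0], [1, 2]]), ["P1", "P2"]
        )
        path = tmp_path / "spec.tsv"
        write_haplotype_table(spec, path)
        back = read_haplotype_table(path)
        assert back.haplotype_ids == spec.haplotype_ids
        assert np.array_equal(back.counts, spec.counts)
        assert back.population_ids == spec.population_ids

    def test_cell_layout_table(self, tmp_path):
        path = tmp_path / "t1.tsv"
        path.write_text(
            "population\thaplotypes\n"
            "PR\tH1(2); H16(2)\n"
            "AM\tH1(3); H16\n"
        )
        spec = read_haplotype_table(path)
        assert spec.sample_size("PR") == 4
        assert spec.sample_size("AM") == 4
        assert spec.column("PR").sum() == 4

    def test_empty_population_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("haplotype\tP1\tP2\nH1\t2\t0\nH2\t1\t0\n")
        spec = read_haplotype_table(path)
        assert spec.sample_size("P2") == 0


class TestGenotypeTable:
    def test_pairs_stored_sorted_and_round_trip(self, tmp_path):
        geno = np.array([[[200, 150]], [[-1, -1]]])
        gt = GenotypeTable(["a", "b"], ["DDC"], geno, ["P1", "P1"])
        assert gt.genotypes[0, 0].tolist() == [150, 200]
        path = tmp_path / "gt.tsv"
        write_genotype_table(gt, path)
        back = read_genotype_table(path)
        assert np.array_equal(back.genotypes, gt.genotypes)
        assert back.loci == ["DDC"]

    def test_nonpositive_allele_rejected(self):
        with pytest.raises(InputError):
            GenotypeTable(["a"], ["L"], np.array([[[0, 5]]]), ["P"])

    def test_malformed_cell_reports_locus(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tpopulation\tDDC\nx\tP1\t150-200\n")
        with pytest.raises(InputError, match="DDC"):
            read_genotype_table(path)


class TestPartition:
    def test_from_alignment(self, toy_alignment):
        part = Partition.from_alignment(toy_alignment)
        assert part.sites() == ["s1", "s2"]
        assert part.regions() == ["r1", "r2"]
        assert part.region_labels(["c"]) == ["r2"]

    def test_inconsistent_site_region_mapping_rejected(self):
        aln = Alignment.from_strings(
            ["a", "b"], ["AA", "AA"], ["s1", "s1"], ["r1", "r2"]
        )
        with pytest.raises(InputError):
            Partition.from_alignment(aln)

    def test_unmapped_individual_rejected(self):
        part = Partition({"a": "s1"}, {"s1": "r1"})
        with pytest.raises(InputError):
            part.site_labels(["a", "zz"])
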