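"""TR-VR alignment, variable-position mapping, and codon-context arithmetic."""

import numpy as np
import pytest

from dgrscope.repeat_model import (
    DGRLocus,
    GenomicInterval,
    OrphanVRError,
    TargetGene,
    align_tr_to_vr,
    codon_position_spectrum,
    identify_variable_positions,
    locus_variable_positions,
)
from dgrscope.synthetic_data import random_tr, simulate_retrohoming


class TestAlignTrToVr:
    @pytest.mark.parametrize(
        "tr, vr, expect_variable, expect_nonA_mm",
        [
            ("TACGAACT", "TACGTTCT", {1, 4, 5}, 0),
            ("GGCC", "GGCC", set(), 0),
            ("AACC", "GTCA", {0, 1}, 1),  # column 3: C in TR vs A in VR
        ],
    )
    def test_column_classification(self, tr, vr, expect_variable, expect_nonA_mm):
        aln = align_tr_to_vr(tr, vr)
        assert set(aln.variable_columns) == expect_variable
        assert aln.nonA_mismatch_count == expect_nonA_mm

    def test_observed_changes_are_subset_of_variable(self):
        aln = align_tr_to_vr("TACGAACT", "TACGTTCT")
        assert aln.observed_variable_changes == {4, 5}
        assert aln.observed_variable_changes <= aln.variable_columns

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_tr_to_vr("", "ACGT")
        with pytest.raises(ValueError):
            align_tr_to_vr("ACGT", "")

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            align_tr_to_vr("ACGU", "ACGT")

    def test_n_bases_belong_to_neither_class(self):
        aln = align_tr_to_vr("ANCA", "AGCN")
        # col 1 (TR N) and col 3 (VR N) excluded everywhere
        assert set(aln.variable_columns) == {0}
        assert aln.nonA_mismatch_count == 0
        assert aln.nonA_column_count == 1  # only the C column counts

    def test_weak_pair_flagged_below_identity_floor(self):
        # 0/2 non-A columns match
        weak = align_tr_to_vr("ACC", "AGG")
        assert weak.weak_pair
        good = align_tr_to_vr("ACC", "TCC")
        assert not good.weak_pair

    def test_gapped_alignment_indexes_columns_consistently(self):
        aln = align_tr_to_vr("ACGTACGT", "ACGACGT")  # one deletion in VR
        assert aln.has_gaps
        for col in aln.columns:
            if not col.is_gap:
                assert aln.tr_seq[col.tr_index] == col.tr_base
                assert aln.vr_seq[col.vr_index] == col.vr_base

    def test_variable_columns_rescannable(self, rng):
        """Property: variable_columns is exactly the aligned-A column set."""
        for _ in range(50):
            tr = random_tr(40, 0.3, rng)
            vr = simulate_retrohoming(tr, 0.7, rng)
            aln = align_tr_to_vr(tr, vr)
            rescanned = {
                i for i, col in enumerate(aln.columns)
                if not col.is_gap and col.tr_base == "A"
            }
            assert set(aln.variable_columns) == rescanned

    def test_full_substitution_mismatches_confined_to_A_columns(self, rng):
        """With per-A substitution probability 1 and no sequencing error,
        every TR/VR mismatch sits at an adenine column."""
        for _ in range(25):
            tr = random_tr(60, 0.25, rng)
            vr = simulate_retrohoming(tr, 1.0, rng)
            aln = align_tr_to_vr(tr, vr)
            assert aln.nonA_mismatch_count == 0


def _toy_gene(seq, strand="+", frame=0, vr_bounds=None):
    genome = {"c": seq}
    cds = GenomicInterval("c", 0, len(seq), strand)
    lo, hi = vr_bounds or (0, len(seq))
    vr = GenomicInterval("c", lo, hi, strand)
    return genome, TargetGene(gene_id="g", cds=cds, vrs=[vr], frame_offset=frame), vr


class TestIdentifyVariablePositions:
    def test_frame_zero_vr_at_cds_start(self):
        genome, target, vr = _toy_gene("AACGGTGGT")
        aln = align_tr_to_vr("AACGGTGGT", "AACGGTGGT")
        pos = identify_variable_positions(target, vr, aln, genome)
        first_codon = [p for p in pos if p.codon_index == 0]
        assert {p.codon_position for p in first_codon} == {1, 2}

    def test_vr_at_cds_offset_four(self):
        # VR begins at CDS offset 4; variable column at VR offset 0
        # lands at (4+0): codon_index 1, codon position 2
        genome, target, vr = _toy_gene("GGGGATTTT", vr_bounds=(4, 9))
        aln = align_tr_to_vr("ATTTT", "ATTTT")
        pos = identify_variable_positions(target, vr, aln, genome)
        assert pos[0].vr_offset == 0
        assert (pos[0].codon_index, pos[0].codon_position) == (1, 2)
        assert pos[0].genome_pos == 4

    def test_reverse_strand_cds_end_is_codon_start(self):
        # minus-strand gene: plus-strand base T at cds.end-1 reads as A in
        # gene orientation and is the first base of codon 0
        seq = "GGGGGGGGT"
        genome, target, vr = _toy_gene(seq, strand="-")
        gene_seq = "ACCCCCCCC"  # revcomp of seq
        aln = align_tr_to_vr(gene_seq, gene_seq)
        pos = identify_variable_positions(target, vr, aln, genome)
        assert len(pos) == 1
        p = pos[0]
        assert p.genome_pos == len(seq) - 1
        assert (p.codon_index, p.codon_position) == (0, 1)
        assert p.ref_base == "T"  # plus-strand genome base

    def test_orphan_vr_rejected(self):
        genome = {"c": "A" * 30}
        target = TargetGene("g", GenomicInterval("c", 0, 12, "+"),
                            [GenomicInterval("c", 0, 6, "+")])
        outside = GenomicInterval("c", 18, 24, "+")
        aln = align_tr_to_vr("AAAAAA", "AAAAAA")
        with pytest.raises(OrphanVRError):
            identify_variable_positions(target, outside, aln, genome)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_codon_arithmetic(self, strand, rng):
        """Mapping genome_pos back through the CDS frame reproduces
        (codon_index, codon_position) on both strands."""
        seq = "".join(rng.choice(list("ACGT"), size=60))
        genome, target, vr = _toy_gene(seq, strand=strand, vr_bounds=(12, 42))
        gene_vr = GenomicInterval("c", 12, 42, strand).fetch(genome, oriented=True)
        aln = align_tr_to_vr(gene_vr, gene_vr)
        for p in identify_variable_positions(target, vr, aln, genome):
            if strand == "+":
                pos_in_gene = p.genome_pos - target.cds.start
            else:
                pos_in_gene = target.cds.end - 1 - p.genome_pos
            assert pos_in_gene // 3 == p.codon_index
            assert pos_in_gene % 3 + 1 == p.codon_position


class TestLocusLevel:
    def test_locus_variable_positions_match_planted_changes(self, toy_locus):
        genome, locus, tr_seq, vr_seq = toy_locus
        varpos = locus_variable_positions(locus, genome)
        (vr_id, positions), = varpos.items()
        assert vr_id == "g1:VR1"
        a_offsets = {i for i, b in enumerate(tr_seq) if b == "A"}
        assert {p.vr_offset for p in positions} == a_offsets
        assert {p.genome_pos for p in positions} == {130 + o for o in a_offsets}

    def test_degenerate_locus_requires_donor(self, toy_locus):
        genome, locus, tr_seq, _ = toy_locus
        degenerate = DGRLocus(locus_id="L2", targets=locus.targets)
        assert degenerate.completeness == "degenerate"
        with pytest.raises(ValueError, match="donor"):
            locus_variable_positions(degenerate, genome)
        via_donor = locus_variable_positions(degenerate, genome, tr_seq=tr_seq)
        assert via_donor == locus_variable_positions(locus, genome)


class TestCodonPositionSpectrum:
    def test_histogram(self, toy_locus):
        genome, locus, _, _ = toy_locus
        positions = locus_variable_positions(locus, genome)["g1:VR1"]
        spectrum, frac3 = codon_position_spectrum(positions)
        assert sum(spectrum.values()) == len(positions)
        assert frac3 == spectrum[3] / len(positions)

    def test_simple_counts(self):
        from dgrscope.repeat_model import VariablePosition

        pos = [VariablePosition(0, "c", i, 0, cp, "A") for i, cp in
               enumerate([1, 2, 1, 2])]
        spectrum, frac3 = codon_position_spectrum(pos)
        assert spectrum == {1: 2, 2: 2, 3: 0}
        assert frac3 == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            codon_position_spectrum([])
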