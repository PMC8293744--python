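import itertools

import pytest

from codonmnv.consequence_engine import (
    SEVERITY_ORDER,
    annotate_snp,
    assign_codon,
    classify_consequence,
    map_genomic_to_cds,
    severity_rank,
    translate_codon,
)
from codonmnv.errors import CodonMnvError, DataConsistencyError
from codonmnv.io_genomics import GenomeSequence, SampleCall, SnpRecord, TranscriptModel, revcomp
from conftest import CODON_TABLE_ORACLE, oracle_classify

ALL_CODONS = list(CODON_TABLE_ORACLE)


def _snp(chrom, pos, ref, alt, snp_id="s1"):
    return SnpRecord(chrom, pos, snp_id, ref, alt,
                     {"S1": SampleCall((0, 1), False)})


# ---------------------------------------------------------------------------
# Genomic -> CDS mapping


def test_map_plus_strand_first_base():
    tx = TranscriptModel("t", "g", "chr1", "+", [(101, 199)])
    assert map_genomic_to_cds(tx, 101) == 1
    assert map_genomic_to_cds(tx, 199) == 99


def test_map_minus_strand_mirrors():
    tx = TranscriptModel("t", "g", "chr1", "-", [(101, 199)])
    assert map_genomic_to_cds(tx, 199) == 1
    assert map_genomic_to_cds(tx, 101) == 99


def test_map_across_junction_hand_count():
    # 101-150 is 50 bases, so 161 is CDS base 51 on '+'
    tx = TranscriptModel("t", "g", "chr1", "+", [(101, 150), (161, 209)])
    assert map_genomic_to_cds(tx, 161) == 51
    assert map_genomic_to_cds(tx, 150) == 50
    assert map_genomic_to_cds(tx, 155) is None  # intronic


def test_map_frame_offset_trims_leading_bases():
    tx = TranscriptModel("t", "g", "chr1", "+", [(101, 202)], frame_first_segment=2)
    assert map_genomic_to_cds(tx, 101) is None  # inside trimmed offset
    assert map_genomic_to_cds(tx, 103) == 1


# ---------------------------------------------------------------------------
# Codon assignment


def test_assign_codon_arithmetic(toy_genome, toy_transcript):
    genome, cds = toy_genome
    # cds_pos 10 (genomic 20) -> codon 4 offset 1; ref codon CGA
    snp = _snp("chr1", 20, "C", "T")
    a = assign_codon(snp, toy_transcript, genome)
    assert (a.cds_pos, a.codon_index, a.codon_offset) == (10, 4, 1)
    assert a.ref_codon == "CGA" and a.alt_codon == "TGA"


def test_assign_codon_ref_mismatch_raises(toy_genome, toy_transcript):
    genome, _ = toy_genome
    snp = _snp("chr1", 20, "T", "A", snp_id="bad_snp")
    with pytest.raises(DataConsistencyError, match="bad_snp"):
        assign_codon(snp, toy_transcript, genome)


def test_assign_codon_outside_cds_is_none(toy_genome, toy_transcript):
    genome, _ = toy_genome
    assert assign_codon(_snp("chr1", 5, "G", "A"), toy_transcript, genome) is None


def test_assign_codon_minus_strand_complements_alleles():
    # '-' transcript whose coding sequence is ATG CGA TAA
    coding = "ATGCGATAA"
    seq = "TTTTT" + revcomp(coding) + "TTTTT"
    genome = GenomeSequence({"c": seq})
    tx = TranscriptModel("t", "g", "c", "-", [(6, 14)])
    assert tx.spliced_cds(genome) == coding
    # coding base 4 (C of CGA) sits at genome pos 11; genome ref is G
    snp = _snp("c", 11, "G", "A")
    a = assign_codon(snp, tx, genome)
    assert a.codon_index == 2 and a.codon_offset == 1
    assert a.ref_allele_coding == "C" and a.alt_allele_coding == "T"
    assert a.ref_codon == "CGA"


# ---------------------------------------------------------------------------
# Translation and classification


@pytest.mark.parametrize(
    "codon,aa", [("CGA", "R"), ("TGA", "*"), ("TGC", "C"), ("CGC", "R"), ("ATG", "M")]
)
def test_translate_codon_worked_examples(codon, aa):
    assert translate_codon(codon) == aa


def test_translate_codon_rejects_bad_input():
    with pytest.raises(CodonMnvError):
        translate_codon("CGN")
    with pytest.raises(CodonMnvError):
        translate_codon("CG")


@pytest.mark.parametrize(
    "ref,alt,idx,expected",
    [
        ("CGA", "TGA", 5, "stop_gained"),
        ("CGA", "CGC", 5, "synonymous"),
        ("TAA", "TGA", 10, "stop_retained"),
        ("TAA", "CAA", 10, "stop_lost"),
        ("ATG", "ACG", 1, "start_lost"),
        ("ATG", "ACG", 5, "missense"),  # internal Met is not a start
        ("AAA", "GAA", 5, "missense"),
    ],
)
def test_classify_consequence_rules(ref, alt, idx, expected):
    assert classify_consequence(ref, alt, idx, 10).category == expected


def test_classify_exhaustive_against_literal_oracle():
    """All 64 codons x 9 single substitutions (576 cases) agree with the
    independent 64-entry-table oracle, at internal, first and terminal
    codon positions."""
    n = 0
    for ref in ALL_CODONS:
        for offset, base in itertools.product(range(3), "ACGT"):
            if ref[offset] == base:
                continue
            alt = ref[:offset] + base + ref[offset + 1 :]
            for idx in (1, 5, 10):
                got = classify_consequence(ref, alt, idx, 10)
                assert got.category == oracle_classify(ref, alt, idx, 10), (
                    ref, alt, idx,
                )
                assert got.ref_aa == CODON_TABLE_ORACLE[ref]
                assert got.alt_aa == CODON_TABLE_ORACLE[alt]
            n += 1
    assert n == 576


def test_severity_total_order():
    ranks = [severity_rank(c) for c in SEVERITY_ORDER]
    assert ranks == [1, 2, 3, 4, 5, 6]
    assert severity_rank("stop_gained") < severity_rank("synonymous")
    assert severity_rank("missense") < severity_rank("stop_retained")
    with pytest.raises(CodonMnvError):
        severity_rank("splice_region")


# ---------------------------------------------------------------------------
# annotate_snp


def test_annotate_snp_per_transcript_independence(toy_genome, toy_transcript):
    genome, _ = toy_genome
    # overlapping transcript in a different frame: same SNP, new category
    tx2 = TranscriptModel("tx2", "g2", "chr1", "+", [(15, 41)])
    snp = _snp("chr1", 20, "C", "T")
    anns = annotate_snp(snp, [toy_transcript, tx2], genome)
    assert {a.transcript_id for a in anns} == {"tx1", "tx2"}
    by_tx = {a.transcript_id: a for a in anns}
    assert by_tx["tx1"].call.category == "stop_gained"  # CGA -> TGA
    assert by_tx["tx1"].assignment.codon_offset == 1
    assert by_tx["tx2"].call.category == "synonymous"  # CGC -> CGT
    assert by_tx["tx2"].assignment.codon_offset == 3


def test_annotate_snp_intronic_empty(toy_genome, toy_transcript):
    genome, _ = toy_genome
    assert annotate_snp(_snp("chr1", 45, "G", "A"), [toy_transcript], genome) == []


def test_annotate_skips_transcript_with_internal_stop():
    cds = "ATGTAACGATAA"  # internal TAA at codon 2: broken model
    genome = GenomeSequence({"c": "AA" + cds + "AA"})
    tx = TranscriptModel("t", "g", "c", "+", [(3, 14)])
    snp = _snp("c", 9, "C", "A")
    assert annotate_snp(snp, [tx], genome) == []


# ---------------------------------------------------------------------------
# Strand invariance and splice junctions


def test_strand_invariance_of_consequences():
    """The same CDS placed forward at one locus and reverse-complemented
    at another yields identical consequence calls for matching variants."""
    coding = "ATGCTTACGCGATCAAAGGATTGTCCGTAA"
    genome = GenomeSequence(
        {
            "fwd": "AAAAA" + coding + "AAAAA",
            "rev": "CCCCC" + revcomp(coding) + "CCCCC",
        }
    )
    tx_f = TranscriptModel("tf", "g", "fwd", "+", [(6, 35)])
    tx_r = TranscriptModel("tr", "g", "rev", "-", [(6, 35)])
    for cds_pos in range(1, 31):
        ref_base = coding[cds_pos - 1]
        for alt_base in "ACGT":
            if alt_base == ref_base:
                continue
            pos_f = 5 + cds_pos
            pos_r = 6 + (30 - cds_pos)
            snp_f = _snp("fwd", pos_f, ref_base, alt_base)
            snp_r = _snp("rev", pos_r, revcomp(ref_base), revcomp(alt_base))
            (af,) = annotate_snp(snp_f, [tx_f], genome)
            (ar,) = annotate_snp(snp_r, [tx_r], genome)
            assert af.call == ar.call, (cds_pos, alt_base)
            assert af.assignment.codon_index == ar.assignment.codon_index


def test_splice_spanning_codon_equals_single_exon():
    """A codon split across two CDS segments classifies identically to
    the same codon in a contiguous CDS."""
    coding = "ATGCGATAA"
    intron = "GTTTTTTTAG"
    # split codon 2 between bases 1 and 2: ATGC | intron | GATAA
    genome = GenomeSequence(
        {
            "split": "AA" + coding[:4] + intron + coding[4:] + "AA",
            "contig": "AA" + coding + "AA",
        }
    )
    tx_split = TranscriptModel("ts", "g", "split", "+", [(3, 6), (17, 21)])
    tx_cont = TranscriptModel("tc", "g", "contig", "+", [(3, 11)])
    assert tx_split.spliced_cds(genome) == coding
    # SNP at coding base 4 (C of CGA), before the junction
    (a1,) = annotate_snp(_snp("split", 6, "C", "T"), [tx_split], genome)
    (a2,) = annotate_snp(_snp("contig", 6, "C", "T"), [tx_cont], genome)
    assert a1.call == a2.call and a1.call.category == "stop_gained"
    # SNP at coding base 6 (A of CGA), after the junction
    (b1,) = annotate_snp(_snp("split", 18, "A", "C"), [tx_split], genome)
    (b2,) = annotate_snp(_snp("contig", 8, "A", "C"), [tx_cont], genome)
    assert b1.call == b2.call and b1.call.category == "synonymous"
    assert b1.assignment.codon_index == 2
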