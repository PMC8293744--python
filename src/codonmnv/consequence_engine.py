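"""Codon mapping and single-substitution coding-consequence classification.

This is a deliberately small re-implementation of the in-CDS subset of a
variant effect predictor: a SNP inside a protein-coding CDS is mapped to
its codon, the reference and alternative codons are translated with the
standard genetic code, and the change is classified into six categories
ordered from severe to weak:

    stop_gained > stop_lost > start_lost > missense > stop_retained > synonymous

Finer consequence terms used by full annotators (splice_region,
coding_sequence_variant, ...) are intentionally collapsed onto these six.
All coordinates are expressed on the coding strand: for a transcript on
the ``-`` strand, VCF alleles are complemented before codon lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import CodonMnvError, DataConsistencyError
from .io_genomics import COMPLEMENT, GenomeSequence, SnpRecord, TranscriptModel

logger = logging.getLogger(__name__)

STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
START_LOST = "start_lost"
MISSENSE = "missense"
STOP_RETAINED = "stop_retained"
SYNONYMOUS = "synonymous"

#: Severity order, most severe first (rank 1).
SEVERITY_ORDER = [
    STOP_GAINED,
    STOP_LOST,
    START_LOST,
    MISSENSE,
    STOP_RETAINED,
    SYNONYMOUS,
]
_SEVERITY_RANK = {cat: i + 1 for i, cat in enumerate(SEVERITY_ORDER)}

CATEGORIES = frozenset(SEVERITY_ORDER)


def severity_rank(category: str) -> int:
    """1 = most severe (stop_gained) ... 6 = weakest (synonymous)."""
    try:
        return _SEVERITY_RANK[category]
    except KeyError:
        raise CodonMnvError(f"unknown consequence category {category!r}") from None


def translate_codon(codon: str) -> str:
    """Standard genetic code (translation table 1); stops return '*'."""
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise CodonMnvError(f"invalid codon {codon!r}")
    return str(Seq(codon).translate(table=1))


@dataclass(frozen=True)
class ConsequenceCall:
    category: str
    ref_aa: str
    alt_aa: str


@dataclass(frozen=True)
class CodonAssignment:
    """Placement of one SNP inside one transcript's codon grid.

    ``cds_pos`` is 1-based in the spliced, frame-trimmed CDS;
    ``codon_offset`` is the 1-based position within the codon (1..3).
    Alleles are expressed on the coding strand.
    """

    transcript_id: str
    snp_id: str
    cds_pos: int
    codon_index: int
    codon_offset: int
    ref_codon: str
    ref_allele_coding: str
    alt_allele_coding: str

    def __post_init__(self):
        if self.cds_pos != 3 * (self.codon_index - 1) + self.codon_offset:
            raise CodonMnvError(
                f"{self.snp_id}/{self.transcript_id}: inconsistent codon arithmetic"
            )
        if self.ref_codon[self.codon_offset - 1] != self.ref_allele_coding:
            raise CodonMnvError(
                f"{self.snp_id}/{self.transcript_id}: ref codon "
                f"{self.ref_codon} does not carry ref allele at offset "
                f"{self.codon_offset}"
            )

    @property
    def alt_codon(self) -> str:
        c = list(self.ref_codon)
        c[self.codon_offset - 1] = self.alt_allele_coding
        return "".join(c)


def map_genomic_to_cds(transcript: TranscriptModel, pos: int) -> int | None:
    """1-based position in the spliced, frame-trimmed CDS, or None when
    ``pos`` falls outside the CDS segments (or inside the trimmed frame
    offset).  On the ``-`` strand position 1 is the segment base with
    the highest genomic coordinate."""
    offset = 0
    for s, e in transcript.segments_translation_order:
        if s <= pos <= e:
            within = (pos - s + 1) if transcript.strand == "+" else (e - pos + 1)
            cds_pos = offset + within - transcript.frame_first_segment
            return cds_pos if cds_pos >= 1 else None
        offset += e - s + 1
    return None


def _transcript_translation_ok(transcript: TranscriptModel,
                               genome: GenomeSequence) -> bool:
    """Reject transcripts whose reference CDS contains an internal stop
    (broken gene model: translation downstream is undefined)."""
    cds = transcript.spliced_cds(genome)
    for i in range(0, len(cds) - 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            continue
        if translate_codon(codon) == "*":
            return False
    return True


def assign_codon(snp: SnpRecord, transcript: TranscriptModel,
                 genome: GenomeSequence) -> CodonAssignment | None:
    """Map a SNP to its codon in one transcript; None when outside the CDS.

    Raises :class:`DataConsistencyError` when the VCF REF disagrees with
    the genome base at that position.  Codons containing N are skipped
    (logged) because their translation is undefined.
    """
    if not transcript.usable or snp.chrom != transcript.chrom:
        return None
    cds_pos = map_genomic_to_cds(transcript, snp.pos)
    if cds_pos is None:
        return None
    genome_base = genome.base(snp.chrom, snp.pos)
    if genome_base != snp.ref:
        raise DataConsistencyError(
            f"SNP {snp.snp_id}: VCF REF {snp.ref} != genome base "
            f"{genome_base} at {snp.chrom}:{snp.pos}"
        )
    if transcript.strand == "+":
        ref_coding, alt_coding = snp.ref, snp.alt
    else:
        ref_coding = snp.ref.translate(COMPLEMENT)
        alt_coding = snp.alt.translate(COMPLEMENT)
    codon_index = (cds_pos - 1) // 3 + 1
    codon_offset = (cds_pos - 1) % 3 + 1
    cds = transcript.spliced_cds(genome)
    if codon_index * 3 > len(cds):
        return None  # trailing partial codon (should not happen when usable)
    ref_codon = cds[(codon_index - 1) * 3 : codon_index * 3]
    if "N" in ref_codon:
        logger.warning(
            "SNP %s in transcript %s: codon %d overlaps N; skipped",
            snp.snp_id, transcript.transcript_id, codon_index,
        )
        return None
    return CodonAssignment(
        transcript_id=transcript.transcript_id,
        snp_id=snp.snp_id,
        cds_pos=cds_pos,
        codon_index=codon_index,
        codon_offset=codon_offset,
        ref_codon=ref_codon,
        ref_allele_coding=ref_coding,
        alt_allele_coding=alt_coding,
    )


def classify_consequence(ref_codon: str, alt_codon: str, codon_index: int,
                         n_codons: int) -> ConsequenceCall:
    """Classify a codon substitution.  Rules, applied in order:

    1. first codon, reference ATG, alternative != ATG  -> start_lost
    2. stop -> stop                                    -> stop_retained
    3. stop -> non-stop                                -> stop_lost
    4. non-stop -> stop                                -> stop_gained
    5. same amino acid                                 -> synonymous
    6. otherwise                                       -> missense
    """
    if not (1 <= codon_index <= n_codons):
        raise CodonMnvError(
            f"codon_index {codon_index} outside [1, {n_codons}]"
        )
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if codon_index == 1 and ref_codon == "ATG" and alt_codon != "ATG":
        category = START_LOST
    elif ref_aa == "*" and alt_aa == "*":
        category = STOP_RETAINED
    elif ref_aa == "*":
        category = STOP_LOST
    elif alt_aa == "*":
        category = STOP_GAINED
    elif ref_aa == alt_aa:
        category = SYNONYMOUS
    else:
        category = MISSENSE
    return ConsequenceCall(category=category, ref_aa=ref_aa, alt_aa=alt_aa)


@dataclass(frozen=True)
class SnpAnnotation:
    """Per-(SNP, transcript) annotation: codon placement + consequence."""

    snp_id: str
    transcript_id: str
    assignment: CodonAssignment
    call: ConsequenceCall


def annotate_snp(snp: SnpRecord, transcripts: list[TranscriptModel],
                 genome: GenomeSequence,
                 _usable_cache: dict | None = None) -> list[SnpAnnotation]:
    """One consequence call per transcript whose CDS contains the SNP.

    Intronic / intergenic SNPs yield an empty list.  Transcripts with a
    broken reference translation (internal stop) are skipped and logged.
    """
    out = []
    for tx in transcripts:
        if not tx.usable or tx.chrom != snp.chrom:
            continue
        if _usable_cache is not None:
            ok = _usable_cache.get(tx.transcript_id)
            if ok is None:
                ok = _transcript_translation_ok(tx, genome)
                if not ok:
                    logger.warning(
                        "transcript %s has an internal reference stop; skipped",
                        tx.transcript_id,
                    )
                _usable_cache[tx.transcript_id] = ok
        else:
            ok = _transcript_translation_ok(tx, genome)
        if not ok:
            continue
        assignment = assign_codon(snp, tx, genome)
        if assignment is None:
            continue
        call = classify_consequence(
            assignment.ref_codon, assignment.alt_codon,
            assignment.codon_index, tx.n_codons,
        )
        out.append(SnpAnnotation(snp.snp_id, tx.transcript_id, assignment, call))
    return out
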