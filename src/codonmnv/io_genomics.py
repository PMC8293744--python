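"""Readers and writers for the three genomic inputs: FASTA, GTF, VCF.

Coordinate conventions
----------------------
Everything at this module's boundary is 1-based and inclusive, matching
both the VCF ``POS`` column and GTF ``start``/``end`` columns.  No
0-based or half-open coordinate ever leaks out of a public function:
mixing the two systems is the classic source of off-by-one bugs in
codon-level variant tools.

The VCF reader keeps only biallelic SNPs (1 bp REF, a single 1 bp ALT)
and preserves the GATK HaplotypeCaller physical-phasing FORMAT fields
``PGT`` (phased genotype) and ``PID`` (phase-set identifier), which are
what allows two heterozygous variants to be placed in cis or in trans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pysam
from Bio import SeqIO

from .errors import FormatError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
VALID_BASES_N = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# Genome


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase ACGTN string.

    Lookups are 1-based inclusive; querying outside ``[1, length]`` is an
    error rather than a silent empty string.
    """

    def __init__(self, sequences: dict[str, str]):
        for name, seq in sequences.items():
            if not seq:
                raise FormatError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq.upper()) - VALID_BASES_N
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Single base at 1-based position ``pos``."""
        return self.slice(chrom, pos, pos)

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if not (1 <= start <= end <= len(seq)):
            raise IndexError(
                f"interval {chrom}:{start}-{end} outside [1, {len(seq)}]"
            )
        return seq[start - 1 : end]


def read_fasta(path) -> GenomeSequence:
    """Load a (small) multi-record FASTA into memory.

    Sequences are uppercased and multi-line records concatenated;
    duplicate headers are rejected because a genome with two ``chr1``
    entries has no well-defined coordinate system.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"duplicate FASTA header {record.id!r}")
        if len(record.seq) == 0:
            raise FormatError(f"FASTA record {record.id!r} has an empty sequence")
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence(seqs)


# ---------------------------------------------------------------------------
# Transcripts

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """Spliced CDS structure of one protein-coding transcript.

    ``cds_segments`` are 1-based inclusive genomic intervals sorted by
    genomic position regardless of strand; translation order is the
    reverse of genomic order on the ``-`` strand.
    ``frame_first_segment`` is the GTF frame of the first segment in
    *translation* order: that many bases are trimmed from the 5' end of
    the spliced sequence before codons are counted.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    frame_first_segment: int = 0
    usable: bool = field(default=True)
    unusable_reason: str | None = field(default=None)
    _cds_cache: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping CDS segments "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        for s, e in segs:
            if s > e or s < 1:
                raise FormatError(
                    f"transcript {self.transcript_id}: invalid CDS segment ({s},{e})"
                )
        self.cds_segments = segs
        if self.frame_first_segment not in {0, 1, 2}:
            raise FormatError(
                f"transcript {self.transcript_id}: frame must be 0/1/2"
            )
        if self.cds_length % 3 != 0:
            self.usable = False
            self.unusable_reason = (
                f"CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def segments_translation_order(self) -> list[tuple[int, int]]:
        return self.cds_segments if self.strand == "+" else self.cds_segments[::-1]

    @property
    def cds_length(self) -> int:
        """Length of the spliced CDS after trimming the frame offset."""
        total = sum(e - s + 1 for s, e in self.cds_segments)
        return total - self.frame_first_segment

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    def spliced_cds(self, genome: GenomeSequence) -> str:
        """Coding-strand CDS sequence (spliced, frame-trimmed)."""
        if self._cds_cache is None:
            parts = [genome.slice(self.chrom, s, e) for s, e in self.cds_segments]
            seq = "".join(parts)
            if self.strand == "-":
                seq = revcomp(seq)
            self._cds_cache = seq[self.frame_first_segment :]
        return self._cds_cache


def _first_attr(feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def read_gtf(path) -> list[TranscriptModel]:
    """Build one :class:`TranscriptModel` per transcript with >= 1 CDS
    feature.  Non-coding transcripts (no CDS lines) are skipped.

    Both Ensembl-style ``key "value";`` and generic ``key=value``
    attribute dialects are accepted (gffutils infers the dialect).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, list] = {}
    for feature in db.features_of_type("CDS"):
        tx_id = _first_attr(feature, "transcript_id")
        if tx_id is None:
            raise FormatError(
                f"CDS feature at {feature.seqid}:{feature.start}-{feature.end} "
                "has no transcript_id attribute"
            )
        if feature.strand not in {"+", "-"}:
            raise FormatError(
                f"transcript {tx_id}: strand {feature.strand!r} not in {{+,-}}"
            )
        by_tx.setdefault(tx_id, []).append(feature)

    transcripts = []
    for tx_id, feats in by_tx.items():
        chroms = {f.seqid for f in feats}
        strands = {f.strand for f in feats}
        if len(chroms) > 1 or len(strands) > 1:
            raise FormatError(
                f"transcript {tx_id}: CDS features span multiple "
                "chromosomes or strands"
            )
        strand = feats[0].strand
        gene_id = _first_attr(feats[0], "gene_id") or tx_id
        segments = sorted((f.start, f.end) for f in feats)
        # frame of the first segment in translation order
        first = (
            min(feats, key=lambda f: f.start)
            if strand == "+"
            else max(feats, key=lambda f: f.end)
        )
        frame = first.frame
        frame = int(frame) if frame in {"0", "1", "2"} else 0
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_id,
            chrom=feats[0].seqid,
            strand=strand,
            cds_segments=segments,
            frame_first_segment=frame,
        )
        if not tx.usable:
            logger.warning(
                "transcript %s flagged unusable: %s", tx_id, tx.unusable_reason
            )
        transcripts.append(tx)
    return transcripts


# ---------------------------------------------------------------------------
# VCF


@dataclass(frozen=True)
class SampleCall:
    """One sample's call at one site: genotype plus optional physical
    phasing (PGT/PID) as emitted by GATK HaplotypeCaller."""

    gt: tuple[int, int] | None  # None = no-call (./.)
    phased: bool = False
    pgt: str | None = None  # e.g. "0|1"
    pid: str | None = None  # e.g. "102_C_T"


@dataclass
class SnpRecord:
    """One biallelic SNP with per-sample calls."""

    chrom: str
    pos: int
    snp_id: str
    ref: str
    alt: str
    calls: dict[str, SampleCall]

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise FormatError(f"{self.snp_id}: REF/ALT must be single bases")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise FormatError(f"{self.snp_id}: alleles must be in ACGT")
        if self.ref == self.alt:
            raise FormatError(f"{self.snp_id}: REF equals ALT")


def default_snp_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """GATK-cohort style SNP identifier CHR_POS_REF/ALT."""
    return f"{chrom}_{pos}_{ref}/{alt}"


def _sample_call(sample) -> SampleCall:
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt) or len(gt) != 2:
        gt_tuple = None
        phased = False
    else:
        gt_tuple = (int(gt[0]), int(gt[1]))
        phased = bool(sample.phased)
    pgt = None
    pid = None
    try:
        raw = sample.get("PGT")
        if raw not in (None, "."):
            pgt = str(raw)
    except KeyError:
        pass
    try:
        raw = sample.get("PID")
        if raw not in (None, "."):
            pid = str(raw)
    except KeyError:
        pass
    return SampleCall(gt=gt_tuple, phased=phased, pgt=pgt, pid=pid)


def read_vcf(path) -> tuple[list[SnpRecord], list[str]]:
    """Read biallelic SNPs from a VCF; returns (records, sample names).

    Multi-allelic sites and indels are skipped with a logged count.
    Sample order always equals VCF header order.
    """
    records: list[SnpRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            if rec.ref not in VALID_BASES or alts[0] not in VALID_BASES:
                n_skipped += 1
                continue
            calls = {name: _sample_call(rec.samples[name]) for name in samples}
            snp_id = rec.id or default_snp_id(rec.chrom, rec.pos, rec.ref, alts[0])
            records.append(
                SnpRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    snp_id=snp_id,
                    ref=rec.ref,
                    alt=alts[0],
                    calls=calls,
                )
            )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-SNP/multi-allelic records", n_skipped)
    return records, samples


VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=PGT,Number=1,Type=String,Description='
    '"Physical phasing haplotype information">',
    '##FORMAT=<ID=PID,Number=1,Type=String,Description='
    '"Physical phasing ID information">',
]


def _format_call(call: SampleCall) -> str:
    if call.gt is None:
        gt = "./."
    else:
        sep = "|" if call.phased else "/"
        gt = f"{call.gt[0]}{sep}{call.gt[1]}"
    return ":".join([gt, call.pgt or ".", call.pid or "."])


def write_vcf(records: list[SnpRecord], samples: list[str], path,
              contigs: list[str] | None = None) -> None:
    """Write SnpRecords as an uncompressed VCF v4.2 (GT:PGT:PID)."""
    if contigs is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.chrom, None)
        contigs = list(seen)
    lines = list(VCF_HEADER_LINES)
    lines += [f"##contig=<ID={c}>" for c in contigs]
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
            "FORMAT", *samples]
    lines.append("\t".join(cols))
    for rec in sorted(records, key=lambda r: (contigs.index(r.chrom), r.pos)):
        row = [rec.chrom, str(rec.pos), rec.snp_id, rec.ref, rec.alt,
               ".", ".", ".", "GT:PGT:PID"]
        row += [_format_call(rec.calls[s]) for s in samples]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
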