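"""Self-contained FASTA/GTF/VCF fixtures with planted in-codon MNVs.

The generator emulates, at toy scale, the structure of a multi-sample
RNA-seq variant cohort: a small genome with forward- and reverse-strand
multi-exon protein-coding transcripts, per-sample genotypes with GATK
physical-phasing fields (GT:PGT:PID), and planted codon groups with
designed consequences — cis pairs (true MNVs, including reverse-strand
and splice-junction-spanning ones), trans pairs (never MNVs), unphased
heterozygotes, and singleton "sequencing error" MNVs seen in a single
individual.

Every fixture ships a machine-readable ground-truth manifest; planted
truth is the only truth (>= 10 bp of padding separates genes so no
accidental codon sharing can occur).

Codon triples realizing a designed (snp1, snp2, mnv) consequence are
found by exhaustive search over the standard genetic code; unrealizable
designs (e.g. synonymous + synonymous -> stop_gained) raise a
:class:`PlanningError` at plan time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .consequence_engine import (
    START_LOST,
    STOP_LOST,
    STOP_RETAINED,
    ConsequenceCall,
    classify_consequence,
    severity_rank,
    translate_codon,
)
from .errors import ParameterError, PlanningError
from .io_genomics import SampleCall, SnpRecord, revcomp, write_vcf
from .reannotation_flux import classify_flux, most_severe_constituent

logger = logging.getLogger(__name__)

#: Population labels used round-robin (11 labels echoing a layer/broiler/
#: jungle-fowl cohort structure; no biological meaning is claimed).
DEFAULT_POPULATIONS = (
    "RJFh", "FLLL", "Cobb", "HerX", "Novo1", "Novo2",
    "RpRm", "LSnu", "FrAg", "FAyo", "Rmx6",
)

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if translate_codon(a + b + c) != "*"
]
STOP_CODONS = ["TAA", "TAG", "TGA"]

INTRON_LEN = 20
PAD_LEN = 30


@dataclass(frozen=True)
class MnvDesign:
    """One planted codon group: designed per-SNP and haplotype
    consequences plus its carrier structure."""

    snp1_category: str
    snp2_category: str
    mnv_category: str
    carrier_count: int
    trans_carrier_count: int = 0
    offsets: tuple[int, int] = (1, 3)
    splice_spanning: bool = False
    strand: str | None = None  # None: drawn from strand_mix

    def label(self) -> str:
        return (
            f"({self.snp1_category},{self.snp2_category})->{self.mnv_category}"
            f"@{self.offsets}"
        )


@dataclass
class FixtureConfig:
    seed: int = 0
    n_samples: int = 40
    strand_mix: float = 0.5
    n_exons_range: tuple[int, int] = (1, 3)
    planted_mnvs: list[MnvDesign] = field(default_factory=list)
    n_singleton_errors: int = 4
    unphased_het_fraction: float = 0.05
    n_lone_snp_genes: int = 2
    populations: tuple[str, ...] = DEFAULT_POPULATIONS

    def __post_init__(self):
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if not (0.0 <= self.strand_mix <= 1.0):
            raise ParameterError("strand_mix must be in [0, 1]")
        for d in self.planted_mnvs:
            if d.carrier_count + d.trans_carrier_count > self.n_samples:
                raise ParameterError(
                    f"design {d.label()}: carriers exceed n_samples"
                )

    @classmethod
    def from_yaml(cls, path) -> "FixtureConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        designs = [
            MnvDesign(
                snp1_category=d["snp1_category"],
                snp2_category=d["snp2_category"],
                mnv_category=d["mnv_category"],
                carrier_count=int(d["carrier_count"]),
                trans_carrier_count=int(d.get("trans_carrier_count", 0)),
                offsets=tuple(d.get("offsets", (1, 3))),
                splice_spanning=bool(d.get("splice_spanning", False)),
                strand=d.get("strand"),
            )
            for d in raw.pop("planted_mnvs", [])
        ]
        if "n_exons_range" in raw:
            raw["n_exons_range"] = tuple(raw["n_exons_range"])
        if "populations" in raw:
            raw["populations"] = tuple(raw["populations"])
        cfg = cls(planted_mnvs=designs, **raw)
        return cfg


def default_designs() -> list[MnvDesign]:
    """The default planted-truth panel: 16 cis MNVs (>= 2 carriers)
    covering every realizable flux family plus reverse-strand and
    splice-spanning cases, 3 trans-only pairs and (via
    ``n_singleton_errors``) 4 singleton errors."""
    return [
        # the reverse-strand rescued-stop worked example (CGA -> TGA/CGC/TGC)
        MnvDesign("stop_gained", "synonymous", "missense", 12, offsets=(1, 3),
                  strand="-"),
        MnvDesign("stop_gained", "synonymous", "missense", 5, offsets=(1, 3),
                  strand="+"),
        MnvDesign("stop_gained", "missense", "missense", 7, offsets=(1, 2)),
        MnvDesign("missense", "missense", "missense", 8, offsets=(1, 2)),
        MnvDesign("missense", "synonymous", "missense", 6, offsets=(2, 3)),
        MnvDesign("missense", "missense", "synonymous", 9, offsets=(1, 2)),
        MnvDesign("synonymous", "synonymous", "synonymous", 10, offsets=(1, 3)),
        MnvDesign("missense", "missense", "stop_gained", 6, offsets=(1, 2)),
        MnvDesign("stop_retained", "stop_retained", "stop_lost", 5,
                  offsets=(2, 3)),
        MnvDesign("stop_lost", "stop_lost", "stop_lost", 8, offsets=(1, 2)),
        MnvDesign("start_lost", "start_lost", "start_lost", 11, offsets=(1, 2)),
        MnvDesign("missense", "missense", "missense", 15, offsets=(2, 3),
                  splice_spanning=True, strand="+"),
        MnvDesign("stop_gained", "synonymous", "missense", 6, offsets=(1, 3),
                  splice_spanning=True, strand="-"),
        MnvDesign("missense", "synonymous", "missense", 20, offsets=(1, 3)),
        MnvDesign("missense", "missense", "missense", 25, offsets=(1, 3)),
        MnvDesign("synonymous", "synonymous", "synonymous", 2, offsets=(1, 3)),
        # trans-only pairs: same codon, opposite haplotypes, never an MNV
        MnvDesign("missense", "missense", "missense", 0, trans_carrier_count=3,
                  offsets=(1, 2)),
        MnvDesign("stop_gained", "synonymous", "missense", 0,
                  trans_carrier_count=2, offsets=(1, 3)),
        MnvDesign("missense", "synonymous", "missense", 0,
                  trans_carrier_count=4, offsets=(2, 3)),
    ]


_SINGLETON_DESIGNS = [
    MnvDesign("stop_gained", "synonymous", "missense", 1, offsets=(1, 3)),
    MnvDesign("missense", "missense", "missense", 1, offsets=(1, 2)),
    MnvDesign("synonymous", "synonymous", "synonymous", 1, offsets=(1, 3)),
    MnvDesign("missense", "missense", "stop_gained", 1, offsets=(1, 2)),
]


def default_fixture_config(seed: int = 0) -> FixtureConfig:
    return FixtureConfig(seed=seed, planted_mnvs=default_designs())


# ---------------------------------------------------------------------------
# Codon-triple search


#: Preferred triples tried first so canonical worked examples reproduce
#: byte-for-byte (ref, alt1, alt2 on the coding strand).
_PREFERRED_TRIPLES = {
    ("stop_gained", "synonymous", "missense", (1, 3)): ("CGA", "T", "C"),
}


def _placement(design: MnvDesign) -> str:
    cats = {design.snp1_category, design.snp2_category, design.mnv_category}
    wants_stop_ref = bool(cats & {STOP_LOST, STOP_RETAINED})
    wants_start = START_LOST in cats
    if wants_stop_ref and wants_start:
        raise PlanningError(
            f"design {design.label()} mixes start-codon and stop-codon rules"
        )
    if wants_start:
        return "start"
    if wants_stop_ref:
        return "terminal"
    return "mid"


def _classify_at(ref: str, alt: str, placement: str) -> ConsequenceCall:
    idx, n = {"start": (1, 10), "mid": (5, 10), "terminal": (10, 10)}[placement]
    return classify_consequence(ref, alt, idx, n)


def find_codon_triple(design: MnvDesign) -> tuple[str, str, str]:
    """Exhaustively search the genetic code for (ref_codon, alt1, alt2)
    realizing the designed consequence triple at the designed offsets.

    Returns coding-strand bases; raises :class:`PlanningError` when no
    triple exists (the design is incompatible with the genetic code)."""
    placement = _placement(design)
    o1, o2 = design.offsets
    key = (design.snp1_category, design.snp2_category, design.mnv_category,
           design.offsets)
    candidates = []
    if key in _PREFERRED_TRIPLES:
        candidates.append(_PREFERRED_TRIPLES[key])
    ref_pool = {
        "start": ["ATG"],
        "terminal": STOP_CODONS,
        "mid": SENSE_CODONS,
    }[placement]
    for ref in ref_pool:
        for a1 in "ACGT":
            if a1 == ref[o1 - 1]:
                continue
            for a2 in "ACGT":
                if a2 == ref[o2 - 1]:
                    continue
                candidates.append((ref, a1, a2))
    for ref, a1, a2 in candidates:
        alt1_codon = ref[: o1 - 1] + a1 + ref[o1:]
        alt2_codon = ref[: o2 - 1] + a2 + ref[o2:]
        mnv_codon = alt1_codon[: o2 - 1] + a2 + alt1_codon[o2:]
        c1 = _classify_at(ref, alt1_codon, placement)
        c2 = _classify_at(ref, alt2_codon, placement)
        cm = _classify_at(ref, mnv_codon, placement)
        if (
            c1.category == design.snp1_category
            and c2.category == design.snp2_category
            and cm.category == design.mnv_category
        ):
            return ref, a1, a2
    raise PlanningError(
        f"no codon triple in the standard genetic code realizes "
        f"{design.label()}"
    )


# ---------------------------------------------------------------------------
# Planning


@dataclass
class PlantedGene:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    block_start: int  # genome pos of the transcript block's first base
    region: str  # pre-mRNA in coding orientation (exons + introns)
    exon_region_intervals: list[tuple[int, int]]  # 1-based in region coords
    coding_seq: str
    design: MnvDesign | None
    codon_index: int | None
    ref_codon: str | None
    alts_coding: tuple[str, str] | None
    carrier_samples: list[str] = field(default_factory=list)
    trans_samples: list[str] = field(default_factory=list)
    unphased_samples: list[str] = field(default_factory=list)
    lone_snp: tuple[int, str] | None = None  # (coding pos, alt base)

    @property
    def n_codons(self) -> int:
        return len(self.coding_seq) // 3

    def coding_to_region(self, c: int) -> int:
        offset = 0
        for s, e in self.exon_region_intervals:
            seg_len = e - s + 1
            if c <= offset + seg_len:
                return s + (c - offset) - 1
            offset += seg_len
        raise ValueError(f"coding position {c} outside exons")

    def region_to_genome(self, r: int) -> int:
        if self.strand == "+":
            return self.block_start + r - 1
        return self.block_start + len(self.region) - r

    def coding_to_genome(self, c: int) -> int:
        return self.region_to_genome(self.coding_to_region(c))

    def genome_allele(self, base_coding: str) -> str:
        return base_coding if self.strand == "+" else revcomp(base_coding)

    @property
    def cds_segments_genomic(self) -> list[tuple[int, int]]:
        segs = []
        for s, e in self.exon_region_intervals:
            if self.strand == "+":
                segs.append((self.region_to_genome(s), self.region_to_genome(e)))
            else:
                segs.append((self.region_to_genome(e), self.region_to_genome(s)))
        return sorted(segs)


@dataclass
class FixturePlan:
    config: FixtureConfig
    samples: list[str]
    sample_to_pop: dict[str, str]
    genes: list[PlantedGene]
    chromosomes: dict[str, str]
    snp_records: list[SnpRecord]
    manifest: pd.DataFrame


def _random_sense_codons(rng, n: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


def _random_bases(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _pick_exon_cuts(rng, design: MnvDesign | None, codon_index: int | None,
                    coding_len: int, n_exons: int) -> list[int]:
    """Cut positions (coding coords; cut after position c) splitting the
    CDS into exons.  A splice-spanning design forces one cut inside the
    planted codon."""
    cuts: set[int] = set()
    if design is not None and design.splice_spanning:
        # junction strictly between the two planted offsets, so the two
        # SNPs land in different CDS segments
        within = 3 * (codon_index - 1) + design.offsets[0]
        cuts.add(within)
    while len(cuts) < n_exons - 1:
        c = int(rng.integers(3, coding_len - 3))
        cuts.add(c)
    return sorted(cuts)


def _build_gene(rng, gene_no: int, design: MnvDesign | None,
                config: FixtureConfig, lone_snp: bool = False) -> PlantedGene:
    gene_id = f"G{gene_no:03d}"
    tx_id = f"{gene_id}.t1"
    strand = None
    if design is not None and design.strand is not None:
        strand = design.strand
    if strand is None:
        strand = "-" if rng.random() < config.strand_mix else "+"

    n_codons = int(rng.integers(8, 14))
    codons = ["ATG"] + _random_sense_codons(rng, n_codons - 2) + ["TAA"]

    codon_index = ref_codon = alts = None
    if design is not None:
        placement = _placement(design)
        ref_codon, a1, a2 = find_codon_triple(design)
        alts = (a1, a2)
        codon_index = {"start": 1, "terminal": n_codons,
                       "mid": n_codons // 2}[placement]
        codons[codon_index - 1] = ref_codon
    coding_seq = "".join(codons)

    lo, hi = config.n_exons_range
    n_exons = int(rng.integers(lo, hi + 1))
    if design is not None and design.splice_spanning:
        n_exons = max(2, n_exons)
    cuts = (
        _pick_exon_cuts(rng, design, codon_index, len(coding_seq), n_exons)
        if n_exons > 1
        else []
    )
    bounds = [0, *cuts, len(coding_seq)]
    exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]

    region_parts = []
    exon_intervals = []
    pos = 0
    offset = 0
    for i, ln in enumerate(exon_lens):
        if i > 0:
            region_parts.append(_random_bases(rng, INTRON_LEN))
            pos += INTRON_LEN
        exon_intervals.append((pos + 1, pos + ln))
        region_parts.append(coding_seq[offset : offset + ln])
        pos += ln
        offset += ln
    region = "".join(region_parts)

    gene = PlantedGene(
        gene_id=gene_id,
        transcript_id=tx_id,
        chrom="",  # set at assembly
        strand=strand,
        block_start=0,
        region=region,
        exon_region_intervals=exon_intervals,
        coding_seq=coding_seq,
        design=design,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alts_coding=alts,
    )
    if lone_snp:
        c = 3 * (n_codons // 2 - 1) + 1
        ref_base = coding_seq[c - 1]
        alt = next(b for b in "ACGT" if b != ref_base)
        gene.lone_snp = (c, alt)
    return gene


def _assign_samples(rng, gene: PlantedGene, samples: list[str],
                    n_unphased: int) -> None:
    d = gene.design
    if d is None:
        if gene.lone_snp is not None:
            gene.carrier_samples = [samples[int(rng.integers(len(samples)))]]
        return
    perm = [samples[i] for i in rng.permutation(len(samples))]
    k, m = d.carrier_count, d.trans_carrier_count
    gene.carrier_samples = perm[:k]
    gene.trans_samples = perm[k : k + m]
    gene.unphased_samples = perm[k + m : k + m + n_unphased]


def _het(phased_side: int | None, pid: str | None) -> SampleCall:
    if phased_side is None:
        return SampleCall(gt=(0, 1), phased=False)
    pgt = "0|1" if phased_side == 1 else "1|0"
    return SampleCall(gt=(0, 1), phased=False, pgt=pgt, pid=pid)


def _snp_calls_for_gene(rng, gene: PlantedGene, samples: list[str],
                        pid: str) -> tuple[dict, dict]:
    """Per-sample calls for the two planted SNPs of one gene."""
    calls1: dict[str, SampleCall] = {}
    calls2: dict[str, SampleCall] = {}
    hom_ref = SampleCall(gt=(0, 0))
    for s in samples:
        calls1[s] = hom_ref
        calls2[s] = hom_ref
    for i, s in enumerate(gene.carrier_samples):
        k = len(gene.carrier_samples)
        if k >= 3 and i == 0:
            # all-hom-alt carrier: cis forced without phasing
            calls1[s] = SampleCall(gt=(1, 1))
            calls2[s] = SampleCall(gt=(1, 1))
        elif k >= 3 and i == 1:
            # mixed carrier: hom-alt at site 1, phased het at site 2
            calls1[s] = SampleCall(gt=(1, 1))
            calls2[s] = _het(1, pid)
        else:
            side = int(rng.integers(2))
            calls1[s] = _het(side, pid)
            calls2[s] = _het(side, pid)
    for s in gene.trans_samples:
        side = int(rng.integers(2))
        calls1[s] = _het(side, pid)
        calls2[s] = _het(1 - side, pid)
    for s in gene.unphased_samples:
        calls1[s] = _het(None, None)
        calls2[s] = _het(None, None)
    return calls1, calls2


def plan_fixture(config: FixtureConfig) -> FixturePlan:
    """Deterministically (under ``config.seed``) plan genome, gene models,
    genotypes and the ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    pops = list(config.populations)
    sample_to_pop = {s: pops[i % len(pops)] for i, s in enumerate(samples)}
    n_unphased = int(round(config.unphased_het_fraction * config.n_samples))

    designs = list(config.planted_mnvs)
    designs += _SINGLETON_DESIGNS[: config.n_singleton_errors]
    if config.n_singleton_errors > len(_SINGLETON_DESIGNS):
        extra = config.n_singleton_errors - len(_SINGLETON_DESIGNS)
        designs += [replace(_SINGLETON_DESIGNS[i % len(_SINGLETON_DESIGNS)])
                    for i in range(extra)]

    genes: list[PlantedGene] = []
    for i, design in enumerate(designs):
        gene = _build_gene(rng, i + 1, design, config)
        _assign_samples(rng, gene, samples,
                        n_unphased if design.carrier_count > 0 else 0)
        genes.append(gene)
    for j in range(config.n_lone_snp_genes):
        gene = _build_gene(rng, len(designs) + j + 1, None, config,
                           lone_snp=True)
        _assign_samples(rng, gene, samples, 0)
        genes.append(gene)

    # assemble chromosomes: round-robin over three chromosomes
    chrom_names = ["chr1", "chr2", "chr3"]
    chrom_seqs = {c: "" for c in chrom_names}
    for i, gene in enumerate(genes):
        chrom = chrom_names[i % len(chrom_names)]
        block = gene.region if gene.strand == "+" else revcomp(gene.region)
        prefix = chrom_seqs[chrom] + _random_bases(rng, PAD_LEN)
        gene.chrom = chrom
        gene.block_start = len(prefix) + 1
        chrom_seqs[chrom] = prefix + block
    for c in chrom_names:
        chrom_seqs[c] += _random_bases(rng, PAD_LEN)

    # SNP records + manifest
    snp_records: list[SnpRecord] = []
    manifest_rows = []
    for gene in genes:
        if gene.design is not None:
            d = gene.design
            o1, o2 = d.offsets
            c1 = 3 * (gene.codon_index - 1) + o1
            c2 = 3 * (gene.codon_index - 1) + o2
            pos1, pos2 = gene.coding_to_genome(c1), gene.coding_to_genome(c2)
            ref1_g = gene.genome_allele(gene.ref_codon[o1 - 1])
            ref2_g = gene.genome_allele(gene.ref_codon[o2 - 1])
            alt1_g = gene.genome_allele(gene.alts_coding[0])
            alt2_g = gene.genome_allele(gene.alts_coding[1])
            # phase-set anchor: first SNP in genome order
            if pos1 <= pos2:
                pid = f"{pos1}_{ref1_g}_{alt1_g}"
            else:
                pid = f"{pos2}_{ref2_g}_{alt2_g}"
            calls1, calls2 = _snp_calls_for_gene(rng, gene, samples, pid)
            id1 = f"{gene.chrom}_{pos1}_{ref1_g}/{alt1_g}"
            id2 = f"{gene.chrom}_{pos2}_{ref2_g}/{alt2_g}"
            snp_records.append(SnpRecord(gene.chrom, pos1, id1, ref1_g,
                                         alt1_g, calls1))
            snp_records.append(SnpRecord(gene.chrom, pos2, id2, ref2_g,
                                         alt2_g, calls2))

            placement = _placement(d)
            alt1_codon = (gene.ref_codon[: o1 - 1] + gene.alts_coding[0]
                          + gene.ref_codon[o1:])
            alt2_codon = (gene.ref_codon[: o2 - 1] + gene.alts_coding[1]
                          + gene.ref_codon[o2:])
            mnv_codon = (alt1_codon[: o2 - 1] + gene.alts_coding[1]
                         + alt1_codon[o2:])
            call1 = _classify_at(gene.ref_codon, alt1_codon, placement)
            call2 = _classify_at(gene.ref_codon, alt2_codon, placement)
            callm = _classify_at(gene.ref_codon, mnv_codon, placement)
            snp_level = most_severe_constituent([call1, call2])
            flux = classify_flux(snp_level, callm, [call1, call2])
            manifest_rows.append(
                {
                    "mnv_id": f"{gene.transcript_id}:{gene.codon_index}",
                    "gene_id": gene.gene_id,
                    "transcript_id": gene.transcript_id,
                    "chrom": gene.chrom,
                    "strand": gene.strand,
                    "codon_index": gene.codon_index,
                    "offsets": f"{o1},{o2}",
                    "pos1": pos1,
                    "ref1": ref1_g,
                    "alt1": alt1_g,
                    "pos2": pos2,
                    "ref2": ref2_g,
                    "alt2": alt2_g,
                    "snp_id1": id1,
                    "snp_id2": id2,
                    "ref_codon": gene.ref_codon,
                    "mnv_codon": mnv_codon,
                    "snp1_category": call1.category,
                    "snp2_category": call2.category,
                    "snp_level": snp_level.category,
                    "mnv_category": callm.category,
                    "flux_class": flux["flux_class"],
                    "missense_subtype": flux["missense_subtype"],
                    "carrier_count": len(gene.carrier_samples),
                    "trans_carrier_count": len(gene.trans_samples),
                    "n_unphased": len(gene.unphased_samples),
                    "splice_spanning": d.splice_spanning,
                    "is_cis_mnv": len(gene.carrier_samples) > 0,
                }
            )
        elif gene.lone_snp is not None:
            c, alt = gene.lone_snp
            pos = gene.coding_to_genome(c)
            ref_g = gene.genome_allele(gene.coding_seq[c - 1])
            alt_g = gene.genome_allele(alt)
            calls = {s: SampleCall(gt=(0, 0)) for s in samples}
            for s in gene.carrier_samples:
                calls[s] = SampleCall(gt=(0, 1))
            snp_id = f"{gene.chrom}_{pos}_{ref_g}/{alt_g}"
            snp_records.append(
                SnpRecord(gene.chrom, pos, snp_id, ref_g, alt_g, calls)
            )

    manifest = pd.DataFrame(manifest_rows)
    manifest = manifest.sort_values("mnv_id").reset_index(drop=True)
    return FixturePlan(
        config=config,
        samples=samples,
        sample_to_pop=sample_to_pop,
        genes=genes,
        chromosomes=chrom_seqs,
        snp_records=snp_records,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Writing


def _gtf_frame(cum_before: int) -> int:
    return (3 - cum_before % 3) % 3


def write_fixture(plan: FixturePlan, outdir) -> dict:
    """Write genome.fa, annotation.gtf, variants.vcf, populations.tsv and
    manifest.tsv; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gtf": os.path.join(outdir, "annotation.gtf"),
        "vcf": os.path.join(outdir, "variants.vcf"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "populations": os.path.join(outdir, "populations.tsv"),
    }
    with open(paths["fasta"], "w") as fh:
        for chrom, seq in plan.chromosomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    gtf_lines = []
    for gene in plan.genes:
        segs = gene.cds_segments_genomic
        translation_order = segs if gene.strand == "+" else segs[::-1]
        cum = 0
        frames = {}
        for s, e in translation_order:
            frames[(s, e)] = _gtf_frame(cum)
            cum += e - s + 1
        for s, e in segs:
            attrs = (
                f'gene_id "{gene.gene_id}"; '
                f'transcript_id "{gene.transcript_id}";'
            )
            gtf_lines.append(
                "\t".join(
                    [gene.chrom, "synthetic", "CDS", str(s), str(e), ".",
                     gene.strand, str(frames[(s, e)]), attrs]
                )
            )
    with open(paths["gtf"], "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")

    write_vcf(plan.snp_records, plan.samples, paths["vcf"],
              contigs=list(plan.chromosomes))
    plan.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    pd.DataFrame(
        {"sample": plan.samples,
         "population": [plan.sample_to_pop[s] for s in plan.samples]}
    ).to_csv(paths["populations"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Validation


def validate_fixture(paths: dict, manifest: pd.DataFrame | None = None) -> list[dict]:
    """Re-read the emitted files through the ordinary parsers and check
    every manifest row; returns a report (one entry per check failure,
    empty means pass)."""
    from .consequence_engine import annotate_snp
    from .io_genomics import read_fasta, read_gtf, read_vcf

    if manifest is None:
        manifest = pd.read_csv(paths["manifest"], sep="\t")
    genome = read_fasta(paths["fasta"])
    transcripts = read_gtf(paths["gtf"])
    tx_by_id = {t.transcript_id: t for t in transcripts}
    snps, _samples = read_vcf(paths["vcf"])
    snps_by_id = {s.snp_id: s for s in snps}

    failures: list[dict] = []

    def fail(mnv_id, message):
        failures.append({"mnv_id": mnv_id, "message": message})

    for row in manifest.itertuples(index=False):
        tx = tx_by_id.get(row.transcript_id)
        if tx is None:
            fail(row.mnv_id, f"transcript {row.transcript_id} missing from GTF")
            continue
        for snp_id, expected_cat in (
            (row.snp_id1, row.snp1_category),
            (row.snp_id2, row.snp2_category),
        ):
            snp = snps_by_id.get(snp_id)
            if snp is None:
                fail(row.mnv_id, f"SNP {snp_id} missing from VCF")
                continue
            try:
                anns = annotate_snp(snp, [tx], genome)
            except Exception as exc:  # surfaced as a report entry, not a crash
                fail(row.mnv_id, f"SNP {snp_id}: {exc}")
                continue
            if not anns:
                fail(row.mnv_id, f"SNP {snp_id} not annotated in CDS")
                continue
            ann = anns[0]
            if ann.call.category != expected_cat:
                fail(
                    row.mnv_id,
                    f"SNP {snp_id}: category {ann.call.category} != "
                    f"expected {expected_cat}",
                )
            if ann.assignment.codon_index != row.codon_index:
                fail(
                    row.mnv_id,
                    f"SNP {snp_id}: codon {ann.assignment.codon_index} != "
                    f"{row.codon_index}",
                )
            if ann.assignment.ref_codon != row.ref_codon:
                fail(
                    row.mnv_id,
                    f"SNP {snp_id}: ref codon {ann.assignment.ref_codon} != "
                    f"{row.ref_codon}",
                )
    return failures
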