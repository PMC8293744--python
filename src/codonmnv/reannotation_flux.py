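"""Haplotype-codon re-annotation and flux classification.

For every called MNV the haplotype codon (all alternative alleles
substituted simultaneously) is re-translated and compared with the most
severe consequence of the constituent SNPs annotated one at a time.
The comparison is classified as *eased* (MNV strictly less severe),
*equal* or *aggravated* (strictly more severe), and for
missense -> missense cases a subtype records whether the MNV amino acid
is novel relative to both constituent predictions.

``summarize_flux`` builds the (SNP annotation -> MNV annotation) count
matrix across a ladder of carrier-count thresholds, and
``headline_stats`` derives the headline percentages from it: the share
of rescued stop-gained codons, the share of missense codons with a novel
amino acid, the overall fraction of MNVs whose predicted impact changes,
the decline of the stop-gained category and the growth of the synonymous
category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .consequence_engine import (
    MISSENSE,
    STOP_GAINED,
    SYNONYMOUS,
    ConsequenceCall,
    SnpAnnotation,
    annotate_snp,
    classify_consequence,
    severity_rank,
)
from .errors import CodonMnvError, DataConsistencyError
from .io_genomics import (
    GenomeSequence,
    SnpRecord,
    TranscriptModel,
    read_fasta,
    read_gtf,
    read_vcf,
)
from .mnv_detection import (
    MnvCall,
    call_mnvs,
    filter_by_support,
    group_by_codon,
)

logger = logging.getLogger(__name__)

EASED = "eased"
EQUAL = "equal"
AGGRAVATED = "aggravated"

NOVEL_AA = "novel_aa"
SHARED_AA = "shared_aa"
NOT_APPLICABLE = "not_applicable"

DEFAULT_THRESHOLDS = (1, 2, 3, 4, 5, 10, 15, 20, 30, 50, 100)


def build_mnv_codon(ref_codon: str,
                    substitutions: list[tuple[int, str]]) -> str:
    """Apply all (codon_offset, alt_base) substitutions simultaneously."""
    codon = list(ref_codon)
    seen: set[int] = set()
    for offset, base in substitutions:
        if offset in seen:
            raise CodonMnvError(f"offset {offset} substituted twice")
        if not (1 <= offset <= 3) or base not in "ACGT":
            raise CodonMnvError(f"invalid substitution ({offset}, {base!r})")
        seen.add(offset)
        codon[offset - 1] = base
    return "".join(codon)


def most_severe_constituent(calls: list[ConsequenceCall]) -> ConsequenceCall:
    """Most impactful call; ties go to the first in codon-offset order."""
    if not calls:
        raise CodonMnvError("most_severe_constituent: empty call list")
    return min(calls, key=lambda c: severity_rank(c.category))


def flux_class(snp_level: ConsequenceCall, mnv_level: ConsequenceCall) -> str:
    rs, rm = severity_rank(snp_level.category), severity_rank(mnv_level.category)
    if rm > rs:
        return EASED
    if rm < rs:
        return AGGRAVATED
    return EQUAL


def classify_flux(
    snp_level: ConsequenceCall,
    mnv_level: ConsequenceCall,
    constituent_calls: list[ConsequenceCall] | None = None,
) -> dict:
    """Flux fields for one MNV.

    ``missense_subtype`` only applies when the MNV *and both/all
    constituents* are missense: ``novel_aa`` when the MNV amino acid
    differs from every constituent prediction, ``shared_aa`` otherwise.
    ``changed_impact`` is true when the category changes or a
    missense -> missense case produces a novel amino acid.
    """
    cls = flux_class(snp_level, mnv_level)
    subtype = NOT_APPLICABLE
    if (
        mnv_level.category == MISSENSE
        and constituent_calls is not None
        and all(c.category == MISSENSE for c in constituent_calls)
    ):
        constituent_aas = {c.alt_aa for c in constituent_calls}
        subtype = NOVEL_AA if mnv_level.alt_aa not in constituent_aas else SHARED_AA
    changed = (snp_level.category != mnv_level.category) or (
        snp_level.category == MISSENSE
        and mnv_level.category == MISSENSE
        and subtype == NOVEL_AA
    )
    rescued_stop = (
        snp_level.category == STOP_GAINED and mnv_level.category != STOP_GAINED
    )
    return {
        "flux_class": cls,
        "missense_subtype": subtype,
        "changed_impact": changed,
        "rescued_stop": rescued_stop,
    }


@dataclass
class FluxRecord:
    """Per-MNV pairing of SNP-level and MNV-level consequences."""

    mnv: MnvCall
    snp_level: ConsequenceCall
    mnv_level: ConsequenceCall
    constituent_calls: list[ConsequenceCall]
    flux_class: str
    missense_subtype: str
    changed_impact: bool
    rescued_stop: bool

    @property
    def carrier_count(self) -> int:
        return self.mnv.carrier_count


FLUX_FRAME_COLUMNS = [
    "transcript_id", "gene_id", "chrom", "codon_index", "snp_ids", "offsets",
    "positions", "ref_codon", "mnv_codon", "ref_aa", "mnv_aa",
    "snp_level", "mnv_level", "flux_class", "missense_subtype",
    "changed_impact", "rescued_stop", "n_snps", "carrier_count",
]


def flux_for_mnv(mnv: MnvCall, annotations_by_key: dict,
                 n_codons: int) -> FluxRecord:
    """Compute the flux record for one called MNV.

    ``annotations_by_key`` maps (snp_id, transcript_id) -> SnpAnnotation;
    constituent calls are taken in codon-offset order.
    """
    cand = mnv.candidate
    constituent = [
        annotations_by_key[(sid, cand.transcript_id)].call for sid in cand.snp_ids
    ]
    snp_level = most_severe_constituent(constituent)
    mnv_level = classify_consequence(
        cand.ref_codon, mnv.mnv_codon, cand.codon_index, n_codons
    )
    fields = classify_flux(snp_level, mnv_level, constituent)
    return FluxRecord(
        mnv=mnv,
        snp_level=snp_level,
        mnv_level=mnv_level,
        constituent_calls=constituent,
        **fields,
    )


# ---------------------------------------------------------------------------
# Summaries


@dataclass
class FluxSummary:
    """Count matrix of (SNP annotation -> MNV annotation) transitions per
    carrier-count threshold, in eased/equal/aggravated row groups."""

    table: pd.DataFrame  # MultiIndex (flux_class, snp_level, mnv_level) x thresholds
    totals: pd.Series  # per-threshold total MNV count

    @property
    def thresholds(self) -> list[int]:
        return list(self.table.columns)

    def cell(self, snp_level: str, mnv_level: str, threshold: int) -> int:
        mask = (
            self.table.index.get_level_values("snp_level") == snp_level
        ) & (self.table.index.get_level_values("mnv_level") == mnv_level)
        return int(self.table.loc[mask, threshold].sum())

    def initial_count(self, category: str, threshold: int) -> int:
        mask = self.table.index.get_level_values("snp_level") == category
        return int(self.table.loc[mask, threshold].sum())

    def final_count(self, category: str, threshold: int) -> int:
        mask = self.table.index.get_level_values("mnv_level") == category
        return int(self.table.loc[mask, threshold].sum())

    def off_diagonal(self, threshold: int) -> int:
        idx = self.table.index
        mask = idx.get_level_values("snp_level") != idx.get_level_values("mnv_level")
        return int(self.table.loc[mask, threshold].sum())


_FLUX_CLASS_ORDER = {EASED: 0, EQUAL: 1, AGGRAVATED: 2}


def summarize_flux(records: pd.DataFrame,
                   thresholds=DEFAULT_THRESHOLDS) -> FluxSummary:
    """Build the transition x threshold count matrix from a record-level
    table with columns ``snp_level``, ``mnv_level``, ``carrier_count``.

    Each column counts the MNVs with carrier_count >= that threshold, so
    columns are monotone non-increasing left to right and each column
    sums to the number of MNVs passing that threshold.
    """
    required = {"snp_level", "mnv_level", "carrier_count"}
    missing = required - set(records.columns)
    if missing:
        raise DataConsistencyError(
            f"record table is missing columns {sorted(missing)}"
        )
    thresholds = list(thresholds)
    rows = {}
    pairs = (
        records[["snp_level", "mnv_level"]].drop_duplicates().itertuples(index=False)
        if len(records)
        else []
    )
    for snp_cat, mnv_cat in pairs:
        cls = flux_class(
            ConsequenceCall(snp_cat, "X", "X"), ConsequenceCall(mnv_cat, "X", "X")
        )
        sel = records[
            (records["snp_level"] == snp_cat) & (records["mnv_level"] == mnv_cat)
        ]
        counts = [int((sel["carrier_count"] >= t).sum()) for t in thresholds]
        rows[(cls, snp_cat, mnv_cat)] = counts
    if rows:
        index = pd.MultiIndex.from_tuples(
            sorted(
                rows,
                key=lambda k: (
                    _FLUX_CLASS_ORDER[k[0]],
                    severity_rank(k[1]),
                    severity_rank(k[2]),
                ),
            ),
            names=["flux_class", "snp_level", "mnv_level"],
        )
        table = pd.DataFrame(
            [rows[k] for k in index], index=index, columns=thresholds
        )
    else:
        index = pd.MultiIndex.from_tuples(
            [], names=["flux_class", "snp_level", "mnv_level"]
        )
        table = pd.DataFrame([], index=index, columns=thresholds, dtype=int)
    totals = table.sum(axis=0).astype(int)
    totals.name = "total_mnvs"
    return FluxSummary(table=table, totals=totals)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for the printed
    percentages), unlike Python's banker's rounding."""
    factor = 10 ** ndigits
    value = math.floor(abs(x) * factor + 0.5) / factor
    return math.copysign(value, x)


def _pct(numerator: float, denominator: float, ndigits: int) -> float | None:
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, ndigits)


def headline_stats(summary: FluxSummary, threshold: int,
                   novel_aa_count: int | None = None) -> dict:
    """Headline re-annotation statistics at one carrier threshold.

    ``novel_aa_count`` is the number of missense->missense MNVs whose
    amino acid differs from both constituent predictions at this
    threshold; when None the novel-amino-acid statistics are undefined.
    Undefined statistics (zero denominators) are reported as None, never
    as 0.
    """
    if threshold not in summary.thresholds:
        raise CodonMnvError(f"threshold {threshold} not present in summary")
    total = int(summary.totals[threshold])
    initial_stop = summary.initial_count(STOP_GAINED, threshold)
    final_stop = summary.final_count(STOP_GAINED, threshold)
    rescued = initial_stop - summary.cell(STOP_GAINED, STOP_GAINED, threshold)
    initial_missense = summary.initial_count(MISSENSE, threshold)
    initial_syn = summary.initial_count(SYNONYMOUS, threshold)
    final_syn = summary.final_count(SYNONYMOUS, threshold)
    off_diag = summary.off_diagonal(threshold)

    stats: dict[str, float | int | None] = {
        "threshold": threshold,
        "total_mnvs": total,
        "initial_stop_gained": initial_stop,
        "final_stop_gained": final_stop,
        "rescued_stop_count": rescued,
        "initial_missense": initial_missense,
        "initial_synonymous": initial_syn,
        "final_synonymous": final_syn,
        "novel_aa_count": novel_aa_count,
        "rescued_stop_pct": _pct(rescued, initial_stop, 1),
        "missense_to_synonymous_pct": _pct(
            summary.cell(MISSENSE, SYNONYMOUS, threshold), initial_missense, 1
        ),
        "rescued_over_total_pct": _pct(rescued, total, 1),
        "stop_gained_decline_pct": _pct(initial_stop - final_stop, initial_stop, 0),
        "synonymous_fold": (
            round_half_away(final_syn / initial_syn, 1) if initial_syn else None
        ),
    }
    if novel_aa_count is None:
        stats["missense_novel_aa_pct"] = None
        stats["changed_impact_pct"] = None
    else:
        stats["missense_novel_aa_pct"] = _pct(
            novel_aa_count, initial_missense, 1
        )
        stats["changed_impact_pct"] = _pct(off_diag + novel_aa_count, total, 1)
    return stats


def singleton_pct(summary: FluxSummary) -> float | None:
    """Share of codon groups observed in exactly one individual, as the
    drop between the threshold-1 and threshold-2 totals (printed as an
    integer percentage)."""
    if 1 not in summary.thresholds or 2 not in summary.thresholds:
        return None
    t1 = int(summary.totals[1])
    t2 = int(summary.totals[2])
    return _pct(t1 - t2, t1, 0)


def novel_aa_count_at(records: pd.DataFrame, threshold: int) -> int:
    """Count missense->missense novel-amino-acid records at a threshold."""
    return int(
        (
            (records["snp_level"] == MISSENSE)
            & (records["mnv_level"] == MISSENSE)
            & (records["missense_subtype"] == NOVEL_AA)
            & (records["carrier_count"] >= threshold)
        ).sum()
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class PipelineResult:
    snp_annotations: pd.DataFrame
    mnv_table: pd.DataFrame
    trans_table: pd.DataFrame
    flux_table: pd.DataFrame
    summary: FluxSummary
    headline: dict
    stage_counts: dict
    flux_records: list[FluxRecord] = field(default_factory=list)


def _annotations_frame(annotations: list[SnpAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "snp_id": a.snp_id,
            "transcript_id": a.transcript_id,
            "cds_pos": a.assignment.cds_pos,
            "codon_index": a.assignment.codon_index,
            "codon_offset": a.assignment.codon_offset,
            "ref_codon": a.assignment.ref_codon,
            "alt_codon": a.assignment.alt_codon,
            "ref_aa": a.call.ref_aa,
            "alt_aa": a.call.alt_aa,
            "category": a.call.category,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=[
        "snp_id", "transcript_id", "cds_pos", "codon_index", "codon_offset",
        "ref_codon", "alt_codon", "ref_aa", "alt_aa", "category",
    ])


def flux_records_to_frame(
    records: list[FluxRecord],
    tx_by_id: dict[str, TranscriptModel],
    snps_by_id: dict[str, SnpRecord],
) -> pd.DataFrame:
    rows = []
    for r in records:
        cand = r.mnv.candidate
        tx = tx_by_id[cand.transcript_id]
        positions = [snps_by_id[s].pos for s in cand.snp_ids]
        rows.append(
            {
                "transcript_id": cand.transcript_id,
                "gene_id": tx.gene_id,
                "chrom": tx.chrom,
                "codon_index": cand.codon_index,
                "snp_ids": ",".join(cand.snp_ids),
                "offsets": ",".join(map(str, cand.offsets)),
                "positions": ",".join(map(str, positions)),
                "ref_codon": cand.ref_codon,
                "mnv_codon": r.mnv.mnv_codon,
                "ref_aa": r.mnv_level.ref_aa,
                "mnv_aa": r.mnv_level.alt_aa,
                "snp_level": r.snp_level.category,
                "mnv_level": r.mnv_level.category,
                "flux_class": r.flux_class,
                "missense_subtype": r.missense_subtype,
                "changed_impact": r.changed_impact,
                "rescued_stop": r.rescued_stop,
                "n_snps": cand.size,
                "carrier_count": r.carrier_count,
            }
        )
    return pd.DataFrame(rows, columns=FLUX_FRAME_COLUMNS)


def run_pipeline(vcf_path, gtf_path, fasta_path, *,
                 min_carriers: int = 5,
                 thresholds=DEFAULT_THRESHOLDS,
                 include_three_snp: bool = False,
                 sample_to_pop: dict[str, str] | None = None) -> PipelineResult:
    """Full analysis: parse inputs, annotate SNPs, group codons, phase
    samples, call MNVs, filter by carrier support and classify fluxes.

    Deterministic given the inputs.  Stage counts mirror the detection
    workflow: SNPs in CDS, codon groups, cis-phased MNVs, post-threshold
    MNVs, transcripts and genes hit.
    """
    genome = read_fasta(fasta_path)
    transcripts = read_gtf(gtf_path)
    snps, samples = read_vcf(vcf_path)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    snps_by_id = {s.snp_id: s for s in snps}

    usable_cache: dict[str, bool] = {}
    annotations: list[SnpAnnotation] = []
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for snp in snps:
        annotations.extend(
            annotate_snp(snp, by_chrom.get(snp.chrom, []), genome,
                         _usable_cache=usable_cache)
        )
    ann_by_key = {(a.snp_id, a.transcript_id): a for a in annotations}

    candidates = group_by_codon([a.assignment for a in annotations])
    mnv_calls, trans_rows = call_mnvs(candidates, snps_by_id, samples)
    kept = filter_by_support(mnv_calls, min_carriers=min_carriers)

    flux_source = [
        m for m in mnv_calls if include_three_snp or m.candidate.size == 2
    ]
    records = [
        flux_for_mnv(m, ann_by_key, tx_by_id[m.candidate.transcript_id].n_codons)
        for m in flux_source
    ]
    flux_table = flux_records_to_frame(records, tx_by_id, snps_by_id)
    summary = summarize_flux(flux_table, thresholds=thresholds)
    novel = novel_aa_count_at(flux_table, min_carriers) if len(flux_table) else 0
    headline = (
        headline_stats(summary, min_carriers, novel_aa_count=novel)
        if min_carriers in summary.thresholds
        else {}
    )

    mnv_rows = []
    for m in mnv_calls:
        cand = m.candidate
        tx = tx_by_id[cand.transcript_id]
        row = {
            "transcript_id": cand.transcript_id,
            "gene_id": tx.gene_id,
            "chrom": tx.chrom,
            "codon_index": cand.codon_index,
            "snp_ids": ",".join(cand.snp_ids),
            "offsets": ",".join(map(str, cand.offsets)),
            "ref_codon": cand.ref_codon,
            "mnv_codon": m.mnv_codon,
            "n_snps": cand.size,
            "carrier_count": m.carrier_count,
            "passes_threshold": m.carrier_count >= min_carriers,
        }
        if sample_to_pop:
            pops = m.population_counts(sample_to_pop)
            row["population_counts"] = ";".join(
                f"{p}:{n}" for p, n in sorted(pops.items())
            )
        mnv_rows.append(row)
    mnv_table = pd.DataFrame(mnv_rows)

    genomic_keys = set()
    for m in mnv_calls:
        positions = tuple(
            sorted(
                (snps_by_id[s].chrom, snps_by_id[s].pos,
                 snps_by_id[s].ref, snps_by_id[s].alt)
                for s in m.candidate.snp_ids
            )
        )
        genomic_keys.add(positions)

    stage_counts = {
        "n_samples": len(samples),
        "n_snps": len(snps),
        "n_snps_in_cds": len({a.snp_id for a in annotations}),
        "n_codon_groups": len(candidates),
        "n_mnvs_cis": len(mnv_calls),
        "n_mnvs_genomic_dedup": len(genomic_keys),
        "n_trans_only_groups": len(trans_rows),
        "n_mnvs_min_carriers": len(kept),
        "n_transcripts_with_mnv": len(
            {m.candidate.transcript_id for m in mnv_calls}
        ),
        "n_genes_with_mnv": len(
            {tx_by_id[m.candidate.transcript_id].gene_id for m in mnv_calls}
        ),
    }
    for key, value in stage_counts.items():
        logger.info("pipeline stage %s = %d", key, value)

    return PipelineResult(
        snp_annotations=_annotations_frame(annotations),
        mnv_table=mnv_table,
        trans_table=pd.DataFrame(
            trans_rows,
            columns=["transcript_id", "codon_index", "snp_ids",
                     "trans_sample_count"],
        ),
        flux_table=flux_table,
        summary=summary,
        headline=headline,
        stage_counts=stage_counts,
        flux_records=records,
    )
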