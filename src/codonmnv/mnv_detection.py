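"""Grouping of co-codon SNPs and cis/trans phase interpretation.

A multi-nucleotide variant (MNV) here is a group of 2-3 SNPs that fall
in the same codon of the same transcript *and* are carried on the same
haplotype (in cis) by at least one individual.  Phase is taken from the
GATK HaplotypeCaller physical-phasing FORMAT fields: two heterozygous
sites are in cis when they share a phase-set identifier (PID) and their
alternative alleles sit on the same side of the phased genotype (PGT),
e.g. ``0|1`` + ``0|1``; opposite sides (``0|1`` + ``1|0``) mean trans.
A sample homozygous for the alternative allele at every site is a cis
carrier with no phasing needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .consequence_engine import CodonAssignment
from .errors import DataConsistencyError, ParameterError
from .io_genomics import SampleCall, SnpRecord

logger = logging.getLogger(__name__)


class HaplotypeState(Enum):
    CIS_CARRIER = "cis_carrier"
    TRANS = "trans"
    UNPHASABLE = "unphasable"
    NON_CARRIER = "non_carrier"


@dataclass
class MnvCandidate:
    """2-3 SNPs sharing one codon of one transcript (phase not yet known)."""

    transcript_id: str
    codon_index: int
    assignments: list[CodonAssignment]  # ordered by codon_offset

    @property
    def snp_ids(self) -> list[str]:
        return [a.snp_id for a in self.assignments]

    @property
    def offsets(self) -> list[int]:
        return [a.codon_offset for a in self.assignments]

    @property
    def codon_key(self) -> str:
        return f"{self.transcript_id}:{self.codon_index}"

    @property
    def ref_codon(self) -> str:
        return self.assignments[0].ref_codon

    @property
    def size(self) -> int:
        return len(self.assignments)


@dataclass
class MnvCall:
    """A candidate with >= 1 cis carrier: an observed MNV."""

    candidate: MnvCandidate
    mnv_codon: str
    carrier_samples: set[str]
    trans_samples: set[str] = field(default_factory=set)
    unphasable_samples: set[str] = field(default_factory=set)

    @property
    def carrier_count(self) -> int:
        return len(self.carrier_samples)

    def population_counts(self, sample_to_pop: dict[str, str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.carrier_samples:
            pop = sample_to_pop.get(s, "unknown")
            counts[pop] = counts.get(pop, 0) + 1
        return counts


def group_by_codon(assignments: list[CodonAssignment]) -> list[MnvCandidate]:
    """Group per-(SNP, transcript) codon assignments into candidates: one
    candidate per (transcript, codon) carrying >= 2 distinct SNPs.

    Assignments must be unique per (snp_id, transcript_id); more than 3
    SNPs in one codon is impossible for biallelic SNPs at 3 offsets and
    is treated as a data error, as is an offset collision.
    """
    groups: dict[tuple[str, int], list[CodonAssignment]] = {}
    seen: set[tuple[str, str]] = set()
    for a in assignments:
        key = (a.snp_id, a.transcript_id)
        if key in seen:
            raise DataConsistencyError(
                f"duplicate assignment for SNP {a.snp_id} in {a.transcript_id}"
            )
        seen.add(key)
        groups.setdefault((a.transcript_id, a.codon_index), []).append(a)

    candidates = []
    for (tx_id, codon_index), members in groups.items():
        if len(members) < 2:
            continue
        offsets = [m.codon_offset for m in members]
        if len(set(offsets)) != len(offsets) or len(members) > 3:
            raise DataConsistencyError(
                f"codon {tx_id}:{codon_index} has colliding SNP offsets "
                f"{sorted(offsets)} — more than one biallelic SNP per base "
                "is not representable"
            )
        members = sorted(members, key=lambda m: m.codon_offset)
        candidates.append(MnvCandidate(tx_id, codon_index, members))
    candidates.sort(key=lambda c: (c.transcript_id, c.codon_index))
    return candidates


def _is_het(gt: tuple[int, int]) -> bool:
    return set(gt) == {0, 1}


def _is_hom_alt(gt: tuple[int, int]) -> bool:
    return set(gt) == {1}


def _pgt_alt_side(call: SampleCall) -> int | None:
    """Side (0 = left of '|', 1 = right) carrying the alt allele in the
    PGT of a heterozygous call; None when PGT is absent or inconsistent
    with the GT."""
    if call.pgt is None or call.pid is None:
        return None
    parts = call.pgt.split("|")
    if len(parts) != 2 or not all(p in {"0", "1"} for p in parts):
        return None
    alleles = tuple(int(p) for p in parts)
    if sorted(alleles) != sorted(call.gt):
        logger.warning("PGT %s inconsistent with GT %s", call.pgt, call.gt)
        return None
    return alleles.index(1)


def sample_haplotype_state(snps: list[SnpRecord], sample: str) -> HaplotypeState:
    """Decide whether one sample carries all alternative alleles of the
    candidate on a single haplotype.

    - any site without the alt allele (or no-call)          -> NON_CARRIER
    - every site homozygous-alt                             -> CIS_CARRIER
    - het sites all sharing one PID with alt alleles on the
      same PGT side (remaining sites hom-alt)               -> CIS_CARRIER
    - shared PID but alt alleles on opposite sides          -> TRANS
    - any het site lacking PGT/PID, or differing PIDs       -> UNPHASABLE
    """
    calls = [s.calls[sample] for s in snps]
    for c in calls:
        if c.gt is None or 1 not in c.gt:
            return HaplotypeState.NON_CARRIER
    het_calls = [c for c in calls if _is_het(c.gt)]
    if not het_calls:  # all hom-alt: both haplotypes carry everything
        return HaplotypeState.CIS_CARRIER
    sides = []
    pids = []
    for c in het_calls:
        side = _pgt_alt_side(c)
        if side is None:
            return HaplotypeState.UNPHASABLE
        sides.append(side)
        pids.append(c.pid)
    if len(set(pids)) != 1:
        return HaplotypeState.UNPHASABLE
    return (
        HaplotypeState.CIS_CARRIER if len(set(sides)) == 1 else HaplotypeState.TRANS
    )


def build_mnv_codon_from(candidate: MnvCandidate) -> str:
    codon = list(candidate.ref_codon)
    for a in candidate.assignments:
        codon[a.codon_offset - 1] = a.alt_allele_coding
    return "".join(codon)


def call_mnvs(
    candidates: list[MnvCandidate],
    snps_by_id: dict[str, SnpRecord],
    samples: list[str],
) -> tuple[list[MnvCall], list[dict]]:
    """Phase every sample for every candidate.

    Returns (mnv_calls, trans_only_rows): an :class:`MnvCall` is emitted
    iff at least one sample is a cis carrier; codon groups observed only
    in trans produce a side-table row instead (they are pairs of SNPs on
    opposite haplotypes, not MNVs).
    """
    calls: list[MnvCall] = []
    trans_rows: list[dict] = []
    for cand in candidates:
        snps = [snps_by_id[sid] for sid in cand.snp_ids]
        states = {s: sample_haplotype_state(snps, s) for s in samples}
        carriers = {s for s, st in states.items() if st is HaplotypeState.CIS_CARRIER}
        trans = {s for s, st in states.items() if st is HaplotypeState.TRANS}
        unph = {s for s, st in states.items() if st is HaplotypeState.UNPHASABLE}
        if carriers:
            calls.append(
                MnvCall(
                    candidate=cand,
                    mnv_codon=build_mnv_codon_from(cand),
                    carrier_samples=carriers,
                    trans_samples=trans,
                    unphasable_samples=unph,
                )
            )
        elif trans:
            trans_rows.append(
                {
                    "transcript_id": cand.transcript_id,
                    "codon_index": cand.codon_index,
                    "snp_ids": ",".join(cand.snp_ids),
                    "trans_sample_count": len(trans),
                }
            )
    return calls, trans_rows


def filter_by_support(mnv_calls: list[MnvCall], min_carriers: int = 5) -> list[MnvCall]:
    """Keep MNVs carried by >= ``min_carriers`` individuals.

    The default of 5 follows the reliability threshold used for the
    cohort analysis; carrier_count == 1 groups are flagged in the log as
    likely sequencing errors.
    """
    if min_carriers < 1:
        raise ParameterError(f"min_carriers must be >= 1, got {min_carriers}")
    n_singletons = sum(1 for c in mnv_calls if c.carrier_count == 1)
    if n_singletons:
        logger.info(
            "%d MNVs observed in a single individual (likely erroneous)",
            n_singletons,
        )
    return [c for c in mnv_calls if c.carrier_count >= min_carriers]
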