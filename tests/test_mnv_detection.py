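import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonmnv.consequence_engine import CodonAssignment
from codonmnv.errors import DataConsistencyError, ParameterError
from codonmnv.io_genomics import SampleCall, SnpRecord
from codonmnv.mnv_detection import (
    HaplotypeState,
    MnvCall,
    MnvCandidate,
    call_mnvs,
    filter_by_support,
    group_by_codon,
    sample_haplotype_state,
)


def _assign(snp_id, tx="txA", codon_index=4, offset=1, ref_codon="CGA"):
    cds_pos = 3 * (codon_index - 1) + offset
    return CodonAssignment(
        transcript_id=tx,
        snp_id=snp_id,
        cds_pos=cds_pos,
        codon_index=codon_index,
        codon_offset=offset,
        ref_codon=ref_codon,
        ref_allele_coding=ref_codon[offset - 1],
        alt_allele_coding={"C": "T", "G": "A", "A": "C", "T": "G"}[
            ref_codon[offset - 1]
        ],
    )


# ---------------------------------------------------------------------------
# Codon grouping


def test_group_by_codon_pairs_and_triples():
    assignments = [
        _assign("s1", offset=1),
        _assign("s2", offset=3),
        _assign("s3", tx="txB", codon_index=2, offset=1),
        _assign("s4", tx="txC", offset=1),
        _assign("s5", tx="txC", offset=2),
        _assign("s6", tx="txC", offset=3),
    ]
    cands = group_by_codon(assignments)
    by_tx = {c.transcript_id: c for c in cands}
    assert set(by_tx) == {"txA", "txC"}  # lone SNP in txB yields no candidate
    assert by_tx["txA"].size == 2 and by_tx["txA"].offsets == [1, 3]
    assert by_tx["txC"].size == 3


def test_group_by_codon_offset_collision_is_data_error():
    with pytest.raises(DataConsistencyError, match="colliding"):
        group_by_codon([_assign("s1", offset=2), _assign("s2", offset=2)])


def test_group_by_codon_duplicate_assignment_is_data_error():
    with pytest.raises(DataConsistencyError, match="duplicate"):
        group_by_codon([_assign("s1"), _assign("s1")])


# ---------------------------------------------------------------------------
# Phase interpretation


def _pair(call1, call2):
    s1 = SnpRecord("chr1", 100, "s1", "C", "T", {"X": call1})
    s2 = SnpRecord("chr1", 102, "s2", "A", "C", {"X": call2})
    return [s1, s2]


def _c(gt, pgt=None, pid=None):
    return SampleCall(gt=gt, phased=False, pgt=pgt, pid=pid)


@pytest.mark.parametrize(
    "call1,call2,expected",
    [
        # same PID, same PGT side -> cis
        (_c((0, 1), "0|1", "p"), _c((0, 1), "0|1", "p"), HaplotypeState.CIS_CARRIER),
        (_c((0, 1), "1|0", "p"), _c((0, 1), "1|0", "p"), HaplotypeState.CIS_CARRIER),
        # opposite PGT sides -> trans
        (_c((0, 1), "0|1", "p"), _c((0, 1), "1|0", "p"), HaplotypeState.TRANS),
        # homozygous alt at both sites: cis without phasing
        (_c((1, 1)), _c((1, 1)), HaplotypeState.CIS_CARRIER),
        # hom-alt + phased het: cis
        (_c((1, 1)), _c((0, 1), "0|1", "p"), HaplotypeState.CIS_CARRIER),
        # het lacking phase info -> unphasable
        (_c((0, 1), "0|1", "p"), _c((0, 1)), HaplotypeState.UNPHASABLE),
        # hom-alt + unphased het -> unphasable (not a carrier)
        (_c((1, 1)), _c((0, 1)), HaplotypeState.UNPHASABLE),
        # differing PIDs -> unphasable
        (_c((0, 1), "0|1", "p1"), _c((0, 1), "0|1", "p2"), HaplotypeState.UNPHASABLE),
        # PGT inconsistent with GT -> unphasable with warning
        (_c((0, 1), "1|1", "p"), _c((0, 1), "0|1", "p"), HaplotypeState.UNPHASABLE),
        # missing alt allele -> non-carrier
        (_c((0, 0)), _c((0, 1), "0|1", "p"), HaplotypeState.NON_CARRIER),
        (_c(None), _c((0, 1), "0|1", "p"), HaplotypeState.NON_CARRIER),
    ],
)
def test_sample_haplotype_state(call1, call2, expected):
    assert sample_haplotype_state(_pair(call1, call2), "X") is expected


def test_three_snp_cis_and_trans():
    def triple(c1, c2, c3):
        return [
            SnpRecord("chr1", 100 + i, f"s{i}", "C", "T", {"X": c})
            for i, c in enumerate((c1, c2, c3))
        ]

    cis = triple(_c((0, 1), "0|1", "p"), _c((0, 1), "0|1", "p"), _c((1, 1)))
    assert sample_haplotype_state(cis, "X") is HaplotypeState.CIS_CARRIER
    trans = triple(_c((0, 1), "0|1", "p"), _c((0, 1), "1|0", "p"), _c((1, 1)))
    assert sample_haplotype_state(trans, "X") is HaplotypeState.TRANS


@given(
    gts=st.lists(
        st.sampled_from([(0, 0), (0, 1), (1, 1), None]), min_size=2, max_size=3
    ),
    phased=st.booleans(),
    side=st.integers(0, 1),
)
@settings(max_examples=200, derandomize=True)
def test_state_partition_property(gts, phased, side):
    """Exactly one of the four states is always returned, and making a
    cis carrier homozygous-alt everywhere never demotes it."""
    pgt = ("0|1" if side else "1|0") if phased else None
    pid = "p" if phased else None
    snps = [
        SnpRecord(
            "chr1", 100 + i, f"s{i}", "C", "T",
            {"X": SampleCall(gt, False, pgt if gt == (0, 1) else None,
                             pid if gt == (0, 1) else None)},
        )
        for i, gt in enumerate(gts)
    ]
    state = sample_haplotype_state(snps, "X")
    assert state in HaplotypeState
    if state is HaplotypeState.CIS_CARRIER:
        hom = [
            SnpRecord("chr1", 100 + i, f"s{i}", "C", "T",
                      {"X": SampleCall((1, 1), False)})
            for i in range(len(gts))
        ]
        assert sample_haplotype_state(hom, "X") is HaplotypeState.CIS_CARRIER


# ---------------------------------------------------------------------------
# Calling and support filtering


def _candidate_with_samples(n_cis, n_trans, n_unphasable=0):
    a1, a2 = _assign("m1", offset=1), _assign("m2", offset=3)
    cand = MnvCandidate("txA", 4, [a1, a2])
    calls1, calls2, samples = {}, {}, []
    i = 0
    for _ in range(n_cis):
        s = f"S{i}"; i += 1
        calls1[s] = _c((0, 1), "0|1", "p"); calls2[s] = _c((0, 1), "0|1", "p")
        samples.append(s)
    for _ in range(n_trans):
        s = f"S{i}"; i += 1
        calls1[s] = _c((0, 1), "0|1", "p"); calls2[s] = _c((0, 1), "1|0", "p")
        samples.append(s)
    for _ in range(n_unphasable):
        s = f"S{i}"; i += 1
        calls1[s] = _c((0, 1)); calls2[s] = _c((0, 1))
        samples.append(s)
    snps = {
        "m1": SnpRecord("chr1", 100, "m1", "C", "T", calls1),
        "m2": SnpRecord("chr1", 102, "m2", "A", "C", calls2),
    }
    return cand, snps, samples


def test_call_mnvs_counts_cis_carriers():
    cand, snps, samples = _candidate_with_samples(n_cis=7, n_trans=3)
    calls, trans_rows = call_mnvs([cand], snps, samples)
    assert len(calls) == 1 and not trans_rows
    assert calls[0].carrier_count == 7
    assert len(calls[0].trans_samples) == 3
    assert calls[0].mnv_codon == "TGC"  # CGA with T@1, C@3


def test_trans_only_group_goes_to_side_table():
    cand, snps, samples = _candidate_with_samples(n_cis=0, n_trans=4)
    calls, trans_rows = call_mnvs([cand], snps, samples)
    assert calls == []
    assert len(trans_rows) == 1 and trans_rows[0]["trans_sample_count"] == 4


def _mk_call(carrier_count):
    cand, snps, samples = _candidate_with_samples(n_cis=carrier_count, n_trans=0)
    return MnvCall(cand, "TGC", {f"S{i}" for i in range(carrier_count)})


def test_filter_by_support_boundary():
    calls = [_mk_call(4), _mk_call(5), _mk_call(1)]
    kept = filter_by_support(calls, min_carriers=5)
    assert [c.carrier_count for c in kept] == [5]
    assert filter_by_support(calls, min_carriers=1) == calls  # identity
    with pytest.raises(ParameterError):
        filter_by_support(calls, min_carriers=0)


@given(
    counts=st.lists(st.integers(1, 50), min_size=0, max_size=20),
    t1=st.integers(1, 40),
    t2=st.integers(1, 40),
)
@settings(max_examples=100, derandomize=True)
def test_filter_monotone_in_threshold(counts, t1, t2):
    calls = [_mk_call(c) for c in counts]
    lo, hi = sorted((t1, t2))
    assert len(filter_by_support(calls, hi)) <= len(filter_by_support(calls, lo))
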