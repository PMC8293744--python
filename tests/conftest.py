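import pandas as pd
import pytest

from codonmnv.io_genomics import GenomeSequence, SampleCall, TranscriptModel
from codonmnv.reannotation_flux import run_pipeline
from codonmnv.synthetic_data import (
    default_fixture_config,
    plan_fixture,
    write_fixture,
)

# ---------------------------------------------------------------------------
# Independent genetic-code oracle: a literal 64-entry table (base order
# T, C, A, G), deliberately not derived from any library the package uses.

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE_ORACLE = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}


def oracle_classify(ref_codon, alt_codon, codon_index=5, n_codons=10):
    """Brute-force consequence classifier over the literal table; written
    independently of the engine under test."""
    ref_aa = CODON_TABLE_ORACLE[ref_codon]
    alt_aa = CODON_TABLE_ORACLE[alt_codon]
    if codon_index == 1 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if ref_aa == "*":
        return "stop_retained" if alt_aa == "*" else "stop_lost"
    if alt_aa == "*":
        return "stop_gained"
    return "synonymous" if ref_aa == alt_aa else "missense"


# ---------------------------------------------------------------------------
# Hand-built toy genome/transcripts for unit tests


@pytest.fixture
def toy_genome():
    # chr1: 10 bp pad + 30 bp CDS (+ strand) + pad
    cds = "ATGCTTACGCGATCAAAGGATTGTCCGTAA"  # ATG ... CGA at codon 4 ... TAA
    seq = "GGGGGGGGGG" + cds + "GGGGGGGGGG"
    return GenomeSequence({"chr1": seq}), cds


@pytest.fixture
def toy_transcript():
    return TranscriptModel(
        transcript_id="tx1",
        gene_id="g1",
        chrom="chr1",
        strand="+",
        cds_segments=[(11, 40)],
    )


def make_call(gt, pgt=None, pid=None):
    return SampleCall(gt=gt, phased=False, pgt=pgt, pid=pid)


# ---------------------------------------------------------------------------
# Session-scoped synthetic fixture + pipeline run (shared across modules)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    plan = plan_fixture(default_fixture_config(seed=1))
    paths = write_fixture(plan, str(outdir))
    return paths


@pytest.fixture(scope="session")
def fixture_manifest(fixture_paths):
    return pd.read_csv(fixture_paths["manifest"], sep="\t")


@pytest.fixture(scope="session")
def pipeline_result(fixture_paths):
    return run_pipeline(
        fixture_paths["vcf"],
        fixture_paths["gtf"],
        fixture_paths["fasta"],
        min_carriers=5,
    )
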