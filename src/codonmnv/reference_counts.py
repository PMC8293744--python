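"""Published cohort re-annotation counts used as a worked example.

A large RNA-seq survey of 382 chickens from 11 populations reported, for
every (SNP-level annotation -> MNV-level annotation) transition, the
number of two-SNP in-codon MNVs carried by at least 1, 2, 3, 4, 5, 10,
15, 20, 30, 50 and 100 individuals, plus the number of
missense -> missense MNVs whose amino acid was novel relative to both
constituent SNPs among the MNVs carried by >= 5 individuals (1,038).

These printed counts are inputs: :func:`expand_to_records` inflates the
cumulative matrix back into a record-level table (one row per MNV with a
concrete carrier count), which the ordinary ``summarize_flux`` /
``headline_stats`` path then re-aggregates.  Every percentage quoted in
the survey is recomputed from that table at run time.
"""

from __future__ import annotations

import pandas as pd

from .consequence_engine import (
    MISSENSE,
    START_LOST,
    STOP_GAINED,
    STOP_LOST,
    STOP_RETAINED,
    SYNONYMOUS,
)
from .reannotation_flux import NOT_APPLICABLE, NOVEL_AA, SHARED_AA

#: Carrier-count thresholds of the published matrix.
COHORT_THRESHOLDS = (1, 2, 3, 4, 5, 10, 15, 20, 30, 50, 100)

#: (snp_level, mnv_level) -> cumulative MNV counts at COHORT_THRESHOLDS.
COHORT_FLUX_COUNTS: dict[tuple[str, str], tuple[int, ...]] = {
    # eased impact
    (MISSENSE, SYNONYMOUS): (110, 91, 86, 86, 83, 76, 74, 74, 72, 66, 54),
    (STOP_GAINED, MISSENSE): (194, 118, 102, 99, 87, 63, 47, 39, 33, 27, 14),
    # equal impact
    (STOP_LOST, STOP_LOST): (8, 4, 4, 4, 4, 2, 2, 2, 2, 1, 0),
    (START_LOST, START_LOST): (19, 11, 11, 11, 11, 8, 7, 6, 5, 3, 1),
    (SYNONYMOUS, SYNONYMOUS): (95, 84, 81, 78, 76, 69, 63, 58, 54, 45, 32),
    (MISSENSE, MISSENSE): (
        4932, 3425, 3107, 2854, 2688, 2162, 1876, 1652, 1369, 1083, 716,
    ),
    (STOP_GAINED, STOP_GAINED): (12, 6, 5, 5, 4, 3, 2, 2, 2, 1, 0),
    # aggravated impact
    (STOP_RETAINED, STOP_LOST): (1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    (SYNONYMOUS, MISSENSE): (15, 6, 6, 4, 3, 2, 1, 1, 1, 1, 1),
    (MISSENSE, STOP_GAINED): (30, 13, 11, 10, 9, 6, 4, 3, 3, 2, 1),
}

#: missense->missense MNVs (>= 5 carriers) with a novel amino acid.
COHORT_NOVEL_AA_MIN5 = 1038

#: Cohort scale, for context in reports.
COHORT_N_INDIVIDUALS = 382
COHORT_N_POPULATIONS = 11


def expand_to_records() -> pd.DataFrame:
    """Record-level table consistent with the cumulative cohort matrix.

    Each cumulative count c(t) is differenced into bins between adjacent
    thresholds; the records in bin [t_i, t_{i+1}) are assigned carrier
    count t_i (the exact within-bin distribution is unknowable from the
    matrix and irrelevant to any statistic evaluated at the published
    thresholds).  The 1,038 novel-amino-acid missense records are
    allocated to the highest-carrier missense -> missense records, which
    again only matters at the >= 5 threshold where the count is exact.
    """
    thresholds = list(COHORT_THRESHOLDS)
    rows = []
    for (snp_cat, mnv_cat), counts in COHORT_FLUX_COUNTS.items():
        for i, t in enumerate(thresholds):
            upper = counts[i + 1] if i + 1 < len(counts) else 0
            n_bin = counts[i] - upper
            if n_bin < 0:
                raise ValueError(
                    f"cohort counts for {snp_cat}->{mnv_cat} are not "
                    "monotone non-increasing"
                )
            rows.extend(
                {"snp_level": snp_cat, "mnv_level": mnv_cat, "carrier_count": t}
                for _ in range(n_bin)
            )
    df = pd.DataFrame(rows, columns=["snp_level", "mnv_level", "carrier_count"])
    df["n_snps"] = 2
    df["missense_subtype"] = NOT_APPLICABLE

    mm = (df["snp_level"] == MISSENSE) & (df["mnv_level"] == MISSENSE)
    df.loc[mm, "missense_subtype"] = SHARED_AA
    eligible = df.index[mm & (df["carrier_count"] >= 5)]
    eligible = sorted(
        eligible, key=lambda i: -int(df.at[i, "carrier_count"])
    )[:COHORT_NOVEL_AA_MIN5]
    df.loc[eligible, "missense_subtype"] = NOVEL_AA
    return df.reset_index(drop=True)
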