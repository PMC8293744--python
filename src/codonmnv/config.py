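"""Run configuration for the detection pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError
from .reannotation_flux import DEFAULT_THRESHOLDS


@dataclass
class RunConfig:
    """Knobs of the detection/re-annotation run.

    ``min_carriers`` (default 5) is the reliability threshold: an MNV
    must be carried in cis by at least that many individuals.
    ``thresholds`` is the ladder of carrier counts the summary matrix is
    tabulated over.  3-SNP codon groups are detected and called but only
    enter the flux analysis when ``include_three_snp`` is set.
    """

    min_carriers: int = 5
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    include_three_snp: bool = False
    population_map: dict[str, str] | None = None
    outdir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        if self.min_carriers < 1:
            raise ParameterError("min_carriers must be >= 1")
        t = list(self.thresholds)
        if any(x < 1 for x in t) or t != sorted(set(t)):
            raise ParameterError(
                "thresholds must be strictly increasing positive integers"
            )
        self.thresholds = tuple(t)


def read_population_map(path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> dict."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParameterError("population map needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
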