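"""Exception hierarchy shared across the package.

All errors raised by the library derive from :class:`CodonMnvError` so
callers (and the CLI) can separate data problems from programming bugs.
"""


class CodonMnvError(Exception):
    """Base class for all package errors."""


class FormatError(CodonMnvError):
    """An input file violates its format contract (FASTA/GTF/VCF/TSV)."""


class DataConsistencyError(CodonMnvError):
    """Inputs are individually well-formed but mutually inconsistent,
    e.g. a VCF REF allele disagreeing with the genome sequence."""


class ParameterError(CodonMnvError):
    """A user-supplied parameter is out of its valid range."""


class PlanningError(CodonMnvError):
    """A synthetic-fixture design cannot be realized in the standard
    genetic code (e.g. synonymous + synonymous -> stop_gained)."""
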