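"""Exception hierarchy shared across the pipeline.

Readers reject malformed input instead of coercing it; statistics raise
:class:`UndefinedStatistic` rather than returning NaN when a quantity has
no defined value (e.g. Tajima's D on a monomorphic alignment).
"""


class VentpopError(Exception):
    """Base class for all errors raised by ventpop."""


class FormatError(VentpopError):
    """Malformed input file (bad FASTA, duplicate ids, bad table header...)."""


class AlignmentError(VentpopError):
    """Sequences that should form an alignment do not (ragged lengths...)."""


class CrossReferenceError(VentpopError):
    """A strain id appears in a data file but not in the metadata table."""

    def __init__(self, message, offenders=()):
        super().__init__(message)
        self.offenders = tuple(offenders)


class ConfigurationError(VentpopError):
    """Invalid simulation or pipeline configuration."""


class UndefinedStatistic(VentpopError):
    """The requested statistic is undefined for this input."""


class NotComputable(VentpopError):
    """The test cannot be run on this input (e.g. too few informative sites)."""


class SaturationError(VentpopError):
    """A distance correction is undefined because divergence is saturated."""

    def __init__(self, message, pairs=()):
        super().__init__(message)
        self.pairs = tuple(pairs)
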