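"""Exception hierarchy for annodepth."""


class AnnodepthError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AnnodepthError, ValueError):
    """Invalid generator / experiment parameters."""


class ValidationError(AnnodepthError, ValueError):
    """A domain-type invariant was violated."""


class QuantificationError(AnnodepthError, ValueError):
    """Quantification is undefined for the given inputs (e.g. no mapped reads)."""


class NormalizationError(AnnodepthError, ValueError):
    """TMM / correction cannot be computed (e.g. too few surviving genes)."""


class SchemaError(AnnodepthError, ValueError):
    """A table on disk does not conform to its declared dialect."""
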