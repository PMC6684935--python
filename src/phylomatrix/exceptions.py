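"""Exception hierarchy for phylomatrix."""


class PhylomatrixError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhylomatrixError):
    """An invalid configuration value; the message names the offending field."""


class DataError(PhylomatrixError):
    """Malformed input data (negative e-values, unknown residue symbols, ...)."""


class AlignmentError(PhylomatrixError):
    """Unaligned or ragged sequences where an alignment is required."""


class LabelingError(PhylomatrixError):
    """Tip labels and sequence/taxon identifiers do not match up."""


class StatisticalError(PhylomatrixError):
    """Too few data points for the requested statistic."""
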