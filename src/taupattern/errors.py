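"""Exception hierarchy shared across the pipeline stages."""


class TauPatternError(Exception):
    """Base class for all package errors."""


class ConfigError(TauPatternError, ValueError):
    """Invalid configuration (bad fractions, counts, thresholds, missing groups)."""


class FormatError(TauPatternError, ValueError):
    """Malformed input table (duplicate ids, non-numeric cells, missing columns)."""


class AnalysisError(TauPatternError, RuntimeError):
    """A statistical stage cannot run on the given data (empty design cell, no DEGs)."""
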