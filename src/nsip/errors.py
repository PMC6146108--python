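"""Typed exceptions raised across the pipeline.

Every validation failure raises one of these; callers never receive a
partially constructed object.
"""


class NsipError(Exception):
    """Base class for all package errors."""


class ConfigError(NsipError):
    """Invalid configuration value or inconsistent simulation setup."""


class FormatError(NsipError):
    """Malformed input table: missing column, bad dtype, duplicate key."""


class VocabularyError(NsipError):
    """Unknown controlled-vocabulary token (substrate, label, light level)."""


class LinkageError(NsipError):
    """Cross-table reference error, e.g. a count row pointing at a fraction
    that does not exist in its gradient."""


class EmptyGradientError(NsipError):
    """Every fraction of a gradient fell below the read-count threshold."""


class InfeasibleRateError(NsipError):
    """A simulated uptake rate would drive particulate atom% above the
    dissolved-pool enrichment within the incubation."""


class UndefinedPoolError(NsipError):
    """Dissolved substrate pool of size zero; mixing ratio undefined."""


class InputError(NsipError):
    """Invalid numeric input to a rate or integration routine."""
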