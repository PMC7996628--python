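"""Exception hierarchy shared by the whole pipeline.

The CLI maps these onto distinct exit codes, so every stage raises one of
the subclasses below rather than a bare ``ValueError``.
"""


class FrailtyKitError(Exception):
    """Base class for all package errors."""


class ParseError(FrailtyKitError):
    """A file could not be parsed; the message names the offending line/record."""


class ValidationError(FrailtyKitError):
    """Parsed data violates a structural invariant (ordering, shape, range)."""


class QualityError(FrailtyKitError):
    """Data parsed fine but is too degraded to analyse (e.g. too many missing frames)."""


class ConfigurationError(FrailtyKitError):
    """Bad configuration: unknown backend, malformed config file, bad parameter."""


class ComputationError(FrailtyKitError):
    """A numerical stage cannot proceed (degenerate geometry, no movement, ...)."""


class FeatureUnavailable(FrailtyKitError):
    """A single phenotype feature cannot be computed; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
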