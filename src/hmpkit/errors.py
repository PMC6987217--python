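"""Exception and warning types shared across hmpkit."""


class HmpkitError(Exception):
    """Base class for all hmpkit errors."""


class ConfigError(HmpkitError, ValueError):
    """Invalid configuration; ``fields`` lists the offending field names."""

    def __init__(self, message, fields=()):
        super().__init__(message)
        self.fields = tuple(fields)


class SchemaError(HmpkitError, ValueError):
    """A file does not match its declared schema (e.g. missing column)."""


class DegenerateGeometryError(HmpkitError, ValueError):
    """Point set too small or collinear for a rigid fit."""


class NoCrossingError(HmpkitError, ValueError):
    """Flexion never crosses the critical angle with positive slope."""


class EmptyPhaseError(HmpkitError, ValueError):
    """A movement phase could not be delimited (e.g. maximum at first sample)."""


class ZeroVarianceError(HmpkitError, ValueError):
    """A statistic requiring positive variance received constant data."""


class ConstantInputError(HmpkitError, ValueError):
    """Regression predictor is constant."""


class MissingRegionError(HmpkitError, ValueError):
    """A cartilage record set does not contain exactly the seven regions."""


class UnknownShoeError(HmpkitError, KeyError):
    """A footwear condition label is not defined for the subject."""


class SubjectMismatchError(HmpkitError, ValueError):
    """Deviation and reduction tables disagree on the subject set."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class GimbalWarning(UserWarning):
    """Middle Cardan angle within tolerance of +/-90 degrees."""


class TieBreakWarning(UserWarning):
    """A tie was resolved by the documented deterministic rule."""
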