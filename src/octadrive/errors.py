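"""Exception types shared across the package."""


class OctadriveError(Exception):
    """Base class for all package-specific errors."""


class IncompatibleCrossError(OctadriveError, ValueError):
    """Both parents carry the same mating type; no zygote can form."""


class FormatError(OctadriveError, ValueError):
    """A table or configuration file violates the expected schema."""


class NoDataError(OctadriveError, ValueError):
    """An operation received an empty input where observations are required."""


class DegenerateTableError(OctadriveError, ValueError):
    """A contingency table has a zero row or column margin."""


class NotInCrossError(OctadriveError, KeyError):
    """The requested chromosome is absent from both parents of the cross."""


class ConfigError(OctadriveError, ValueError):
    """A configuration value is missing or outside its allowed range."""
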