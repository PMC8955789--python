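"""Exception hierarchy shared across the package."""


class CastevarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CastevarError):
    """Invalid configuration or missing/mismatched inputs (CLI exit code 2)."""


class GenerationError(CastevarError):
    """The synthetic generator cannot satisfy the requested parameters."""


class VcfParseError(CastevarError):
    """A VCF could not be parsed."""


class DataConsistencyError(CastevarError):
    """Inputs disagree with each other (CLI exit code 3)."""


class ReferenceMismatchError(DataConsistencyError):
    """A variant's REF allele disagrees with the reference sequence."""


class SaturationError(CastevarError, ValueError):
    """A substitution proportion >= 3/4 cannot be Jukes-Cantor corrected."""


class DegenerateInputError(CastevarError, ValueError):
    """An estimate is requested from inputs with no usable signal."""
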