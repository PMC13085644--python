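"""Exception hierarchy shared across chemcal modules."""


class ChemcalError(Exception):
    """Base class for all chemcal errors."""


class ConfigurationError(ChemcalError):
    """Invalid configuration or unsupported option."""


class UnsupportedDesignError(ConfigurationError):
    """Requested experimental design cannot be constructed."""


class DomainError(ChemcalError):
    """Input violates a documented precondition."""


class InfeasibleDesignError(ChemcalError):
    """Requested selection size cannot support the model."""


class NumericalRankError(ChemcalError):
    """All attempted designs were singular."""


class CollinearityError(ChemcalError):
    """Concentration matrix is rank-deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = columns or []


class AlignmentError(ChemcalError):
    """Wavelength grids (or shapes) do not match."""


class AssignmentError(ChemcalError):
    """Resolved components cannot be unambiguously mapped to analytes."""


class ParseError(ChemcalError):
    """Malformed input file."""
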