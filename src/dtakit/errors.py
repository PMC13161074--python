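"""Exception hierarchy shared across the package."""


class DTAKitError(Exception):
    """Base class for all package errors."""


class FormatError(DTAKitError):
    """A file does not conform to the expected tabular/FASTA layout."""


class ParseError(DTAKitError):
    """A field could not be parsed; carries the offending row when known."""


class DomainError(DTAKitError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InvalidStructureError(DTAKitError):
    """A SMILES string could not be parsed into a molecule."""


class ConfigError(DTAKitError):
    """An unknown backend, mode, or inconsistent configuration value."""


class ShapeError(DTAKitError, ValueError):
    """Array dimensions incompatible with the requested operation."""
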