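"""Exception hierarchy shared across the package."""


class SuperbarcodeError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(SuperbarcodeError):
    """Raised when sequences in a putative alignment have unequal lengths."""


class AlphabetError(SuperbarcodeError):
    """Raised when a sequence contains a character outside IUPAC+gap."""


class CoordinateError(SuperbarcodeError):
    """Raised when a feature or interval falls outside its sequence."""


class TreeError(SuperbarcodeError):
    """Raised for malformed trees (duplicate leaves, bad Newick, leaf-set mismatch)."""


class ConfigurationError(SuperbarcodeError):
    """Raised when parameters are inconsistent or a scoring scheme is degenerate."""
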