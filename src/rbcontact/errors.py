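"""Exception types shared across the package."""


class RBContactError(Exception):
    """Base class for all package-specific errors."""


class AlignmentFormatError(RBContactError, ValueError):
    """A file does not parse as the declared alignment format."""


class EmptyInputError(RBContactError, ValueError):
    """An input file or alignment contains no usable records."""


class EmptyPairingError(RBContactError, ValueError):
    """No organism is shared between the protein and RNA alignments."""


class AlphabetError(RBContactError, ValueError):
    """A residue or base character is outside the declared alphabet."""


class MissingLabelError(RBContactError, ValueError):
    """A training operation received an instance without a contact grid."""


class GridSizeError(RBContactError, ValueError):
    """A grid is too large for exhaustive enumeration."""


class UndefinedAUCError(RBContactError, ValueError):
    """ROC analysis is undefined because only one class is present."""


class CoordinateMismatchError(RBContactError, ValueError):
    """Structure-derived sequence does not match the target sequence."""


class NumericError(RBContactError, RuntimeError):
    """A numerical routine produced a non-finite value."""
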