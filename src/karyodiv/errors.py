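"""Exception hierarchy shared across the package."""


class KaryodivError(Exception):
    """Base class for all package errors."""


class FormatError(KaryodivError):
    """Malformed input file (missing column, bad header, empty table)."""


class ValidationError(KaryodivError):
    """Structurally valid input carrying invalid values."""


class InsufficientComplementError(ValidationError):
    """A metaphase has too few chromosomes for the requested pairing."""


class AmbiguousModeError(ValidationError):
    """Tied chromosome-number mode; the modal complement is undefined."""

    def __init__(self, tied):
        self.tied = tuple(sorted(tied))
        super().__init__(
            f"ambiguous modal chromosome number: counts tie at {self.tied}"
        )


class AlignmentError(KaryodivError):
    """Sequences incompatible with the requested alignment operation."""
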