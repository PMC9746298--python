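"""Exception hierarchy for rgptyper."""


class RgpTyperError(Exception):
    """Base class for all rgptyper errors."""


class SchemeError(RgpTyperError):
    """A typing scheme failed validation."""


class SchemeParseError(SchemeError):
    """A scheme-definition file could not be parsed."""


class SchemeLookupError(RgpTyperError, KeyError):
    """A primer pair or map entry is absent from the scheme."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class InputError(RgpTyperError, ValueError):
    """Malformed user input (bad alphabet, bad parameter)."""


class AssayInvalidError(RgpTyperError):
    """A panel's control reaction failed; no call can be made."""


class AnchorNotFoundError(RgpTyperError):
    """No gene matched an anchor query at the required identity/coverage."""


class SplitLocusError(RgpTyperError):
    """The two locus anchors were found on different contigs."""
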