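"""Exception hierarchy shared across the package."""


class MirstabError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MirstabError):
    """A file or record could not be parsed; the message names the record."""


class ValidationError(MirstabError):
    """An in-memory object violates one of its invariants."""


class NonHairpinError(MirstabError):
    """A secondary structure is not a single hairpin (no pairs or multibranch)."""
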