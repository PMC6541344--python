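"""Exception hierarchy for triogrs."""


class TrioGRSError(Exception):
    """Base class for all triogrs errors."""


class ParseError(TrioGRSError):
    """A file could not be parsed (malformed row, missing column, ...)."""


class ValidationError(TrioGRSError):
    """Parsed content violates a domain invariant."""


class AlignmentError(TrioGRSError):
    """Genotype alleles cannot be reconciled with the weight table."""
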