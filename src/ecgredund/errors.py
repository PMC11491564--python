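"""Exception taxonomy shared by all modules.

All failures that stem from violated call contracts, malformed input files,
or mathematically undefined quantities raise one of these, so callers can
distinguish "you called it wrong" from "the answer does not exist here".
"""


class EcgRedundError(Exception):
    """Base class for all package-specific errors."""


class ContractError(EcgRedundError, ValueError):
    """A precondition of an operation was violated by the caller."""


class FormatError(EcgRedundError, ValueError):
    """An input file is malformed or uses an unsupported convention."""


class UndefinedValueError(EcgRedundError, ArithmeticError):
    """The requested quantity is mathematically undefined for this input
    (e.g. NMI of two constant channels, PCC of a zero-variance channel)."""


class InternalConsistencyError(EcgRedundError):
    """A numerical invariant the implementation guarantees was violated by
    more than the documented tolerance; indicates a bug, not bad input."""
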