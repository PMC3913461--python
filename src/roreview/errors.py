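"""Exception hierarchy.

All data-level problems raise :class:`RoreviewError` subclasses so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class RoreviewError(Exception):
    """Base class for all domain errors raised by this package."""


class PairingError(RoreviewError):
    """An unpaired or mis-ordered c1/c2/d1/d2 therapy event."""


class OverlapError(RoreviewError):
    """Therapy events imply overlapping compression/defibrillation intervals."""


class EmptyDomainError(RoreviewError):
    """A domain sequence was requested from zero events."""


class OutOfSpanError(RoreviewError):
    """An event time falls outside the covered episode span."""


class DisjointDomainsError(RoreviewError):
    """Two domain sequences share no common time window."""


class MalformedCodeError(RoreviewError):
    """An hr/mn/sc triplet is neither a valid time nor a known sentinel."""


class SchemaError(RoreviewError):
    """An input file violates its documented dialect."""


class AlignmentError(RoreviewError):
    """Manual and derived databases cannot be aligned by (episode, shkn)."""


class ParameterError(RoreviewError):
    """Simulation parameters are internally infeasible."""
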