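"""Exception hierarchy shared across the toolkit.

Every data-level failure derives from :class:`RnaTopoError` so that callers
(and the CLI, which maps them to exit code 3) can catch one base class.
"""


class RnaTopoError(Exception):
    """Base class for all rnatopo data errors."""

    exit_code = 3


class FormatError(RnaTopoError):
    """Input file could not be parsed in the expected format."""


class EmptyStructureError(RnaTopoError):
    """A structure source contained no recognisable RNA residues."""


class UnknownResidueError(RnaTopoError):
    """A residue name could not be resolved to a standard nucleotide."""


class MissingAtomError(RnaTopoError):
    """A residue lacks the atom required by the active contact definition."""


class MalformedRecordError(RnaTopoError):
    """A contact-table (or restraint-table) record is invalid."""


class EmptyMapError(RnaTopoError):
    """An operation that needs at least one contact received an empty map."""


class RequestTooLargeError(RnaTopoError):
    """More contacts were requested than the map contains."""


class DomainError(RnaTopoError):
    """A numeric argument lies outside its mathematical domain."""


class CapacityError(RnaTopoError):
    """Not enough candidate pairs exist to satisfy a sampling request."""


class InsufficientPointsError(RnaTopoError):
    """Too few points for a spatial statistic to be defined."""


class InsufficientMatchError(RnaTopoError):
    """Too few matched atoms for a superposition to be defined."""


class UndefinedMetricError(RnaTopoError):
    """A ratio metric was requested on an empty denominator."""
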