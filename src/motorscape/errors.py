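"""Exception hierarchy for motorscape.

Every error raised by the library derives from :class:`MotorscapeError`
so callers can catch library failures with a single clause while tests
can assert on the specific subclass.
"""


class MotorscapeError(Exception):
    """Base class for all motorscape errors."""


class ParseError(MotorscapeError):
    """A file could not be parsed; message carries the line number."""


class TopologyError(MotorscapeError):
    """Frames of one ensemble disagree on atom count or identity."""


class FormatError(MotorscapeError):
    """A value cannot be represented in the requested file format."""


class SelectionError(MotorscapeError):
    """A motif or anchor selection resolved to nothing (or too much)."""


class AnchorError(SelectionError):
    """An atom anchor did not resolve to exactly one atom."""


class BoostLogError(MotorscapeError):
    """Boost-potential log is malformed (ordering, duplicates, pairing)."""


class InputError(MotorscapeError):
    """Invalid argument values (lengths, counts, ranges)."""


class DegenerateGeometryError(MotorscapeError):
    """Geometry has no well-defined answer (coincident points, zero spread)."""


class RadiusError(MotorscapeError):
    """No van der Waals radius available for an element."""


class DefinitionError(MotorscapeError):
    """Operation is undefined for these inputs (e.g. overlapping groups)."""


class CorrespondenceError(MotorscapeError):
    """Atoms could not be matched between two topologies."""


class EmptyProfileError(MotorscapeError):
    """All bins fell under the minimum-count threshold."""


class SpecError(MotorscapeError):
    """A synthetic-data specification is infeasible or invalid."""


class ConfigError(MotorscapeError):
    """Analysis configuration failed validation; message lists all errors."""


class ComparisonError(MotorscapeError):
    """Two state reports share no comparable quantities."""
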