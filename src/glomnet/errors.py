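"""Exception hierarchy.

Validation errors (exit code 2 in the CLI) identify the offending record;
internal errors (exit code 1) indicate states that valid inputs cannot reach.
"""


class GlomnetError(Exception):
    """Base class for all package errors."""


class ValidationError(GlomnetError):
    """A network or table violates an input invariant."""


class DuplicateIdError(ValidationError):
    """A node or segment id occurs more than once."""


class UnknownNodeError(ValidationError):
    """A segment references a node id absent from the node table."""


class SelfLoopError(ValidationError):
    """A segment joins a node to itself."""


class TerminalCountError(ValidationError):
    """Not exactly one afferent and one efferent terminal."""


class TerminalDegreeError(ValidationError):
    """A terminal node does not have degree exactly 1."""


class DisconnectedNetworkError(ValidationError):
    """The capillary graph is not connected."""


class NonFiniteCoordinateError(ValidationError):
    """A node position component is NaN or infinite."""


class InvalidValueError(ValidationError):
    """A radius, length or config value is out of its allowed range."""


class DegenerateGeometryError(ValidationError):
    """Pole-frame construction failed (coincident or collinear landmarks)."""


class MissingRadiusError(ValidationError):
    """An operation requiring segment radii found segments without one."""


class PathExplosionError(GlomnetError):
    """Geodesic enumeration would exceed the configured cap."""


class NotNonplanarError(GlomnetError):
    """A Kuratowski witness was requested for a planar graph."""


class FlowResidualError(GlomnetError):
    """The solved flow violates Kirchhoff's current law beyond tolerance."""


class InternalError(GlomnetError):
    """A state that validated inputs should make unreachable."""
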