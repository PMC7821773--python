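"""Typed exceptions raised across the package.

Every anticipated failure mode maps to one of these classes so callers
(and the CLI) can distinguish bad input files from bad geometry from
numerical breakdown.
"""


class MorphodistError(Exception):
    """Base class for all package errors."""


class MeshIOError(MorphodistError, IOError):
    """File could not be read or written."""


class MeshFormatError(MorphodistError, ValueError):
    """File parsed but violates the format dialect (bad indices, truncation...)."""


class ValidationError(MorphodistError, ValueError):
    """An in-memory object violates its invariants."""


class LandmarkError(ValidationError):
    """Landmark file or set fails its requirements (count, coincidence...)."""


class DegenerateGeometryError(MorphodistError, ValueError):
    """Geometry too degenerate for the requested operation (e.g. collinear landmarks)."""


class NumericalError(MorphodistError, ArithmeticError):
    """A computation produced non-finite values."""


class AliasingError(MorphodistError, ValueError):
    """ANOVA factors are confounded and cannot be separated."""
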