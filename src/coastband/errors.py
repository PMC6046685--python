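"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`CoastbandError` so the
CLI can map validation problems to exit code 2 uniformly.
"""


class CoastbandError(Exception):
    """Base class for all coastband errors."""


class SchemaError(CoastbandError):
    """Input layer lacks a required attribute; message lists available fields."""


class CRSError(CoastbandError):
    """Layer is in a geographic (degree-based) CRS, or CRSs of inputs differ."""


class EmptyInputError(CoastbandError):
    """Layer contains no usable features."""


class ConfigurationError(CoastbandError):
    """Invalid or inconsistent parameters."""


class EmptyCoastlineError(CoastbandError):
    """Sea and land unions share no boundary of positive length."""


class GeometryError(CoastbandError):
    """A feature's geometry is invalid and could not be repaired."""


class FormatError(CoastbandError):
    """Unknown output format name."""


class GenerationError(CoastbandError):
    """Synthetic-fixture motifs collide or do not fit the grid."""


class InternalConsistencyError(CoastbandError):
    """Pipeline stages were combined on inconsistent inputs (a bug upstream)."""
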