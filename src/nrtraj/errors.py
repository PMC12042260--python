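"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`NrtrajError`
so callers can catch one type at pipeline boundaries.
"""


class NrtrajError(Exception):
    """Base class for all package errors."""


class ParseError(NrtrajError):
    """A file could not be parsed; the message names the offending line/row."""


class StructureError(NrtrajError):
    """Structure-level inconsistency (e.g. atom-count mismatch between models)."""


class SelectionError(NrtrajError):
    """An atom-selection query referenced an unknown field or invalid value."""


class GeometryError(NrtrajError):
    """Degenerate or under-determined geometry (short span, zero-length axis...)."""


class TopologyError(NrtrajError):
    """Role/connectivity bookkeeping problem (donor without hydrogen, tiny ring)."""


class ConsistencyError(NrtrajError):
    """Cross-object inconsistency (event refers to a frame outside a trajectory)."""


class GeneratorError(NrtrajError):
    """Synthetic-data generation could not satisfy the requested constraints."""


class AssemblyError(NrtrajError):
    """Feature-table assembly found missing descriptors; message lists the gaps."""


class DegenerateDataError(NrtrajError):
    """An analysis has no usable data left (e.g. every replica flagged)."""
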