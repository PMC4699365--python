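"""Exception hierarchy shared across the package.

Every error raised by screenminer derives from :class:`ScreenMinerError`,
so callers (CLI, HTTP service) can catch one base class and map it to an
exit status or HTTP error code.
"""

from __future__ import annotations


class ScreenMinerError(Exception):
    """Base class for all screenminer errors."""


# --- graph model ---------------------------------------------------------

class SchemaError(ScreenMinerError):
    """An object kind or property is not registered in the graph."""


class DuplicateObjectError(ScreenMinerError):
    """Strict insertion hit an existing (kind, ID-tuple) node."""


class ImportConflictError(ScreenMinerError):
    """Merging rows produced two different values for one property."""


class MissingNodeError(ScreenMinerError):
    """An edge endpoint does not exist in the graph."""


class GraphIntegrityError(ScreenMinerError):
    """A descriptive node does not resolve to exactly one grouping node."""


class LabelValueError(ScreenMinerError):
    """A label annotation value was not binary (0 or 1)."""


# --- importer ------------------------------------------------------------

class FormatError(ScreenMinerError):
    """The screen file violates the three-header-row CSV dialect."""


class ScreenImportError(ScreenMinerError):
    """A data cell could not be imported (e.g. unparseable NUMBER).

    Carries ``row`` and ``column`` as 1-based file coordinates when known.
    """

    def __init__(self, message: str, row: int | None = None,
                 column: int | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class UnknownGroupWarning(UserWarning):
    """A label row referenced a grouping ID-tuple absent from the graph."""


# --- query ---------------------------------------------------------------

class QueryError(ScreenMinerError):
    """A query referenced an unknown kind, feature or label."""


class TransformError(ScreenMinerError):
    """An axis transform is undefined for the data (log10 of x <= 0).

    ``entities`` lists the offending entity ID-tuples.
    """

    def __init__(self, message: str, entities=()):
        super().__init__(message)
        self.entities = list(entities)


# --- analytics / export / share / service / synthgen ---------------------

class AnalyticsError(ScreenMinerError):
    """Invalid input to a post-query analytics operation."""


class ExportError(ScreenMinerError):
    """Nothing to export, or the result cannot be rendered."""


class ShareTokenError(ScreenMinerError):
    """A share token is malformed, tampered or of an unknown version."""


class GenerationError(ScreenMinerError):
    """Invalid parameters for the synthetic screen generator."""
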