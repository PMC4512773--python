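"""Exception hierarchy for metaboot.

All metaboot errors derive from :class:`MetabootError` so callers can catch
the package's failures with a single ``except`` clause while still
distinguishing malformed input files from degenerate data or bad parameters.
"""


class MetabootError(Exception):
    """Base class for all metaboot errors."""


class TableFormatError(MetabootError, ValueError):
    """An abundance or metadata table violates the expected TSV layout
    (missing/duplicate ids, non-numeric cells, bad headers)."""


class ConsistencyError(MetabootError, ValueError):
    """Paired inputs disagree (e.g. a metadata sample absent from the table,
    or a selected feature unknown to the ground truth)."""


class DegenerateDataError(MetabootError, ValueError):
    """The data cannot support the requested operation (all-zero sample,
    single class label, empty stratum, too few samples)."""


class ParameterError(MetabootError, ValueError):
    """A parameter is out of its valid range (k larger than the feature
    count, M not greater than M', empty grids, ...)."""
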