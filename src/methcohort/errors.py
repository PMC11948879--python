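"""Exception hierarchy.

DataError covers malformed or inconsistent input data; UsageError covers
bad invocations. The CLI maps DataError -> exit 1 and UsageError -> exit 2.
"""


class MethcohortError(Exception):
    """Base class for all package errors."""


class DataError(MethcohortError):
    """Malformed or inconsistent data (exit status 1 at the CLI)."""


class UsageError(MethcohortError):
    """Invalid invocation or arguments (exit status 2 at the CLI)."""


class RegionFormatError(UsageError):
    """A region string could not be parsed."""


class TableParseError(DataError):
    """A frequency table file violates the on-disk dialect."""


class TableConflictError(DataError):
    """Two table parts disagree on a non-missing cell."""


class MissingIndexError(DataError):
    """A region query was attempted on a table without a tabix index."""


class MalformedTagError(DataError):
    """An MM/ML modified-base tag pair is internally inconsistent."""


class NoModificationTagsError(DataError):
    """An alignment file contains no MM/ML tags at all."""


class SchemaError(DataError):
    """A tabular input lacks a required column."""


class MalformedGroupError(DataError):
    """A nanopolish call group's sequence does not contain its motifs."""


class NothingToClusterError(DataError):
    """Every column was removed before clustering could run."""


class ConsistencyError(DataError):
    """Figure inputs (table vs clustering result) do not agree."""
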