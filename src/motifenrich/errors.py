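"""Exception hierarchy for motifenrich.

All library errors derive from :class:`MotifEnrichError` so callers (and the
CLI) can catch one base class and map it to an exit code.
"""


class MotifEnrichError(Exception):
    """Base class for all motifenrich errors."""


class InputError(MotifEnrichError):
    """Invalid user-supplied data or parameters."""


class FormatError(MotifEnrichError):
    """Malformed file content.

    Carries an optional 1-based ``line`` number pointing at the offending
    line of the input file.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UndefinedAffinityError(MotifEnrichError):
    """A sequence has no scoreable window for the motif (too short or all-N)."""


class EmptyDatasetError(MotifEnrichError):
    """All records were dropped while mapping a dataset."""


class EmptyPositiveSetError(MotifEnrichError):
    """The signal threshold produced an empty positive set.

    Datasets raising this are skipped by the evaluation harness rather than
    treated as failures.
    """


class PartitionError(MotifEnrichError):
    """A partition put all points on one side where both sides are required."""


class DegenerateDataError(MotifEnrichError):
    """Association is undefined (constant variable, exact collinearity, ...)."""
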