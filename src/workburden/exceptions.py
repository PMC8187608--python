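"""Exception hierarchy.

All data-quality problems raise a subclass of :class:`WorkburdenError`, so
callers (and the CLI) can distinguish dirty input data (exit code 1) from
programming errors.
"""


class WorkburdenError(Exception):
    """Base class for all package errors."""


class ICDParseError(WorkburdenError):
    """A diagnosis string could not be parsed as an ICD-10 code."""


class UnmappableCodeError(WorkburdenError):
    """A valid ICD-10 code falls outside every configured disease group."""


class DataIntegrityError(WorkburdenError):
    """Input records contradict each other (e.g. overlapping spells with
    conflicting diagnoses, or both death and retirement for one person)."""


class ReferentialIntegrityError(DataIntegrityError):
    """An event references an employee that is not on the roster."""


class SchemaError(WorkburdenError):
    """An input file is missing required columns or has unparseable rows."""
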