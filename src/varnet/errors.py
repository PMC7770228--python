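"""Exception hierarchy shared across the pipeline.

Schema errors indicate malformed on-disk inputs (CLI exit code 2); stage
errors indicate a pipeline stage that could not run (exit code 3).
"""


class VarnetError(Exception):
    """Base class for all package errors."""


class SchemaError(VarnetError):
    """An input file violates its declared schema."""

    exit_code = 2


class StageError(VarnetError):
    """A pipeline stage failed on otherwise well-formed input."""

    exit_code = 3
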