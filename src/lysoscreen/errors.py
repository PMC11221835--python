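"""Exception hierarchy shared across the pipeline.

Validation errors signal bad parameters or inconsistent annotations;
format errors signal malformed input files; data errors signal inputs
that parse but violate a contract (e.g. a plate without control wells).
"""


class LysoscreenError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(LysoscreenError, ValueError):
    """A parameter or annotation violates its contract."""


class FormatError(LysoscreenError, ValueError):
    """An input file is structurally malformed."""


class DataError(LysoscreenError, ValueError):
    """Parsed input violates a run-level requirement."""
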