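"""Package exceptions, mapped onto CLI exit codes."""


class ScreenSevenError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ValidationError(ScreenSevenError):
    """Invalid input data or configuration (CLI exit code 2)."""

    exit_code = 2


class StatisticalError(ScreenSevenError):
    """A statistical procedure failed: singularity, separation,
    non-convergence, degenerate table (CLI exit code 3)."""

    exit_code = 3
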