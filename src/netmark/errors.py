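"""Exception hierarchy mapped to the CLI's exit codes."""


class NetmarkError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(NetmarkError):
    """Invalid parameter or configuration value (exit code 2)."""

    exit_code = 2


class FormatError(NetmarkError):
    """Malformed input file (exit code 3)."""

    exit_code = 3


class DegenerateInputError(NetmarkError):
    """Input that makes a statistic undefined, e.g. zero variance (exit code 4)."""

    exit_code = 4
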