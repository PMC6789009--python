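"""Exception hierarchy shared across the package."""


class StrainRecovError(Exception):
    """Base class for all errors raised by strainrecov."""


class ConfigError(StrainRecovError, ValueError):
    """Invalid configuration, parameter value, or lookup (e.g. missing cut-off)."""


class FormatError(StrainRecovError, ValueError):
    """Malformed input file.

    Carries the offending path and, where known, the 1-based line number.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
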