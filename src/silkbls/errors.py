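"""Exception hierarchy.

``SilkBLSError`` is the common base; the CLI maps it to exit code 1
(validation) and any other exception to exit code 2 (runtime).
"""


class SilkBLSError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SilkBLSError):
    """Invalid scattering or analysis configuration."""


class PhysicalDomainError(SilkBLSError):
    """Physically impossible parameter combination (e.g. n² < cos²(θ/2))."""


class ValidationError(SilkBLSError):
    """Invariant violation on a domain object (tensor not positive definite, ...)."""


class ParseError(SilkBLSError):
    """Malformed input file; carries file name and line number where known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class IdentifiabilityError(SilkBLSError):
    """The experimental design cannot constrain one or more elastic constants."""


class FitConvergenceError(SilkBLSError):
    """Optimizer failed to converge; ``last_iterate`` holds the best parameters seen."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
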