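"""Exception hierarchy shared across the package."""


class LatentLeafError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LatentLeafError):
    """A landmark table (or sidecar) could not be parsed.

    The message names the offending file, and where possible the line or
    record at fault.
    """


class ValidationError(LatentLeafError):
    """A dataset or record violates an invariant.

    The message names the leaf (or vine) and the rule that failed.
    """


class DegenerateConfigurationError(LatentLeafError):
    """All landmarks of a configuration coincide (centroid size 0)."""


class ConvergenceError(LatentLeafError):
    """Iterative superimposition failed to converge."""

    def __init__(self, message: str, final_delta: float):
        super().__init__(message)
        self.final_delta = final_delta
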