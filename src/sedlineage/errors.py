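"""Exception types shared across the package."""


class SedlineageError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(SedlineageError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(SedlineageError, ValueError):
    """A file or string does not conform to the expected format."""


class SimulationError(SedlineageError, RuntimeError):
    """A simulation could not satisfy its constraints (e.g. bounded retries)."""


class DegenerateInputError(SedlineageError, ValueError):
    """Input is structurally valid but degenerate for the requested analysis."""
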