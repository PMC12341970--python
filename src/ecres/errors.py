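"""Package-wide exception types."""


class EcresError(Exception):
    """Base class for all package errors."""


class ValidationError(EcresError, ValueError):
    """A parameter set violates a stated invariant; the message names it."""


class TraceFormatError(EcresError, ValueError):
    """A trace file or in-memory trace is malformed."""


class IntegrationError(EcresError, RuntimeError):
    """Numerical integration diverged; the message names the first bad time."""


class FitError(EcresError, ValueError):
    """A curve fit cannot be performed on the given data."""
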