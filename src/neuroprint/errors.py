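"""Exception hierarchy for neuroprint."""


class NeuroprintError(Exception):
    """Base class for all neuroprint errors."""


class ParseError(NeuroprintError):
    """Raised when a morphology file cannot be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class RepairError(NeuroprintError):
    """Raised when a morphology defect cannot be repaired."""


class PolicyError(NeuroprintError):
    """Raised when a diameter policy produces an invalid morphology."""


class MeshingError(NeuroprintError):
    """Raised when surface tessellation cannot proceed."""


class MeshIOError(NeuroprintError):
    """Raised on malformed or truncated mesh files."""


class StatsError(NeuroprintError):
    """Raised when a requested mesh/morphology statistic is undefined."""
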