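"""Exception hierarchy used across haemokit."""


class HaemokitError(Exception):
    """Base class for all haemokit errors."""


class InfeasibleSpecError(HaemokitError, ValueError):
    """Raised when waveform/target constraints cannot be satisfied jointly."""


class SolverError(HaemokitError, RuntimeError):
    """Raised when a time integration produces non-finite state."""


class FormatError(HaemokitError, ValueError):
    """Raised on malformed input files (CSV waveform, JSON manifest/network)."""
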