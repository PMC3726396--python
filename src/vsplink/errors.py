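"""Exception hierarchy for vsplink."""


class VspLinkError(Exception):
    """Base class for all vsplink errors."""


class ParseError(VspLinkError):
    """Malformed input file (PDB, TSV, config)."""


class CongruenceError(VspLinkError):
    """Trajectory models/frames do not match the topology."""


class SelectionError(VspLinkError):
    """An atom selection is invalid or resolves to an unusable set."""


class SpecError(VspLinkError):
    """A synthetic-data specification violates its invariants."""


class FitError(VspLinkError):
    """A nonlinear fit failed to converge or was given invalid options."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AnalysisError(VspLinkError):
    """An analysis precondition is violated (empty window, bad interval, ...)."""
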