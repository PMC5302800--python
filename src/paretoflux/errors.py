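"""Exception hierarchy.

Validation failures (bad models, bad files) and solver failures (infeasible,
unbounded, non-convergence) are kept distinct so callers -- in particular the
CLI -- can map them to different exit codes.
"""


class ParetofluxError(Exception):
    """Base class for all package errors."""


class ValidationError(ParetofluxError):
    """A model, table or configuration violates an invariant."""


class ParseError(ParetofluxError):
    """A file could not be parsed; the message names the offending element."""


class SolverError(ParetofluxError):
    """An optimization failed. Carries the solver status when available."""

    def __init__(self, message: str, status: str | None = None):
        super().__init__(message)
        self.status = status


class InfeasibleError(SolverError):
    def __init__(self, message: str):
        super().__init__(message, status="infeasible")


class UnboundedObjectiveError(SolverError):
    def __init__(self, message: str):
        super().__init__(message, status="unbounded")
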