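"""Exception hierarchy.

Errors are split into input/format problems (bad files, bad specs),
model-integrity problems (a network violating its own invariants) and
solver-side failures, so callers — in particular the CLI — can map them
to distinct exit codes.
"""


class DopafbaError(Exception):
    """Base class for all package errors."""


class ModelIntegrityError(DopafbaError):
    """A network violates a structural invariant (dangling ids, bad bounds...)."""


class PolicyError(DopafbaError):
    """The bounds policy cannot be applied (e.g. missing reference flux)."""


class GroupingError(DopafbaError):
    """A group tag table references an unknown reaction."""


class FormatError(DopafbaError):
    """A TSV/JSON document is malformed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SBMLParseError(DopafbaError):
    """An SBML stream could not be parsed into a model."""


class SpecError(DopafbaError):
    """An experiment or scan specification is invalid for the given model."""


class SizeError(DopafbaError):
    """An exhaustive oracle was asked to run beyond its hard size cap."""


class AnalysisError(DopafbaError):
    """An analysis precondition failed (e.g. infeasible basic model)."""


class SolverError(DopafbaError):
    """The LP backend failed for a reason other than infeasible/unbounded."""
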