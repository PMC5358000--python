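"""Exception types raised by the simulator."""


class OsmosimError(Exception):
    """Base class for all osmosim errors."""


class DegenerateStateError(OsmosimError):
    """A state variable has left its physical domain (e.g. zero plasma volume)."""

    def __init__(self, field: str, value: float, message: str | None = None):
        self.field = field
        self.value = value
        super().__init__(message or f"degenerate state: {field} = {value!r}")


class ScheduleError(OsmosimError):
    """A protocol's event schedule is inconsistent (overlaps, bad ordering)."""


class ConvergenceError(OsmosimError):
    """An iterative solver (TGF closure, baseline search) failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class IntegrationError(OsmosimError):
    """A state invariant was violated during time integration."""

    def __init__(self, t: float, field: str, value: float):
        self.t = t
        self.field = field
        self.value = value
        super().__init__(f"integration failure at t = {t:.4f} min: {field} = {value!r}")


class InternalConsistencyError(OsmosimError):
    """A tubule stage produced a negative outflow; indicates a bad parameter set."""


class AuditError(OsmosimError):
    """A conservation audit could not be performed (missing flux records)."""


class ValidationInputError(OsmosimError):
    """Reference data are malformed or cannot be matched against the runs."""
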