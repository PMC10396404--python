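"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`MDagPlanError`,
so callers can catch one type at workflow boundaries.
"""


class MDagPlanError(Exception):
    """Base class for all errors raised by mdagplan."""


class GraphFormatError(MDagPlanError):
    """A graph document is malformed (bad JSON, missing field, bad value)."""


class CyclicGraphError(MDagPlanError):
    """The supplied edge set contains a directed cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        path = " -> ".join(self.cycle + [self.cycle[0]])
        super().__init__(f"graph is cyclic: {path}")


class UnknownNodeError(MDagPlanError):
    """A query referenced a node name not present in the graph."""


class RoleError(MDagPlanError):
    """A role assignment is incomplete or inconsistent with node kinds."""


class EstimandError(MDagPlanError):
    """An estimand is malformed or of an unsupported target type."""


class UnsupportedCriterionError(MDagPlanError):
    """The requested graphical criterion does not apply to this estimand."""


class ModelGraphMismatchError(MDagPlanError):
    """A generative model references parents absent from the m-DAG (or misses some)."""


class CalibrationError(MDagPlanError):
    """Intercept calibration failed to reach the target marginal proportion."""


class EstimationError(MDagPlanError):
    """Base class for estimator failures (counted, not fatal, in Monte Carlo runs)."""


class InsufficientDataError(EstimationError):
    """Too few complete records to fit the analysis model."""


class ImputationModelError(EstimationError):
    """An imputation model could not be fitted (singular design, separation)."""


class DeltaUnsupportedError(MDagPlanError):
    """A delta offset was requested for a variable family that has no defined scale
    for it (binary variables: a shift could mean log-odds or probability; we refuse
    to guess)."""


class HarnessError(MDagPlanError):
    """The Monte Carlo harness could not produce a report (e.g. every replicate failed)."""


class PlanError(MDagPlanError):
    """An analysis plan violates its own consistency invariants."""


class WorkflowError(MDagPlanError):
    """A workflow stage failed; the message names the stage."""
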