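"""Exception hierarchy shared across the package."""


class OptStratError(Exception):
    """Base class for all package errors."""


class ParameterError(OptStratError, ValueError):
    """Invalid distribution or model parameters."""


class DomainError(OptStratError, ValueError):
    """Boundary or width outside the admissible domain."""


class DegenerateStratumError(OptStratError, ValueError):
    """A stratum carries (numerically) zero probability mass."""


class DegenerateDataError(OptStratError, ValueError):
    """Input data without enough spread to fit or bin."""


class FitError(OptStratError, RuntimeError):
    """Maximum-likelihood fit failed to converge."""


class FeasibilityError(OptStratError, ValueError):
    """The stratification problem admits no feasible solution."""


class ComplexityError(OptStratError, ValueError):
    """Requested computation exceeds a documented complexity guard."""


class AllocationError(OptStratError, ValueError):
    """Sample allocation is infeasible under the stated bounds."""


class ConfigError(OptStratError, ValueError):
    """Invalid run configuration."""
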