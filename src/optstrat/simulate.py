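"""Synthetic survey populations with the structure the method assumes.

Populations are generated with right-skewed parametric auxiliaries
(3-parameter Weibull or Gamma), a polynomial link from the auxiliaries
to the study variable, and additive homoscedastic normal noise — the
same statistical structure under which the stratification objective is
derived.  Bootstrap resampling of whole rows supports consistency
checks of downstream results.

``paperlike_population`` packages the module's reference study
condition: N = 5000 units, two Weibull auxiliaries with shape near 2,
and a link so weak that the regression explains essentially none of
the variance (adjusted R^2 well below 1%) — an emulation of the
near-uncorrelated simulated regime, not a reproduction of any specific
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, draw, weibull3p
from .exceptions import DegenerateDataError, ParameterError
from .regression import RegressionModel, Term

__all__ = [
    "PopulationSpec",
    "generate_population",
    "bootstrap_resample",
    "paperlike_population",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one synthetic population (reproducible given the seed)."""

    N: int
    auxiliaries: tuple[DistributionSpec, ...]
    link: RegressionModel
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError("population size N must be at least 2")
        if not self.auxiliaries:
            raise ParameterError("at least one auxiliary distribution is required")
        object.__setattr__(self, "auxiliaries", tuple(self.auxiliaries))
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")
        if max(self.link.variables) > len(self.auxiliaries):
            raise ParameterError(
                f"link references x{max(self.link.variables)} but only "
                f"{len(self.auxiliaries)} auxiliaries are specified"
            )


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw the table: columns x1..xp from their distributions, y = lambda + eps."""
    rng = np.random.default_rng(spec.seed)
    cols = {
        f"x{i}": draw(dist, spec.N, rng)
        for i, dist in enumerate(spec.auxiliaries, start=1)
    }
    table = pd.DataFrame(cols)
    eps = spec.noise_sd * rng.standard_normal(spec.N)
    table["y"] = spec.link.predict(table) + eps
    return table


def bootstrap_resample(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Row-level resample with replacement, same size, rows kept intact."""
    if len(table) == 0:
        raise DegenerateDataError("cannot resample an empty table")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(table), size=len(table))
    return table.iloc[idx].reset_index(drop=True)


def paperlike_population(seed: int = 20180405) -> PopulationSpec:
    """Reference skewed study condition: N = 5000, two Weibull auxiliaries
    (shape ~ 2), a weak linear link drowned in unit-scale noise."""
    link = RegressionModel(
        intercept=12.0,
        terms=(Term(var=1, power=1, coef=0.02), Term(var=2, power=1, coef=0.01)),
        error_scale=1.0,
    )
    return PopulationSpec(
        N=5000,
        auxiliaries=(
            weibull3p(shape=2.0, scale=3.0, location=2.0),
            weibull3p(shape=1.8, scale=5.0, location=1.0),
        ),
        link=link,
        noise_sd=1.8,
        seed=seed,
    )
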