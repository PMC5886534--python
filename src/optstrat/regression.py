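"""Study-variable regression model y = lambda(x_1..x_p) + eps.

The survey's study variable is assumed to follow a polynomial (degree
<= 2) regression on the auxiliary variables with additive homoscedastic
normal error.  This module fits that model by ordinary least squares,
reports the comparison metrics tabulated in survey-design studies
(multiple correlation, residual standard error, adjusted R^2, AIC), and
propagates the model through a stratum: the within-stratum variance of
lambda is assembled from the auxiliaries' conditional moments, treating
auxiliaries as independent across strata (cross-variable covariances
are taken as zero).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ParameterError

__all__ = ["Term", "FitMetrics", "RegressionModel", "parse_term", "fit", "lambda_stratum_variance"]

_TERM_RE = re.compile(r"^x(\d+)(?:\^([12]))?$")


@dataclass(frozen=True)
class Term:
    """One regression term beta * x_var^power (power in {1, 2})."""

    var: int
    power: int
    coef: float

    def __post_init__(self) -> None:
        if self.power not in (1, 2):
            raise ParameterError(f"term power must be 1 or 2, got {self.power}")
        if self.var < 1:
            raise ParameterError("variable indices are 1-based")


def parse_term(spec: str) -> tuple[int, int]:
    """Parse a term string like ``"x1"`` or ``"x2^2"`` into (var, power)."""
    m = _TERM_RE.match(spec.strip())
    if not m:
        raise ParameterError(f"cannot parse term {spec!r}; expected e.g. 'x1' or 'x1^2'")
    return int(m.group(1)), int(m.group(2) or 1)


@dataclass(frozen=True)
class FitMetrics:
    correlation: float  # multiple correlation sqrt(R^2)
    rse: float          # residual standard error sqrt(SSE/(n - p - 1))
    adj_r2: float
    aic: float          # R/lm convention: n log(2 pi) + n log(SSE/n) + n + 2(p + 2)


@dataclass(frozen=True)
class RegressionModel:
    intercept: float
    terms: tuple[Term, ...]
    error_scale: float = 1.0
    metrics: FitMetrics | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ParameterError("model needs at least one term")
        keys = [(t.var, t.power) for t in self.terms]
        if len(set(keys)) != len(keys):
            raise ParameterError(f"duplicate (variable, power) terms: {keys}")
        if not self.error_scale > 0:
            raise ParameterError("error_scale must be positive")
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def variables(self) -> tuple[int, ...]:
        return tuple(sorted({t.var for t in self.terms}))

    def coefficients(self, var: int) -> dict[int, float]:
        """Power -> coefficient map for one variable."""
        return {t.power: t.coef for t in self.terms if t.var == var}

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.intercept, dtype=float)
        for t in self.terms:
            out += t.coef * np.asarray(table[f"x{t.var}"], dtype=float) ** t.power
        return out


def _design_matrix(table: pd.DataFrame, term_keys: Sequence[tuple[int, int]]) -> np.ndarray:
    cols = []
    for var, power in term_keys:
        col = f"x{var}"
        if col not in table.columns:
            raise ParameterError(f"column {col!r} missing from the population table")
        cols.append(np.asarray(table[col], dtype=float) ** power)
    return np.column_stack(cols)


def fit(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str | tuple[int, int]],
    error_mode: str = "rse",
) -> RegressionModel:
    """OLS fit of y on the requested polynomial terms.

    ``terms`` may be strings ("x1", "x2^2") or (var, power) pairs.
    ``error_mode='rse'`` sets the model's error_scale to the residual
    standard error; ``'unit'`` fixes it at 1 (the convention in which the
    error term enters the stratification objective as a standard
    normal).
    """
    if response not in table.columns:
        raise ParameterError(f"response column {response!r} not in table")
    term_keys = [parse_term(t) if isinstance(t, str) else (int(t[0]), int(t[1])) for t in terms]
    if len(set(term_keys)) != len(term_keys):
        raise ParameterError(f"duplicate terms requested: {term_keys}")
    y = np.asarray(table[response], dtype=float)
    n = y.size
    p = len(term_keys)
    if n <= p + 1:
        raise ParameterError(f"need more than {p + 1} observations to fit {p} terms")
    X = _design_matrix(table, term_keys)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ParameterError(f"collinear design for terms {term_keys}")
    res = sm.OLS(y, Xc).fit()
    sse = float(res.ssr)
    rse = float(np.sqrt(sse / (n - p - 1)))
    r2 = float(res.rsquared)
    # R's AIC for lm: gaussian log-likelihood with sigma^2 = SSE/n, counting
    # sigma as a parameter -> n log(2 pi) + n log(SSE/n) + n + 2 (p + 2)
    with np.errstate(divide="ignore"):
        aic = float(n * np.log(2 * np.pi) + n * np.log(sse / n) + n + 2 * (p + 2))
    metrics = FitMetrics(
        correlation=float(np.sqrt(max(r2, 0.0))),
        rse=rse,
        adj_r2=float(res.rsquared_adj),
        aic=aic,
    )
    if error_mode not in ("rse", "unit"):
        raise ParameterError(f"error_mode must be 'rse' or 'unit', got {error_mode!r}")
    scale = rse if error_mode == "rse" else 1.0
    if not scale > 0:
        scale = 1.0  # perfect fit: degenerate error term, keep model valid
    built = [Term(v, pw, float(c)) for (v, pw), c in zip(term_keys, res.params[1:])]
    return RegressionModel(
        intercept=float(res.params[0]), terms=tuple(built),
        error_scale=scale, metrics=metrics,
    )


def lambda_stratum_variance(
    model: RegressionModel,
    moments: Mapping[int, Mapping[int, float]],
) -> float:
    """Within-stratum variance of lambda(x_1..x_p) from conditional moments.

    ``moments[var][k]`` is the conditional raw moment E[X_var^k | stratum].
    A variable entering linearly needs orders 1-2; with a quadratic term,
    orders up to 4.  Var(sum_i g_i(X_i)) = sum_i Var g_i(X_i) because
    cross-variable covariances are assumed zero.
    """
    total = 0.0
    for var in model.variables:
        coeffs = model.coefficients(var)
        max_order = 2 * max(coeffs)
        try:
            m = {k: float(moments[var][k]) for k in range(1, max_order + 1)}
        except KeyError as exc:
            raise ParameterError(
                f"variable x{var} requires conditional moments up to order "
                f"{max_order}; missing order {exc.args[0]!r}"
            ) from exc
        # Var(g(X)) = E[g^2] - E[g]^2 for g(x) = sum_p c_p x^p (intercept-free)
        eg = sum(c * m[p] for p, c in coeffs.items())
        eg2 = sum(
            cp * cq * m[p + q] for p, cp in coeffs.items() for q, cq in coeffs.items()
        )
        total += max(eg2 - eg * eg, 0.0)
    return total
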