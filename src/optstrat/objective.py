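"""Per-stratum objective phi_h for the stratum-width programming problem.

Minimizing the variance of the stratified mean under Neyman allocation
is equivalent to minimizing sum_h W_h sigma_hy over the boundaries.
With y = lambda(x_1..x_p) + eps, each stratum term decomposes as

    phi_h = sqrt( sum_i (W^2 sigma^2)_{h,x_i-poly} + s_eps^2 (W^2 sigma^2)_{h,eps} ),

where every factor is a function of the two cut points (y_{h-1}, y_h)
on a common (max-scaled) boundary domain.  Each weight-scaled variance
is evaluated through the product form W * (W E[g^2]) - (W E[g])^2 built
from upper partial moments, so no division by a tiny stratum weight
ever occurs; strata with negligible mass contribute phi = 0.

A component may carry a full polynomial (degree <= 2) in its auxiliary
variable, which covers both the linear and the quadratic regression
links.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import distributions as dist_mod
from .distributions import DistributionSpec, StratumMoments, std_normal_error
from .exceptions import DomainError, FeasibilityError, ParameterError

__all__ = [
    "Component",
    "StratificationProblem",
    "StratificationResult",
    "ObjectiveEvaluator",
    "GridObjective",
    "stratum_objective",
    "total_objective",
    "stratum_moment_table",
]

_MASSLESS = 1e-12


@dataclass(frozen=True)
class Component:
    """One auxiliary variable: its distribution and regression terms.

    ``terms`` maps power -> coefficient of the polynomial through which
    the variable enters lambda; a plain linear link is ``{1: beta}``.
    """

    dist: DistributionSpec
    terms: dict[int, float]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ParameterError("component needs at least one polynomial term")
        for p in self.terms:
            if p not in (1, 2):
                raise ParameterError(f"component powers must be 1 or 2, got {p}")

    @classmethod
    def linear(cls, dist: DistributionSpec, beta: float) -> "Component":
        return cls(dist=dist, terms={1: float(beta)})

    @property
    def max_order(self) -> int:
        return 2 * max(self.terms)


@dataclass(frozen=True)
class StratificationProblem:
    """The separable width-programming problem on [y0, y0 + d].

    ``error_scale`` multiplies the truncated-standard-normal error
    contribution (None disables the error term entirely); ``grid_step``
    is the dynamic-programming discretization delta; ``min_width``
    defaults to one grid step so that every stratum can receive at
    least one sample unit.
    """

    y0: float
    d: float
    components: tuple[Component, ...]
    error_scale: float | None = 1.0
    L: int = 2
    grid_step: float | None = None
    min_width: float | None = None

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ParameterError("domain length d must be positive")
        if not self.components:
            raise ParameterError("at least one auxiliary component is required")
        object.__setattr__(self, "components", tuple(self.components))
        if self.L < 1:
            raise ParameterError("L must be >= 1")
        if self.error_scale is not None and not self.error_scale >= 0:
            raise ParameterError("error_scale must be nonnegative")
        step = self.grid_step if self.grid_step is not None else self.d / 1000.0
        if not step > 0:
            raise ParameterError("grid_step must be positive")
        # snap so that d / delta is an integer
        n_steps = max(int(round(self.d / step)), 1)
        object.__setattr__(self, "grid_step", self.d / n_steps)
        mw = self.min_width if self.min_width is not None else self.grid_step
        if mw < 0:
            raise ParameterError("min_width must be nonnegative")
        if self.L * mw > self.d * (1 + 1e-12):
            raise FeasibilityError(
                f"L * min_width = {self.L * mw} exceeds the domain length {self.d}"
            )
        object.__setattr__(self, "min_width", mw)

    @property
    def n_steps(self) -> int:
        return int(round(self.d / self.grid_step))

    def with_L(self, L: int) -> "StratificationProblem":
        return replace(self, L=L)

    @classmethod
    def linear(
        cls,
        y0: float,
        d: float,
        dists: Sequence[DistributionSpec],
        betas: Sequence[float],
        **kwargs,
    ) -> "StratificationProblem":
        """Convenience constructor for a linear link."""
        if len(dists) != len(betas):
            raise ParameterError("one coefficient per distribution is required")
        comps = tuple(Component.linear(ds, b) for ds, b in zip(dists, betas))
        return cls(y0=y0, d=d, components=comps, **kwargs)


@dataclass(frozen=True)
class StratificationResult:
    """Boundaries, widths and the per-stratum objective of one solution."""

    boundaries: tuple[float, ...]      # interior cut points y_1..y_{L-1}
    widths: tuple[float, ...]          # l_1..l_L
    stratum_objectives: tuple[float, ...]
    total_objective: float
    stratum_moments: tuple[dict[int, StratumMoments], ...] = field(default=(), compare=False)
    sample_sizes: tuple[int, ...] | None = None
    stratum_counts: tuple[int, ...] | None = None
    warnings: tuple[str, ...] = ()

    @property
    def L(self) -> int:
        return len(self.widths)


class ObjectiveEvaluator:
    """Vectorized evaluation of phi over boundary-point pairs.

    Each weight-scaled variance is a combination of upper partial
    moments U_k at the two cut points; the evaluator computes U_k in
    bulk for arrays of cut points, which is what makes the DP's
    O((d/delta)^2) pair evaluations affordable.
    """

    def __init__(self, problem: StratificationProblem):
        self.problem = problem
        self._err = std_normal_error() if problem.error_scale is not None else None

    def _upms(self, dist: DistributionSpec, orders: Sequence[int], y: np.ndarray):
        return {k: np.asarray(dist_mod.upper_partial_moment(dist, k, y)) for k in orders}

    def scaled_var_sum(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """sum of W^2 sigma^2 contributions (phi^2) for cut-point pairs."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        out = np.zeros(np.broadcast(lo, hi).shape, dtype=float)
        for comp in self.problem.components:
            orders = range(comp.max_order + 1)
            ua = self._upms(comp.dist, orders, lo)
            ub = self._upms(comp.dist, orders, hi)
            diff = {k: ua[k] - ub[k] for k in orders}
            w = diff[0]
            s1 = sum(c * diff[p] for p, c in comp.terms.items())
            s2 = sum(
                cp * cq * diff[p + q]
                for p, cp in comp.terms.items()
                for q, cq in comp.terms.items()
            )
            out += np.maximum(w * s2 - s1 * s1, 0.0)
        if self._err is not None and self.problem.error_scale > 0:
            ua = self._upms(self._err, (0, 1, 2), lo)
            ub = self._upms(self._err, (0, 1, 2), hi)
            w = ua[0] - ub[0]
            s1 = ua[1] - ub[1]
            s2 = ua[2] - ub[2]
            out += self.problem.error_scale**2 * np.maximum(w * s2 - s1 * s1, 0.0)
        return out

    def phi_pairs(self, lo, hi) -> np.ndarray:
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        out = np.sqrt(self.scaled_var_sum(lo, hi))
        return np.where(hi > lo, out, 0.0)

    def phi(self, lower: float, width: float) -> float:
        if width == 0:
            return 0.0
        return float(self.phi_pairs(np.asarray(lower), np.asarray(lower + width)))


class GridObjective:
    """phi evaluated between *indexed* grid points via precomputed tables.

    The upper partial moments U_k are tabulated once at every grid
    point; phi between grid indices (i, j) then reduces to table
    differences, which keeps the DP's O((d/delta)^2) pair sweep in
    plain vectorized arithmetic.
    """

    def __init__(self, problem: StratificationProblem, grid: np.ndarray):
        self.problem = problem
        self.grid = np.asarray(grid, dtype=float)
        self._tables: list[tuple[dict[int, float], dict[int, np.ndarray]]] = []
        for comp in problem.components:
            T = {
                k: np.asarray(dist_mod.upper_partial_moment(comp.dist, k, self.grid))
                for k in range(comp.max_order + 1)
            }
            self._tables.append((comp.terms, T))
        self._err_tables = None
        if problem.error_scale is not None and problem.error_scale > 0:
            err = std_normal_error()
            self._err_tables = {
                k: np.asarray(dist_mod.upper_partial_moment(err, k, self.grid))
                for k in (0, 1, 2)
            }

    def phi_idx(self, i, j) -> np.ndarray:
        """phi for strata spanning grid indices i..j (0 where j <= i)."""
        i = np.asarray(i, dtype=np.intp)
        j = np.asarray(j, dtype=np.intp)
        out = np.zeros(np.broadcast(i, j).shape, dtype=float)
        for terms, T in self._tables:
            diff = {k: T[k][i] - T[k][j] for k in T}
            w = diff[0]
            s1 = sum(c * diff[p] for p, c in terms.items())
            s2 = sum(
                cp * cq * diff[p + q]
                for p, cp in terms.items()
                for q, cq in terms.items()
            )
            out += np.maximum(w * s2 - s1 * s1, 0.0)
        if self._err_tables is not None:
            T = self._err_tables
            w = T[0][i] - T[0][j]
            s1 = T[1][i] - T[1][j]
            s2 = T[2][i] - T[2][j]
            out += self.problem.error_scale**2 * np.maximum(w * s2 - s1 * s1, 0.0)
        out = np.sqrt(out)
        return np.where(j > i, out, 0.0)


def _check_domain(problem: StratificationProblem, lower: float, width: float) -> None:
    tol = 1e-9 * max(1.0, abs(problem.d))
    if width < 0:
        raise DomainError(f"width must be nonnegative, got {width}")
    if lower < problem.y0 - tol or lower + width > problem.y0 + problem.d + tol:
        raise DomainError(
            f"stratum [{lower}, {lower + width}] outside the boundary domain "
            f"[{problem.y0}, {problem.y0 + problem.d}]"
        )


def stratum_objective(problem: StratificationProblem, lower: float, width: float) -> float:
    """phi_h for a single candidate stratum [lower, lower + width]."""
    _check_domain(problem, lower, width)
    return ObjectiveEvaluator(problem).phi(lower, width)


def total_objective(
    problem: StratificationProblem, boundaries: Sequence[float]
) -> tuple[float, tuple[float, ...]]:
    """sum_h phi_h over the strata induced by interior ``boundaries``.

    Returns the total and the per-stratum breakdown.
    """
    bs = [float(b) for b in boundaries]
    if any(b2 < b1 for b1, b2 in zip(bs, bs[1:])):
        raise DomainError(f"boundaries must be nondecreasing, got {bs}")
    cuts = [problem.y0, *bs, problem.y0 + problem.d]
    if bs and (bs[0] < problem.y0 - 1e-12 or bs[-1] > problem.y0 + problem.d + 1e-12):
        raise DomainError(f"boundaries {bs} outside [{problem.y0}, {problem.y0 + problem.d}]")
    ev = ObjectiveEvaluator(problem)
    lo = np.asarray(cuts[:-1])
    hi = np.asarray(cuts[1:])
    phis = ev.phi_pairs(lo, hi)
    return float(np.sum(phis)), tuple(float(p) for p in phis)


def stratum_moment_table(
    problem: StratificationProblem, boundaries: Sequence[float]
) -> tuple[dict[int, StratumMoments], ...]:
    """Per-stratum, per-variable (1-based index) weight/mean/variance.

    Massless strata report weight 0 with mean/variance NaN.
    """
    cuts = [problem.y0, *[float(b) for b in boundaries], problem.y0 + problem.d]
    rows = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        row: dict[int, StratumMoments] = {}
        for i, comp in enumerate(problem.components, start=1):
            w = dist_mod.stratum_weight(comp.dist, a, b - a)
            if w <= _MASSLESS:
                row[i] = StratumMoments(weight=w, mean=float("nan"), variance=float("nan"))
            else:
                row[i] = dist_mod.stratum_moments(comp.dist, a, b - a)
        rows.append(row)
    return tuple(rows)
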