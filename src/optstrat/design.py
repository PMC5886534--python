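"""Strata-count profiling, baseline stratifiers and efficiency comparison.

How many strata are worth building?  For an (approximately) uniform
variable the variance of the stratified mean falls like 1/L^2, so the
profile V(L) = (sum_h W_h sigma_h)^2 / n flattens quickly; this module
tabulates it by re-solving the width program for each L, suggests an
"elbow" with two documented (purely advisory) heuristics, and provides
the two classical data-driven baselines the method is compared against:
the cumulative square-root-frequency rule (Dalenius-Hodges) and the
geometric-progression rule (Gunning-Horgan).  Baseline boundaries are
scored with the same parametric objective as the optimum, so the
efficiency percentages are apples-to-apples.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DegenerateDataError, DomainError, ParameterError
from .objective import StratificationProblem, total_objective
from .solver import solve, refine

__all__ = [
    "StrataCountProfile",
    "strata_count_profile",
    "suggest_elbow",
    "cum_sqrt_f_boundaries",
    "geometric_boundaries",
    "efficiency",
    "compare_boundaries",
]


@dataclass(frozen=True)
class StrataCountProfile:
    """Rows of (L, objective sum W_h sigma_h, V(mean) = objective^2 / n)."""

    L: tuple[int, ...]
    objective: tuple[float, ...]
    variance: tuple[float, ...]
    n: int

    def __len__(self) -> int:
        return len(self.L)


def strata_count_profile(
    problem: StratificationProblem,
    L_max: int,
    n: int,
    refine_factor: int = 1,
) -> StrataCountProfile:
    """Solve the width program for L = 1..L_max and tabulate the variance."""
    if L_max < 2:
        raise ParameterError("L_max must be at least 2")
    if n < 1:
        raise ParameterError("n must be positive")
    Ls, objs, variances = [], [], []
    for L in range(1, L_max + 1):
        res = solve(problem.with_L(L))
        if refine_factor > 1:
            res = refine(problem.with_L(L), res, refine_factor)
        Ls.append(L)
        objs.append(res.total_objective)
        variances.append(res.total_objective**2 / n)
    return StrataCountProfile(
        L=tuple(Ls), objective=tuple(objs), variance=tuple(variances), n=n
    )


def suggest_elbow(
    profile: StrataCountProfile,
    threshold: float = 0.10,
    method: str = "threshold",
) -> int:
    """Advisory choice of L from a variance profile.

    ``method='threshold'``: the smallest L whose step to L+1 improves
    the variance by less than ``threshold`` (relative); on a 1/L^2
    profile with the default 10% this crosses at L = 19, with 25% at
    L = 7.  ``method='curvature'``: the L maximizing the discrete
    second difference of log-variance.  Both are heuristics; the final
    choice belongs to the surveyor.
    """
    if len(profile) < 3:
        raise ParameterError("profile needs at least 3 rows to suggest an elbow")
    v = np.asarray(profile.variance, dtype=float)
    Ls = np.asarray(profile.L, dtype=int)
    if method == "threshold":
        with np.errstate(divide="ignore", invalid="ignore"):
            improvement = np.where(v[:-1] > 0, (v[:-1] - v[1:]) / v[:-1], 0.0)
        below = np.flatnonzero(improvement < threshold)
        if below.size:
            return int(Ls[below[0]])
        _warnings.warn(
            f"variance improvement never drops below {threshold:.0%} within "
            f"L <= {Ls[-1]}; returning L_max",
            stacklevel=2,
        )
        return int(Ls[-1])
    if method == "curvature":
        with np.errstate(divide="ignore"):
            logv = np.log(np.maximum(v, np.finfo(float).tiny))
        d2 = logv[2:] - 2 * logv[1:-1] + logv[:-2]
        return int(Ls[1:-1][int(np.argmax(d2))])
    raise ParameterError(f"unknown elbow method {method!r}")


def cum_sqrt_f_boundaries(
    sample: Sequence[float], L: int, n_bins: int = 30
) -> tuple[float, ...]:
    """Dalenius-Hodges cumulative square-root-frequency boundaries.

    Histogram the sample into ``n_bins`` equal-width bins, accumulate
    sqrt(frequency), and cut at the bin edges whose cumulative value is
    nearest to the equal multiples of the total.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2 or np.ptp(x) <= 0:
        raise DegenerateDataError("sample needs positive spread for the cum-sqrt-f rule")
    if n_bins < L:
        raise ParameterError(f"n_bins = {n_bins} must be >= L = {L}")
    freq, edges = np.histogram(x, bins=n_bins)
    cum = np.cumsum(np.sqrt(freq))  # cum[k] = value at edges[k+1]
    total = cum[-1]
    boundaries = []
    prev_edge_idx = 0
    for t in range(1, L):
        target = total * t / L
        # nearest interior edge, strictly after the previous boundary and
        # leaving edges for the remaining cuts
        lo = prev_edge_idx + 1
        hi = n_bins - (L - t)
        if lo > hi:
            raise DegenerateDataError("not enough occupied bins to place all boundaries")
        k = lo + int(np.argmin(np.abs(cum[lo - 1 : hi] - target)))
        boundaries.append(float(edges[k]))
        prev_edge_idx = k
    return tuple(boundaries)


def geometric_boundaries(a: float, b: float, L: int) -> tuple[float, ...]:
    """Gunning-Horgan geometric-progression boundaries a r^h, r = (b/a)^(1/L)."""
    if a <= 0:
        raise DomainError("geometric stratification requires a positive lower bound")
    if b <= a:
        raise DomainError(f"need b > a, got a = {a}, b = {b}")
    if L < 1:
        raise ParameterError("L must be >= 1")
    r = (b / a) ** (1.0 / L)
    return tuple(float(a * r**h) for h in range(1, L))


def efficiency(objective_other: float, objective_dp: float) -> float:
    """Efficiency (%) of the optimum over another method: 100 * other / dp."""
    if objective_other <= 0 or objective_dp <= 0:
        raise DomainError("efficiency is defined only for positive objectives")
    return 100.0 * objective_other / objective_dp


def compare_boundaries(
    problem: StratificationProblem,
    others: dict[str, Sequence[float]],
    dp_objective: float,
) -> dict[str, dict[str, float]]:
    """Score baseline boundary sets under the parametric objective.

    Boundaries are clipped to the problem domain before scoring, since
    data-driven rules can place cuts outside the parametric range.
    """
    out: dict[str, dict[str, float]] = {}
    lo, hi = problem.y0, problem.y0 + problem.d
    for name, bounds in others.items():
        clipped = sorted(min(max(float(b), lo), hi) for b in bounds)
        obj, _ = total_objective(problem, clipped)
        out[name] = {"objective": obj, "efficiency_pct": efficiency(obj, dp_objective)}
    return out
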