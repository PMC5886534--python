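"""Dynamic-programming solution of the stratum-width problem.

The separable program

    minimize sum_{h=1}^L phi_h(l_h)   subject to  sum l_h = d,  l_h >= min_width

is solved exactly on a width grid of step delta by the forward Bellman
recursion

    Phi_1(d_1) = phi_1(d_1)
    Phi_k(d_k) = min_{l_k} [ phi_k(d_k - l_k, l_k) + Phi_{k-1}(d_k - l_k) ],

followed by a backward trace that reads off the optimum widths
l*_L .. l*_1 and hence the boundaries y_h = y_{h-1} + l_h.  States d_k
live on the same grid, so the forward pass costs O(L (d/delta)^2)
vectorized phi lookups.  An exhaustive brute-force enumeration (L <= 3)
and a windowed grid-refinement pass are provided alongside.

Ties between equally good widths are broken toward the smallest l_k,
making the output deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ComplexityError, FeasibilityError
from .objective import (
    GridObjective,
    ObjectiveEvaluator,
    StratificationProblem,
    StratificationResult,
    stratum_moment_table,
)

__all__ = ["DPTable", "solve", "brute_force", "refine", "MAX_GRID_STATES"]

MAX_GRID_STATES = 20_000  # d/delta cap; the forward pass is O(L (d/delta)^2)
_CHUNK_CELLS = 40_000_000  # max temp-matrix cells per DP chunk (~320 MB float64)


@dataclass(frozen=True)
class DPTable:
    """Forward-pass record: Phi_k(d_k) values and argmin predecessor states."""

    grid: np.ndarray          # boundary values y0 + delta * index, length M+1
    grid_step: float
    min_width_steps: int
    Phi: np.ndarray           # (L+1, M+1); Phi[k, j] = Phi_k at state j*delta
    pred: np.ndarray          # (L+1, M+1) predecessor state index


def _grid_setup(problem: StratificationProblem):
    M = problem.n_steps
    if M > MAX_GRID_STATES:
        raise ComplexityError(
            f"d/delta = {M} exceeds the cap of {MAX_GRID_STATES}; "
            "coarsen grid_step (a refinement pass can recover resolution)"
        )
    delta = problem.grid_step
    grid = problem.y0 + delta * np.arange(M + 1)
    wmin = int(math.ceil(problem.min_width / delta - 1e-9))
    if problem.L * wmin > M:
        raise FeasibilityError(
            f"L * min_width ({problem.L} * {problem.min_width}) does not fit in d = {problem.d}"
        )
    return M, delta, grid, wmin


def _argmin_largest(A: np.ndarray) -> np.ndarray:
    """Column argmin preferring the *largest* row index among ties.

    The predecessor state with the largest index gives the smallest
    width l_k, the documented tie-break.
    """
    rev = A[::-1, :]
    return (A.shape[0] - 1) - np.argmin(rev, axis=0)


def _forward(problem: StratificationProblem) -> DPTable:
    M, delta, grid, wmin = _grid_setup(problem)
    L = problem.L
    gp = GridObjective(problem, grid)
    INF = np.inf
    Phi = np.full((L + 1, M + 1), INF)
    pred = np.zeros((L + 1, M + 1), dtype=np.intp)
    Phi[0, 0] = 0.0

    js = np.arange(M + 1)
    # stage-k states j must leave room for the remaining strata
    for k in range(1, L + 1):
        j_lo, j_hi = k * wmin, M - (L - k) * wmin
        if k == 1:
            cols = js[j_lo : j_hi + 1]
            Phi[1, cols] = gp.phi_idx(np.zeros_like(cols), cols)
            pred[1, cols] = 0
            continue
        i_lo = (k - 1) * wmin
        cols_all = js[j_lo : j_hi + 1]
        n_rows = M + 1 - i_lo
        chunk = max(1, _CHUNK_CELLS // max(n_rows, 1))
        for c0 in range(0, cols_all.size, chunk):
            cols = cols_all[c0 : c0 + chunk]
            rows = np.arange(i_lo, cols.max() - wmin + 1)
            A = Phi[k - 1, rows][:, None] + gp.phi_idx(rows[:, None], cols[None, :])
            # widths below min_width are infeasible
            infeas = rows[:, None] > (cols[None, :] - wmin)
            A[infeas] = INF
            best = _argmin_largest(A)
            Phi[k, cols] = A[best, np.arange(cols.size)]
            pred[k, cols] = rows[best]
    return DPTable(grid=grid, grid_step=delta, min_width_steps=wmin, Phi=Phi, pred=pred)


def _trace(problem: StratificationProblem, table: DPTable) -> StratificationResult:
    M = table.grid.size - 1
    L = problem.L
    idx = [M]
    j = M
    for k in range(L, 0, -1):
        j = int(table.pred[k, j])
        idx.append(j)
    idx = idx[::-1]  # state indices 0 = y0 .. M = y0 + d
    cuts = table.grid[idx]
    widths = tuple(float(w) for w in np.diff(cuts))
    boundaries = tuple(float(b) for b in cuts[1:-1])
    total, phis = _consistent_objective(problem, boundaries)
    warnings = _mass_warnings(problem, boundaries)
    return StratificationResult(
        boundaries=boundaries,
        widths=widths,
        stratum_objectives=phis,
        total_objective=total,
        stratum_moments=stratum_moment_table(problem, boundaries),
        warnings=warnings,
    )


def _consistent_objective(problem, boundaries):
    ev = ObjectiveEvaluator(problem)
    cuts = np.asarray([problem.y0, *boundaries, problem.y0 + problem.d])
    phis = ev.phi_pairs(cuts[:-1], cuts[1:])
    return float(np.sum(phis)), tuple(float(p) for p in phis)


def _mass_warnings(problem, boundaries) -> tuple[str, ...]:
    out = []
    for h, row in enumerate(stratum_moment_table(problem, boundaries), start=1):
        if all(m.weight <= 1e-12 for m in row.values()):
            out.append(
                f"stratum {h} carries negligible probability mass under every "
                "auxiliary distribution; the n_h >= 1 bound may bind"
            )
    return tuple(out)


def solve(problem: StratificationProblem, return_table: bool = False):
    """Optimum stratum boundaries by forward DP + backward trace."""
    table = _forward(problem)
    result = _trace(problem, table)
    if not math.isclose(
        result.total_objective, float(table.Phi[problem.L, table.grid.size - 1]),
        rel_tol=1e-9, abs_tol=1e-12,
    ):
        raise ArithmeticError(
            "forward-pass optimum disagrees with the traced boundary objective"
        )
    return (result, table) if return_table else result


def brute_force(problem: StratificationProblem) -> StratificationResult:
    """Exhaustive grid enumeration (global grid optimum); guard L <= 3."""
    L = problem.L
    if L > 3:
        raise ComplexityError(f"brute_force is limited to L <= 3, got L = {L}")
    M, delta, grid, wmin = _grid_setup(problem)
    gp = GridObjective(problem, grid)

    if L == 1:
        best_idx: tuple[int, ...] = ()
    elif L == 2:
        i = np.arange(wmin, M - wmin + 1)
        tot = gp.phi_idx(np.zeros_like(i), i) + gp.phi_idx(i, np.full_like(i, M))
        # prefer the largest first-cut index on ties (smallest last width)
        k = (tot.size - 1) - int(np.argmin(tot[::-1]))
        best_idx = (int(i[k]),)
    else:
        best_val = np.inf
        best_idx = (wmin, 2 * wmin)
        for i in range(wmin, M - 2 * wmin + 1):
            j = np.arange(i + wmin, M - wmin + 1)
            tot = (
                gp.phi_idx(0, i)
                + gp.phi_idx(np.full_like(j, i), j)
                + gp.phi_idx(j, np.full_like(j, M))
            )
            k = int(np.argmin(tot))
            if tot[k] < best_val - 1e-15:
                best_val = float(tot[k])
                best_idx = (i, int(j[k]))
    boundaries = tuple(float(grid[i]) for i in best_idx)
    total, phis = _consistent_objective(problem, boundaries)
    widths = tuple(
        float(w)
        for w in np.diff([problem.y0, *boundaries, problem.y0 + problem.d])
    )
    return StratificationResult(
        boundaries=boundaries,
        widths=widths,
        stratum_objectives=phis,
        total_objective=total,
        stratum_moments=stratum_moment_table(problem, boundaries),
        warnings=_mass_warnings(problem, boundaries),
    )


def refine(
    problem: StratificationProblem,
    coarse: StratificationResult,
    refine_factor: int = 10,
) -> StratificationResult:
    """Re-solve on a grid ``refine_factor`` times finer, restricted to
    windows of +/- 2 coarse steps around each coarse boundary.

    The coarse optimum lies inside every window, so the refined
    objective is never worse than the coarse one.
    """
    if refine_factor < 1 or int(refine_factor) != refine_factor:
        raise ValueError(f"refine_factor must be a positive integer, got {refine_factor}")
    if refine_factor == 1 or problem.L == 1:
        return coarse
    f = int(refine_factor)
    M, delta, _, wmin = _grid_setup(problem)
    Mf = M * f
    delta_f = problem.d / Mf
    wmin_f = int(math.ceil(problem.min_width / delta_f - 1e-9))
    L = problem.L
    ev = ObjectiveEvaluator(problem)

    coarse_idx = [int(round((b - problem.y0) / delta)) for b in coarse.boundaries]
    windows: list[np.ndarray] = [np.array([0])]
    for k, bi in enumerate(coarse_idx, start=1):
        lo = max((bi - 2) * f, k * wmin_f)
        hi = min((bi + 2) * f, Mf - (L - k) * wmin_f)
        windows.append(np.arange(lo, hi + 1))
    windows.append(np.array([Mf]))

    def y_of(idx: np.ndarray) -> np.ndarray:
        return problem.y0 + delta_f * idx

    Phi_prev = np.zeros(1)
    preds: list[np.ndarray] = []
    for k in range(1, L + 1):
        S_prev, S = windows[k - 1], windows[k]
        A = Phi_prev[:, None] + ev.phi_pairs(
            y_of(S_prev)[:, None], y_of(S)[None, :]
        )
        A[S_prev[:, None] > S[None, :] - wmin_f] = np.inf
        best = _argmin_largest(A)
        Phi_prev = A[best, np.arange(S.size)]
        preds.append(best)

    # backward trace through the window index chains
    pos = 0  # position inside windows[L] (single terminal state)
    chain = [int(windows[L][pos])]
    for k in range(L, 0, -1):
        pos = int(preds[k - 1][pos])
        chain.append(int(windows[k - 1][pos]))
    chain = chain[::-1]
    boundaries = tuple(float(problem.y0 + delta_f * i) for i in chain[1:-1])
    total, phis = _consistent_objective(problem, boundaries)
    if total > coarse.total_objective + 1e-12:
        return coarse  # numerically degenerate window; keep the coarse optimum
    widths = tuple(
        float(w)
        for w in np.diff([problem.y0, *boundaries, problem.y0 + problem.d])
    )
    return StratificationResult(
        boundaries=boundaries,
        widths=widths,
        stratum_objectives=phis,
        total_objective=total,
        stratum_moments=stratum_moment_table(problem, boundaries),
        warnings=_mass_warnings(problem, boundaries),
    )


def solve_refined(
    problem: StratificationProblem, refine_factor: int = 10
) -> StratificationResult:
    """Coarse DP solve followed by one windowed refinement pass."""
    coarse = solve(problem)
    return refine(problem, coarse, refine_factor)
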