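"""Neyman allocation of a fixed total sample across strata.

Under Neyman allocation the stratum sample sizes are proportional to
W_h sigma_h, which minimizes the variance of the stratified mean for a
fixed total n.  Real-valued allocations are integerized by
largest-remainder (Hamilton) rounding and then clamped to the bounds
1 <= n_h <= N_h: over-capacity strata are fixed at N_h with the excess
re-allocated Neyman-proportionally among the rest, and empty strata are
raised to one unit with the deficit taken from the largest allocation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import AllocationError

__all__ = ["AllocationResult", "neyman_allocate", "integerize_and_bound", "allocate"]


@dataclass(frozen=True)
class AllocationResult:
    n_h: tuple[int, ...]
    N_h: tuple[int, ...]
    clamped: tuple[bool, ...]
    variance_terms: tuple[float, ...]  # (W_h sigma_h)^2 / n_h contributions

    @property
    def variance_proxy(self) -> float:
        return float(sum(self.variance_terms))


def neyman_allocate(stratum_terms: Sequence[float], n: int) -> np.ndarray:
    """Real-valued Neyman allocations n * term_h / sum(terms)."""
    terms = np.asarray(stratum_terms, dtype=float)
    if terms.size == 0 or np.any(terms < 0):
        raise AllocationError("stratum terms must be nonnegative")
    total = terms.sum()
    if total <= 0:
        raise AllocationError("all stratum terms are zero; allocation is undefined")
    if n <= 0:
        raise AllocationError("total sample size must be positive")
    return n * terms / total


def _largest_remainder(reals: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(reals).astype(int)
    short = total - int(floors.sum())
    if short < 0:  # guard against upstream rounding drift
        raise AllocationError(f"real allocations exceed the total by {-short}")
    remainders = reals - floors
    # deterministic: larger remainder first, ties to the lower index
    order = np.lexsort((np.arange(reals.size), -remainders))
    out = floors.copy()
    out[order[:short]] += 1
    return out


def integerize_and_bound(
    reals: Sequence[float],
    n: int,
    N_h: Sequence[int],
    stratum_terms: Sequence[float] | None = None,
) -> AllocationResult:
    """Integerize real allocations to sum exactly to n within 1 <= n_h <= N_h.

    ``stratum_terms`` (the W_h sigma_h weights) steer the proportional
    redistribution after clamping; they default to the real allocations
    themselves.
    """
    reals = np.asarray(reals, dtype=float)
    caps = np.asarray(N_h, dtype=int)
    L = reals.size
    if caps.size != L:
        raise AllocationError("N_h must have one entry per stratum")
    if np.any(caps < 1):
        raise AllocationError("every stratum must contain at least one unit (N_h >= 1)")
    if abs(reals.sum() - n) > 1e-6 * max(n, 1):
        raise AllocationError(f"real allocations sum to {reals.sum()}, expected {n}")
    if n > int(caps.sum()):
        raise AllocationError(f"n = {n} exceeds the population total {int(caps.sum())}")
    if n < L:
        raise AllocationError(f"n = {n} cannot give every one of {L} strata a unit")
    terms = np.asarray(stratum_terms, dtype=float) if stratum_terms is not None else reals.copy()

    alloc = np.zeros(L, dtype=int)
    fixed = np.zeros(L, dtype=bool)
    # iterative clamping at capacity; terminates in <= L rounds since each
    # round fixes at least one stratum
    for _ in range(L + 1):
        free = ~fixed
        remaining = n - int(alloc[fixed].sum())
        w = terms[free]
        if w.sum() <= 0:
            share = np.full(free.sum(), remaining / free.sum())
        else:
            share = remaining * w / w.sum()
        cand = _largest_remainder(share, remaining)
        over = cand > caps[free]
        if not over.any():
            alloc[free] = cand
            break
        free_idx = np.flatnonzero(free)
        alloc[free_idx[over]] = caps[free_idx[over]]
        fixed[free_idx[over]] = True
        if fixed.all():
            break
    clamped_over = alloc >= caps

    # raise empty strata to one unit, taking the deficit from the largest
    clamped_low = np.zeros(L, dtype=bool)
    while np.any(alloc < 1):
        i = int(np.argmin(alloc))
        j = int(np.argmax(alloc))
        if alloc[j] <= 1:
            raise AllocationError("cannot satisfy n_h >= 1 within the total n")
        alloc[i] += 1
        alloc[j] -= 1
        clamped_low[i] = True

    if int(alloc.sum()) != n:
        raise AllocationError(
            f"internal error: allocations sum to {int(alloc.sum())}, expected {n}"
        )
    var_terms = tuple(
        float(t * t / m) if m > 0 else float("inf") for t, m in zip(terms, alloc)
    )
    return AllocationResult(
        n_h=tuple(int(v) for v in alloc),
        N_h=tuple(int(c) for c in caps),
        clamped=tuple(bool(a or b) for a, b in zip(clamped_over, clamped_low)),
        variance_terms=var_terms,
    )


def allocate(
    stratum_terms: Sequence[float], n: int, N_h: Sequence[int]
) -> AllocationResult:
    """Neyman allocation + integerization + bounds in one call."""
    reals = neyman_allocate(stratum_terms, n)
    return integerize_and_bound(reals, n, N_h, stratum_terms=stratum_terms)
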