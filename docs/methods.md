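# Methods

This note records the model, the numerical choices and the known
limitations of the package, in the order the method runs.

## Model and objective

The population is to be stratified for estimating the mean of a study
variable *y* that follows

    y = λ(x₁, …, x_p) + ε,   E[ε|x] = 0,   Var(ε|x) = σ_ε²  (homoscedastic),

with λ a polynomial of degree ≤ 2 in auxiliary variables x_i whose
marginal distributions are parametric (3P Weibull, 3P Gamma, or uniform
for reference).  λ and ε are taken as uncorrelated, so within stratum h

    σ²_hy = σ²_hλ + σ²_hε.

Dropping the finite-population correction, minimizing the Neyman-allocated
variance `V(ȳ_st) = (Σ_h W_h σ_hy)²/n` for fixed n reduces to minimizing
`Σ_h W_h σ_hy`.  Every stratum factor is a function of the two cut
points, so with widths l_h as decision variables the problem is the
separable program

    min Σ φ_h(l_h)  s.t.  Σ l_h = d,  l_h ≥ min_width,

with φ_h² = Σ_i β_i²(W²σ²)_{h,x_i} + s_ε²(W²σ²)_{h,ε}.

Two modelling conventions deserve emphasis:

* **Cross-variable covariances are set to zero** when summing σ²_hλ over
  auxiliaries.  This is exact when the auxiliaries are independent (as in
  the synthetic generator) and an approximation otherwise; real
  health-survey auxiliaries (e.g. iron and folate) are correlated, and
  the objective then under- or over-states σ²_hλ accordingly.
* **Error-term scale.**  `error_mode="unit"` (default) enters the error
  component as a truncated *standard* normal, the construction in which
  the boundary problem is usually stated; `error_mode="rse"` multiplies
  the truncated-normal variance by the fitted residual standard error
  squared, which is the internally consistent choice when the fitted
  model has RSE far from 1.  The two modes generally give different
  boundaries; the default favours comparability with the standard
  construction and the discrepancy is a user-visible switch, not a
  hidden constant.

## Truncated moments

All stratum quantities derive from upper partial moments
U_k(t) = ∫_t^∞ x^k f(x) dx:

* Weibull(r, θ, γ): ∫_t^∞ (x−γ)^k f dx = θ^k Γ(1+k/r) Q(1+k/r, z^r),
  z = (t−γ)/θ clipped to ≥ 0, Q the regularized upper incomplete gamma;
* Gamma(α, θ, γ): θ^k (α)_k Q(α+k, z) with (α)_k the rising factorial;
* standard normal: the recurrence I_k = t^{k−1}φ(t) + (k−1) I_{k−2}
  with I₀ = Φ̄, I₁ = φ;
* γ ≠ 0 handled by binomial expansion of ((x−γ)+γ)^k.

Orders up to 4 are closed-form (order 4 is what a quadratic link
needs); higher orders raise `NotImplementedError` and are available via
the quadrature oracle.  Weight-scaled variances are always computed in
the **product form** W²σ² = W·(W E[g²]) − (W E[g])², never by dividing
by W first: strata in the far tail have weights near underflow, and
the product form stays exact there (a massless stratum contributes
φ = 0, which is the correct limit — there is nothing to sample).
Negative values from cancellation are clipped at 0; the user-facing
`stratum_variance` raises if the inconsistency exceeds 1e−12
relatively.  Cut points below the support are clipped to the support,
which is exact because the density vanishes there.

`quadrature_moment` integrates x^k f(x) by adaptive quadrature
(`scipy.integrate.quad`, tolerances 1e−13/1e−11) and is the independent
oracle for every closed form in the tests; improper upper limits are
truncated where the remaining mass underflows double precision.

## Fitting

Distribution fitting profiles the location out of the likelihood:
γ is restricted to ≤ min(sample) − ε with ε = 1e−6 × range (the 3P
Weibull/Gamma likelihood is unbounded as γ → min(sample)), the
conditional shape/scale MLE is computed by `scipy.stats.*.fit(floc=γ)`,
and the profile is maximized by bounded scalar search.  The KS test is
run against the *fitted* CDF; with estimated parameters its p-value is
anti-conservative (no Lilliefors correction), and is reported as
approximate.  Family "auto" fits both Weibull and Gamma and keeps the
higher log-likelihood.

The regression link is ordinary least squares (statsmodels) on terms
like `x1`, `x1^2`.  Reported metrics: multiple correlation √R²,
RSE = √(SSE/(n−p−1)), adjusted R², and AIC in the R/`lm` convention
(n log 2π + n log(SSE/n) + n + 2(p+2), σ² counted as a parameter);
only AIC *differences* are meaningful and those agree with any
fixed-constant convention.

## Dynamic program

The grid has M = d/δ states (δ snapped so M is integral; default
δ = d/1000, hard cap M ≤ 20 000 since the forward pass is O(L·M²)).
Stage k stores Φ_k(d_k) = min over feasible widths of
φ_k + Φ_{k−1}(d_k − l_k); the pair sweep is evaluated from per-grid
tables of U_k, so each stage is vectorized arithmetic rather than
special-function calls, chunked to bound temporary matrices at
~320 MB.  The backward trace reads the widths; ties are broken toward
the smallest width (implemented as the largest predecessor index), so
output is deterministic.

`min_width` defaults to one grid step, which keeps every stratum
non-empty so the n_h ≥ 1 allocation bound is attainable; it can be set
to 0 for the literal l_h ≥ 0 program.  A windowed refinement pass
re-solves on a grid `refine_factor` times finer inside ±2 coarse steps
of each coarse boundary; the coarse optimum lies in every window, so
refinement can only improve the objective.  `brute_force` enumerates
all boundary placements for L ≤ 3 and is the solver's oracle in tests.
The one-stage grid plus a ×10 refinement is this package's own
engineering default; both δ and the factor are exposed in config.

## Allocation

Real Neyman allocations n·t_h/Σt (t_h = W_h σ_h, here φ_h) are
integerized by largest-remainder rounding (deterministic, ties to the
lower index), then clamped: strata over capacity are fixed at N_h with
the excess redistributed Neyman-proportionally among the rest
(terminates in ≤ L rounds), and sub-unit strata are raised to 1 with
the deficit taken from the largest allocation.  On exhaustive small
instances the result is within one unit-swap of the integer optimum of
Σ t_h²/n_h (the tests assert exactly that).  For parametric inputs N_h
is not observable; it is taken as round(N·W_h) using the weights of the
first-listed auxiliary by default (`weight_variable` selects another) —
a documented convention, since with several auxiliaries each implies
its own W_h for the same cuts.

## Strata-count profile and baselines

The profile tabulates the objective and V = objective²/n for
L = 1..L_max.  For a uniform variable V(L) = V(1)/L² exactly (verified
on the DP within grid tolerance).  Two advisory elbow rules are
implemented: the first L whose step to L+1 improves V by less than a
threshold (default 10%; on a 1/L² profile the 10% rule crosses at
L = 19 and a 25% rule at L = 7), and the L maximizing the second
difference of log V.  Neither replaces surveyor judgment, and no cost
model is attempted.

Baselines: the classical cumulative-√frequency rule (equal-width
histogram, default 30 bins, cuts at edges nearest to equal increments
of cumulative √f, successive cuts forced strictly forward) and the
geometric-progression rule k_h = a·r^h, r = (b/a)^{1/L} (undefined for
a ≤ 0).  Baseline boundaries are scored with **the same parametric
objective** as the DP optimum, so efficiency percentages
(100·other/DP) compare rules, not estimation pipelines; the
Lavallée–Hidiroglou/Kozak family is not reimplemented (an established
R package exists for it) and externally computed objectives can be
injected into the comparison table.

## Pipeline conventions

* Max-scaling: each auxiliary is divided by its maximum, which puts all
  variables on a common (0, 1]-ish boundary domain and shrinks the DP
  search space; factors are retained and boundaries are rescaled for
  reporting.  When the study variable is present its maximum is the
  reporting scale; for purely parametric input boundaries stay on the
  given scale.
* "auto" domain: y₀ = min over fitted locations γ̂_i, floored at the
  observed scaled minimum; d = max scaled observation − y₀.  Supplying
  (y₀, d) from subject-matter knowledge of the study variable's range
  is generally better and always possible.
* OSB are rounded to 2 decimals and n_h printed as integers only in the
  presentation columns; `result.json` carries full precision and is
  byte-stable for a fixed config and seed.

## Synthetic generator

`paperlike_population()` is the package's reference study condition:
N = 5000 units, two independent 3P Weibull auxiliaries with shapes
2.0 and 1.8 (moderately right-skewed, as is typical of micronutrient
measurements), a weak linear link (β = 0.02, 0.01) under noise
σ = 1.8, giving adjusted R² below 0.1 % and RSE ≈ 1.8 — the
near-uncorrelated regime.  It is labelled an *emulation* of that
regime, not a reproduction of any published dataset: auxiliaries are
drawn independently (no copula), the link is exactly polynomial and
the error exactly normal and homoscedastic.  Passing tests on it
therefore validate the machinery under the model's own assumptions;
they do not certify behaviour under correlated auxiliaries,
heteroscedastic errors or misspecified marginals.

## Problem sizes and tolerances

Defaults used in tests and the acceptance script: DP grids of 200–1000
states with refinement factors 1–10, populations of N = 5000,
20 randomized solver-oracle problems, quadrature-oracle agreement at
1e−8 relative, DP-vs-brute-force agreement at 1e−10 in objective and
one grid step per boundary, allocation optimality checked exhaustively
for L ≤ 3, n ≤ 30.  These sizes were chosen so the whole suite
completes in well under a minute while leaving every check far from
its tolerance.

## Known limitations

* Heteroscedastic error models ψ(x) are out of scope; only constant σ_ε.
* λ beyond degree-2 polynomials is not supported (closed-form moments
  would need orders > 4).
* Correlated auxiliaries violate the zero-covariance assembly of σ²_hλ
  (see above); the package follows the standard construction and flags
  it here.
* The DP guarantees the *grid* optimum; continuous optimality holds up
  to O(δ) (empirically verified convergence), not exactly.
* The KS p-values after fitting are optimistic; treat "p > 0.05" as a
  screening statement.
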