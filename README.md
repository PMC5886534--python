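# optstrat

Optimum stratum boundaries (OSB) and optimum sample sizes (OSS) for
stratified surveys, computed from **auxiliary variables** when the study
variable itself is unavailable at the design stage.

## The problem

A survey planner wants to estimate the mean of a study variable *y*
(say, haemoglobin in a national anaemia survey) by stratified random
sampling.  Precision is maximized when strata are internally homogeneous
in *y* — but *y* is exactly what the survey has yet to measure.  What
*is* available are correlated auxiliary variables *x₁…x_p* (iron,
folate, …) from registers or earlier surveys, which in health data are
typically right-skewed and well described by three-parameter Weibull or
Gamma distributions.

Assume the regression model

    y = λ(x₁, …, x_p) + ε,   λ polynomial of degree ≤ 2,   ε ~ N(0, σ_ε²),

with homoscedastic error.  Under Neyman allocation the variance of the
stratified mean is `V(ȳ_st) = (Σ_h W_h σ_hy)² / n`, and with the model
above `σ²_hy = σ²_hλ + σ²_hε`.  Choosing the L−1 cut points
`y₁ ≤ … ≤ y_{L−1}` of a common (max-scaled) boundary domain `[y₀, y₀+d]`
to minimize `Σ_h W_h σ_hy` is therefore a **separable mathematical
programming problem over the stratum widths** `l_h = y_h − y_{h−1}`:

    minimize Σ_h φ_h(l_h)   subject to  Σ_h l_h = d,  l_h ≥ 0,

where every factor of

    φ_h = √( Σ_i β_i² W²_{h,x_i} σ²_{h,x_i} + W²_{h,ε} σ²_{h,ε} )

is available **in closed form** through regularized incomplete gamma
functions (Weibull/Gamma truncated moments) and erf/φ expressions
(truncated normal error).  The program is solved exactly on a width grid
by forward dynamic programming with backward trace, then the sample is
spread by Neyman allocation with the bounds `1 ≤ n_h ≤ N_h`.

## What the package provides

| module | contents |
| --- | --- |
| `optstrat.distributions` | 3P Weibull/Gamma/uniform/standard-normal truncated weights, means, variances and moments (closed form + quadrature oracle); MLE fitting with a KS check |
| `optstrat.regression` | polynomial OLS link fitting; metrics (correlation, RSE, adjusted R², AIC); within-stratum variance of λ |
| `optstrat.objective` | assembly of φ_h and the total objective for a boundary set |
| `optstrat.solver` | the DP solver, an exhaustive brute-force oracle (L ≤ 3) and windowed grid refinement |
| `optstrat.allocation` | Neyman allocation, largest-remainder integerization, bound clamping |
| `optstrat.design` | strata-count profiling with elbow heuristics; cum-√f and geometric baseline stratifiers; efficiency comparison |
| `optstrat.simulate` | synthetic skewed populations and bootstrap resampling |
| `optstrat.pipeline` / `optstrat.cli` | end-to-end runs from CSV or config, JSON/CSV reports, `optstrat` command |

## Worked example

```python
import math
from optstrat import StratificationProblem, uniform, weibull3p, solve, allocate

# analytic sanity check: uniform(0,1), one auxiliary, two strata
p = StratificationProblem.linear(0.0, 1.0, [uniform(0, 1)], [1.0],
                                 error_scale=None, L=2, grid_step=0.001)
res = solve(p)
print(res.boundaries, round(res.total_objective, 6), round(1/(2*math.sqrt(12)), 6))
# (0.5,) 0.144338 0.144338   <- the optimum cuts the range in half and the
#                               objective halves the unstratified 1/sqrt(12)

# a skewed auxiliary: Rayleigh-shaped Weibull on [0, 4], three strata
w = StratificationProblem.linear(0.0, 4.0, [weibull3p(2.0, 1.0, 0.0)], [1.0],
                                 error_scale=None, L=3, grid_step=0.002)
res = solve(w)
print([round(b, 3) for b in res.boundaries], round(res.total_objective, 5))
# [0.688, 1.21] 0.18627      <- narrow strata where the density is high

alloc = allocate(res.stratum_objectives, n=500, N_h=[1980, 1560, 1460])
print(alloc.n_h)
# (167, 156, 177)            <- Neyman shares, integers summing to 500
```

The first line confirms the solver against a case solvable by calculus;
the second shows the typical behaviour on skewed data: boundaries crowd
the mode so every stratum carries comparable `W_h σ_h`, and Neyman
allocation then assigns more of the sample where that product is larger.

The same chain runs end-to-end from data via the CLI:

```bash
optstrat stratify config.yaml -o out/    # fit + solve + allocate
optstrat profile config.yaml --l-max 8   # objective/variance vs L
optstrat compare config.yaml             # vs cum-sqrt-f and geometric rules
```

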