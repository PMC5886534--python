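"""Parametric distribution layer for stratified survey design.

Auxiliary variables in skewed survey populations are modelled with
three-parameter (shape, scale, location) Weibull or Gamma families; the
regression error is a standard normal; a uniform family serves as an
analytic reference.  Everything the stratification objective needs —
stratum weight W_h, conditional mean, variance and higher conditional
moments over an interval [lower, lower + width] — is available in closed
form through regularized incomplete gamma functions (Weibull/Gamma) or
erf/phi expressions (normal error).

The numerically load-bearing primitive is the *upper partial moment*

    U_k(y) = integral_y^inf  x^k f(x) dx,

because every stratum quantity is a difference U_k(lower) -
U_k(lower + width): weights are U_0 differences, W*E[X^k | stratum] is a
U_k difference, and the weight-scaled variance W^2 sigma^2 can be formed
without ever dividing by a tiny W.  A quadrature oracle integrating the
density directly backs every closed form in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
from scipy import integrate, optimize, special, stats

from .exceptions import (
    DegenerateDataError,
    DegenerateStratumError,
    DomainError,
    FitError,
    ParameterError,
)

__all__ = [
    "Family",
    "DistributionSpec",
    "StratumMoments",
    "FitReport",
    "weibull3p",
    "gamma3p",
    "uniform",
    "std_normal_error",
    "pdf",
    "cdf",
    "upper_partial_moment",
    "stratum_weight",
    "stratum_mean",
    "stratum_variance",
    "stratum_moments",
    "truncated_moment",
    "quadrature_moment",
    "weight_scaled_variance",
    "draw",
    "fit_mle",
]

_MAX_CLOSED_FORM_ORDER = 4
_TINY_WEIGHT = 1e-300  # below this a stratum is treated as massless
_DEGENERATE_WEIGHT = 1e-15


class Family(str, Enum):
    WEIBULL3P = "weibull3p"
    GAMMA3P = "gamma3p"
    UNIFORM = "uniform"
    STD_NORMAL_ERROR = "std_normal_error"


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric family with its parameters.

    ``shape``/``scale``/``location`` follow the (r, theta, gamma)
    convention for Weibull and (alpha, theta, gamma) for Gamma.  For the
    uniform family ``location`` is the lower bound a and ``scale`` the
    upper bound b.  The standard-normal error carries no parameters.
    """

    family: Family
    shape: float | None = None
    scale: float | None = None
    location: float | None = None

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        if fam in (Family.WEIBULL3P, Family.GAMMA3P):
            if self.shape is None or self.scale is None:
                raise ParameterError(f"{fam.value} requires shape and scale")
            if not (self.shape > 0 and self.scale > 0):
                raise ParameterError("shape and scale must be positive")
            if self.location is None:
                object.__setattr__(self, "location", 0.0)
        elif fam is Family.UNIFORM:
            if self.scale is None or self.location is None:
                raise ParameterError("uniform requires location=a and scale=b")
            if not self.scale > self.location:
                raise ParameterError("uniform requires b > a")
            if self.shape is not None:
                raise ParameterError("uniform has no shape parameter")
        else:  # STD_NORMAL_ERROR
            if any(v is not None for v in (self.shape, self.scale, self.location)):
                raise ParameterError("std_normal_error takes no parameters")

    @property
    def support(self) -> tuple[float, float]:
        if self.family in (Family.WEIBULL3P, Family.GAMMA3P):
            return (float(self.location), math.inf)
        if self.family is Family.UNIFORM:
            return (float(self.location), float(self.scale))
        return (-math.inf, math.inf)

    def mean(self) -> float:
        """Unconditional mean (closed form)."""
        return stratum_mean(self, self.support[0], math.inf)

    def variance(self) -> float:
        """Unconditional variance (closed form)."""
        return stratum_variance(self, self.support[0], math.inf)


def weibull3p(shape: float, scale: float, location: float = 0.0) -> DistributionSpec:
    return DistributionSpec(Family.WEIBULL3P, shape=shape, scale=scale, location=location)


def gamma3p(shape: float, scale: float, location: float = 0.0) -> DistributionSpec:
    return DistributionSpec(Family.GAMMA3P, shape=shape, scale=scale, location=location)


def uniform(a: float, b: float) -> DistributionSpec:
    return DistributionSpec(Family.UNIFORM, scale=b, location=a)


def std_normal_error() -> DistributionSpec:
    return DistributionSpec(Family.STD_NORMAL_ERROR)


@dataclass(frozen=True)
class StratumMoments:
    """Weight W_h, conditional mean mu_h and conditional variance sigma_h^2."""

    weight: float
    mean: float
    variance: float


# ---------------------------------------------------------------------------
# densities and CDFs
# ---------------------------------------------------------------------------

def pdf(dist: DistributionSpec, x):
    """Density f(x); zero below/above the support. Vectorized in ``x``."""
    x = np.asarray(x, dtype=float)
    fam = dist.family
    if fam is Family.WEIBULL3P:
        r, th, g = dist.shape, dist.scale, dist.location
        z = np.where(x >= g, (x - g) / th, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = (r / th) * z ** (r - 1.0) * np.exp(-(z**r))
        val = np.where(x >= g, val, 0.0)
        # r < 1 diverges at the support edge; keep the limit convention f=inf
        return val if val.shape else float(val)
    if fam is Family.GAMMA3P:
        a, th, g = dist.shape, dist.scale, dist.location
        val = stats.gamma.pdf(x, a, loc=g, scale=th)
        return val if val.shape else float(val)
    if fam is Family.UNIFORM:
        a, b = dist.location, dist.scale
        val = np.where((x >= a) & (x <= b), 1.0 / (b - a), 0.0)
        return val if val.shape else float(val)
    val = stats.norm.pdf(x)
    return val if val.shape else float(val)


def cdf(dist: DistributionSpec, x):
    """Distribution function F(x); vectorized in ``x``."""
    x = np.asarray(x, dtype=float)
    val = 1.0 - upper_partial_moment(dist, 0, x)
    return val if np.shape(val) else float(val)


# ---------------------------------------------------------------------------
# upper partial moments U_k(y) = int_y^inf x^k f(x) dx
# ---------------------------------------------------------------------------

def upper_partial_moment(dist: DistributionSpec, order: int, y):
    """U_k(y) = integral over (y, upper support) of x^k f(x) dx.

    Closed form for k = 0..4; vectorized in ``y``.  Values of ``y`` below
    the support are clipped to the support (the density vanishes there,
    so clipping is exact).
    """
    if not (isinstance(order, (int, np.integer)) and 0 <= order):
        raise ParameterError("order must be a nonnegative integer")
    if order > _MAX_CLOSED_FORM_ORDER:
        raise NotImplementedError(
            f"closed-form moments available up to order {_MAX_CLOSED_FORM_ORDER}; "
            "use quadrature_moment for higher orders"
        )
    y = np.asarray(y, dtype=float)
    fam = dist.family
    if fam is Family.WEIBULL3P:
        out = _upm_gamma_kernel(order, y, dist, weibull=True)
    elif fam is Family.GAMMA3P:
        out = _upm_gamma_kernel(order, y, dist, weibull=False)
    elif fam is Family.UNIFORM:
        a, b = dist.location, dist.scale
        yc = np.clip(y, a, b)
        k = order
        out = (b ** (k + 1) - yc ** (k + 1)) / ((k + 1) * (b - a))
    else:
        out = _upm_std_normal(order, y)
    return out if out.shape else float(out)


def _central_upm(order: int, z_pow: np.ndarray, dist: DistributionSpec, weibull: bool):
    """integral_y^inf (x - gamma)^k f(x) dx as a function of the transformed
    lower limit (z^r for Weibull, z for Gamma)."""
    th = dist.scale
    if weibull:
        r = dist.shape
        return th**order * special.gamma(1.0 + order / r) * special.gammaincc(
            1.0 + order / r, z_pow
        )
    a = dist.shape
    # Gamma(alpha+k)/Gamma(alpha) = rising factorial alpha(alpha+1)...(alpha+k-1)
    rising = 1.0
    for j in range(order):
        rising *= a + j
    return th**order * rising * special.gammaincc(a + order, z_pow)


def _upm_gamma_kernel(order: int, y: np.ndarray, dist: DistributionSpec, weibull: bool):
    g = dist.location
    th = dist.scale
    z = np.clip((y - g) / th, 0.0, None)
    z = np.where(np.isfinite(y), z, np.where(y > 0, np.inf, 0.0))
    z_pow = z ** dist.shape if weibull else z
    # binomial expansion of x^k = ((x - gamma) + gamma)^k
    out = np.zeros_like(z, dtype=float)
    for j in range(order + 1):
        cj = math.comb(order, j) * g ** (order - j)
        if cj != 0.0:
            out = out + cj * _central_upm(j, z_pow, dist, weibull)
    if order == 0:  # avoid 0**0 bookkeeping above when gamma == 0
        out = _central_upm(0, z_pow, dist, weibull)
    return out


def _upm_std_normal(order: int, y: np.ndarray):
    """U_k for the standard normal via the recurrence
    I_k(y) = y^(k-1) phi(y) + (k-1) I_{k-2}(y), I_0 = Phi-bar, I_1 = phi."""
    phi_y = stats.norm.pdf(y)
    finite = np.isfinite(y)
    yf = np.where(finite, y, 0.0)  # phi(+-inf)=0 kills these terms anyway
    moments = [np.asarray(stats.norm.sf(y), dtype=float), phi_y]
    for k in range(2, order + 1):
        moments.append(yf ** (k - 1) * phi_y + (k - 1) * moments[k - 2])
    return moments[order]


# ---------------------------------------------------------------------------
# stratum quantities
# ---------------------------------------------------------------------------

def _bounds(dist: DistributionSpec, lower: float, width: float) -> tuple[float, float]:
    if width < 0:
        raise DomainError(f"stratum width must be nonnegative, got {width}")
    upper = lower + width if math.isfinite(width) else math.inf
    return float(lower), float(upper)


def stratum_weight(dist: DistributionSpec, lower: float, width: float) -> float:
    """Probability mass W of the stratum [lower, lower + width]."""
    a, b = _bounds(dist, lower, width)
    if a == b:
        return 0.0
    w = float(upper_partial_moment(dist, 0, a) - upper_partial_moment(dist, 0, b))
    return min(max(w, 0.0), 1.0)


def _scaled_raw(dist: DistributionSpec, order: int, a: float, b: float) -> float:
    """W * E[X^k | stratum] = U_k(a) - U_k(b) (no division by W)."""
    return float(upper_partial_moment(dist, order, a) - upper_partial_moment(dist, order, b))


def weight_scaled_variance(dist: DistributionSpec, lower: float, width: float) -> float:
    """W^2 sigma^2 for the stratum, via W*(W E[X^2]) - (W E[X])^2.

    This product form stays finite and accurate for strata of tiny
    weight, where dividing by W first would lose all precision.
    """
    a, b = _bounds(dist, lower, width)
    if a == b:
        return 0.0
    w = stratum_weight(dist, lower, width)
    s1 = _scaled_raw(dist, 1, a, b)
    s2 = _scaled_raw(dist, 2, a, b)
    v = w * s2 - s1 * s1
    if v < -1e-12 * max(1.0, abs(s2)):
        raise DegenerateStratumError(
            f"inconsistent negative scaled variance {v!r} for stratum [{a}, {b}]"
        )
    return max(v, 0.0)


def _require_mass(dist: DistributionSpec, lower: float, width: float) -> float:
    w = stratum_weight(dist, lower, width)
    if w <= _DEGENERATE_WEIGHT:
        raise DegenerateStratumError(
            f"stratum [{lower}, {lower + width}] carries no probability mass "
            f"(W = {w!r}) under {dist.family.value}"
        )
    return w


def stratum_mean(dist: DistributionSpec, lower: float, width: float) -> float:
    """Conditional mean E[X | X in stratum]."""
    a, b = _bounds(dist, lower, width)
    w = _require_mass(dist, lower, width)
    return _scaled_raw(dist, 1, a, b) / w


def stratum_variance(dist: DistributionSpec, lower: float, width: float) -> float:
    """Conditional variance Var(X | X in stratum)."""
    w = _require_mass(dist, lower, width)
    return weight_scaled_variance(dist, lower, width) / (w * w)


def stratum_moments(dist: DistributionSpec, lower: float, width: float) -> StratumMoments:
    """Weight, conditional mean and conditional variance in one call."""
    w = _require_mass(dist, lower, width)
    a, b = _bounds(dist, lower, width)
    mean = _scaled_raw(dist, 1, a, b) / w
    var = weight_scaled_variance(dist, lower, width) / (w * w)
    return StratumMoments(weight=w, mean=mean, variance=var)


def truncated_moment(dist: DistributionSpec, order: int, lower: float, width: float) -> float:
    """Conditional raw moment E[X^k | X in stratum], closed form for k <= 4."""
    a, b = _bounds(dist, lower, width)
    if order == 0:
        _require_mass(dist, lower, width)
        return 1.0
    w = _require_mass(dist, lower, width)
    return _scaled_raw(dist, order, a, b) / w


def quadrature_moment(
    dist: DistributionSpec, order: int, lower: float, width: float
) -> float:
    """E[X^k | stratum] by adaptive quadrature of x^k f(x).

    Independent numeric oracle for every closed form above; integrates
    the density directly rather than reusing the incomplete-gamma/erf
    expressions.
    """
    a, b = _bounds(dist, lower, width)
    lo, hi = dist.support
    a, b = max(a, lo), min(b, hi)
    if not b > a:
        raise DegenerateStratumError("stratum does not intersect the support")
    if not math.isfinite(b):
        # truncate the improper integral where the remaining mass underflows
        # to zero in double precision (exp(-745) == 0.0)
        if dist.family is Family.WEIBULL3P:
            b = dist.location + dist.scale * 745.0 ** (1.0 / dist.shape)
        elif dist.family is Family.GAMMA3P:
            b = dist.location + dist.scale * (745.0 + 10.0 * dist.shape)
        else:
            b = 40.0
        b = max(b, a + 1.0)
    if not math.isfinite(a):
        a = min(-40.0, b - 1.0)

    def integrand(x, k=order):
        return x**k * pdf(dist, x)

    opts = dict(limit=400, epsabs=1e-13, epsrel=1e-11)
    w, werr = integrate.quad(integrand, a, b, args=(0,), **opts)
    if w <= _DEGENERATE_WEIGHT:
        raise DegenerateStratumError(f"quadrature weight {w!r} is numerically zero")
    m, merr = integrate.quad(integrand, a, b, **opts)
    # quad's error estimates are conservative upper bounds; the absolute
    # floor covers moments that vanish by symmetry
    if werr > max(1e-6 * w, 1e-10) or merr > max(1e-6 * abs(m), 1e-10):
        raise ArithmeticError(
            f"quadrature failed to converge: weight err {werr}, moment err {merr}"
        )
    return m / w


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def draw(dist: DistributionSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` variates (used by the synthetic-population generator)."""
    fam = dist.family
    if fam is Family.WEIBULL3P:
        return dist.location + dist.scale * rng.weibull(dist.shape, size)
    if fam is Family.GAMMA3P:
        return dist.location + rng.gamma(dist.shape, dist.scale, size)
    if fam is Family.UNIFORM:
        return rng.uniform(dist.location, dist.scale, size)
    return rng.standard_normal(size)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting with a Kolmogorov-Smirnov check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitReport:
    spec: DistributionSpec
    log_likelihood: float
    ks_statistic: float
    ks_pvalue: float


def _scipy_frozen(family: Family, shape: float, scale: float, location: float):
    if family is Family.WEIBULL3P:
        return stats.weibull_min(shape, loc=location, scale=scale)
    return stats.gamma(shape, loc=location, scale=scale)


def fit_mle(sample: Iterable[float], family: Family | str) -> FitReport:
    """MLE of a 3-parameter Weibull or Gamma, with a KS goodness-of-fit check.

    The location is profiled out: for each candidate gamma (bounded above
    by min(sample) - eps to keep the likelihood finite) the shape/scale
    MLE is computed conditionally, and the profile likelihood is
    maximized over gamma by bounded scalar search.

    The KS p-value is computed against the *fitted* CDF; with estimated
    parameters it is anti-conservative (no Lilliefors-type correction is
    applied) and should be read as approximate.
    """
    family = Family(family)
    if family not in (Family.WEIBULL3P, Family.GAMMA3P):
        raise ParameterError(f"fit_mle supports weibull3p/gamma3p, got {family.value}")
    x = np.asarray(list(sample), dtype=float)
    if x.size < 10:
        raise DegenerateDataError("need at least 10 observations to fit")
    rng_width = float(np.max(x) - np.min(x))
    if rng_width <= 0:
        raise DegenerateDataError("sample has no spread; cannot fit a distribution")

    frozen_cls = stats.weibull_min if family is Family.WEIBULL3P else stats.gamma
    eps = 1e-6 * rng_width
    gamma_hi = float(np.min(x)) - eps
    gamma_lo = float(np.min(x)) - 2.0 * rng_width

    def profile_nll(gamma: float) -> float:
        try:
            c, loc, sc = frozen_cls.fit(x, floc=gamma)
        except Exception:
            return np.inf
        ll = frozen_cls.logpdf(x, c, loc=loc, scale=sc).sum()
        return np.inf if not np.isfinite(ll) else -float(ll)

    res = optimize.minimize_scalar(
        profile_nll, bounds=(gamma_lo, gamma_hi), method="bounded",
        options={"xatol": 1e-3 * rng_width},
    )
    if not np.isfinite(res.fun):
        raise FitError(f"profile likelihood did not converge: {res}")
    gamma_hat = float(res.x)
    c, loc, sc = frozen_cls.fit(x, floc=gamma_hat)
    frozen = _scipy_frozen(family, c, sc, loc)
    ll = float(frozen.logpdf(x).sum())
    ks = stats.kstest(x, frozen.cdf)
    spec = DistributionSpec(family, shape=float(c), scale=float(sc), location=float(loc))
    return FitReport(
        spec=spec,
        log_likelihood=ll,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )
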