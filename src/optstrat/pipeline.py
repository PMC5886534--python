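"""End-to-end stratification runs: data in, boundary/allocation report out.

The chain mirrors how a survey designer would use the method:

1.  load a population table (CSV) or a fully parametric problem;
2.  max-scale every auxiliary variable (divide by its maximum) onto a
    common boundary domain;
3.  fit a 3P Weibull and/or Gamma to each scaled auxiliary (family
    "auto" keeps the higher log-likelihood fit) with a KS check;
4.  fit the polynomial regression of the study variable on the scaled
    auxiliaries;
5.  assemble the width program, solve it by DP with one refinement
    pass, allocate the sample by bounded Neyman allocation;
6.  rescale boundaries to the original scale and emit a JSON bundle
    plus CSV tables (rounding to 2 decimals happens only in the
    presentation columns).

All computation is deterministic for a fixed config and seed; the JSON
twin is written with sorted keys and no timestamps so identical runs
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from .allocation import allocate
from .distributions import DistributionSpec, Family, FitReport, fit_mle
from .exceptions import ConfigError, ParameterError
from .objective import Component, StratificationProblem
from .regression import RegressionModel, Term, fit as fit_regression, parse_term
from .simulate import PopulationSpec, generate_population
from .solver import refine, solve

__all__ = [
    "RunConfig",
    "scale_variables",
    "rescale_boundaries",
    "run",
    "write_bundle",
    "config_from_dict",
    "load_config",
]

log = logging.getLogger("optstrat")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """One stratification run.

    Exactly one of ``csv_path``, ``population``, ``problem`` must be
    set.  ``L`` may be an int or an inclusive (L_min, L_max) range; a
    range additionally produces the strata-count profile.
    """

    csv_path: str | None = None
    population: PopulationSpec | None = None
    problem: StratificationProblem | None = None
    response: str = "y"
    terms: tuple[str, ...] = ("x1",)
    families: Mapping[str, str] | str = "auto"
    y0: float | str = "auto"
    d: float | str = "auto"
    L: int | tuple[int, int] = 2
    n: int = 500
    N: int | None = None
    grid_step: float | None = None
    refine_factor: int = 10
    min_width: float | None = None
    error_mode: str = "unit"
    weight_variable: int = 1
    compare: bool = False
    compare_bins: int = 30
    external_objectives: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.csv_path, self.population, self.problem)]
        if sum(sources) != 1:
            raise ConfigError(
                "exactly one input source (csv_path, population, problem) is required"
            )
        if self.error_mode not in ("unit", "rse"):
            raise ConfigError(f"error_mode must be 'unit' or 'rse', got {self.error_mode!r}")
        Ls = self.L_values
        if min(Ls) < 1:
            raise ConfigError("L must be >= 1")
        if self.n < max(Ls):
            raise ConfigError(f"n = {self.n} cannot cover {max(Ls)} strata with one unit each")
        for t in self.terms:
            parse_term(t)

    @property
    def L_values(self) -> tuple[int, ...]:
        if isinstance(self.L, (tuple, list)):
            lo, hi = int(self.L[0]), int(self.L[1])
            if hi < lo:
                raise ConfigError(f"invalid L range {self.L}")
            return tuple(range(lo, hi + 1))
        return (int(self.L),)

    @property
    def is_range(self) -> bool:
        return isinstance(self.L, (tuple, list))


def _dist_to_dict(spec: DistributionSpec) -> dict[str, Any]:
    return {
        "family": spec.family.value,
        "shape": spec.shape,
        "scale": spec.scale,
        "location": spec.location,
    }


def _dist_from_dict(d: Mapping[str, Any]) -> DistributionSpec:
    return DistributionSpec(
        Family(d["family"]),
        shape=d.get("shape"),
        scale=d.get("scale"),
        location=d.get("location"),
    )


def _model_from_dict(d: Mapping[str, Any]) -> RegressionModel:
    terms = tuple(
        Term(var=int(t["var"]), power=int(t.get("power", 1)), coef=float(t["coef"]))
        for t in d["terms"]
    )
    return RegressionModel(
        intercept=float(d.get("intercept", 0.0)),
        terms=terms,
        error_scale=float(d.get("error_scale", 1.0)),
    )


def config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    """Build a RunConfig from a parsed YAML/JSON mapping."""
    d = dict(raw)
    if "population" in d and d["population"] is not None:
        p = d["population"]
        d["population"] = PopulationSpec(
            N=int(p["N"]),
            auxiliaries=tuple(_dist_from_dict(a) for a in p["auxiliaries"]),
            link=_model_from_dict(p["link"]),
            noise_sd=float(p["noise_sd"]),
            seed=int(p.get("seed", d.get("seed", 0))),
        )
    if "problem" in d and d["problem"] is not None:
        pr = d["problem"]
        comps = tuple(
            Component(dist=_dist_from_dict(c["dist"]), terms={int(k): float(v) for k, v in c["terms"].items()})
            for c in pr["components"]
        )
        d["problem"] = StratificationProblem(
            y0=float(pr["y0"]),
            d=float(pr["d"]),
            components=comps,
            error_scale=pr.get("error_scale", 1.0),
            grid_step=pr.get("grid_step"),
            min_width=pr.get("min_width"),
        )
    if "L" in d and isinstance(d["L"], (list, tuple)):
        d["L"] = (int(d["L"][0]), int(d["L"][1]))
    if "terms" in d:
        d["terms"] = tuple(d["terms"])
    if "external_objectives" in d and d["external_objectives"]:
        d["external_objectives"] = {
            m: {int(L): float(v) for L, v in vals.items()}
            for m, vals in d["external_objectives"].items()
        }
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**d)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def scale_variables(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Divide each column by its maximum; returns (scaled table, factors)."""
    cols = list(columns) if columns is not None else list(table.columns)
    scaled = table.copy()
    factors: dict[str, float] = {}
    for c in cols:
        mx = float(np.max(table[c]))
        if not mx > 0:
            raise ParameterError(f"column {c!r} has nonpositive maximum {mx}; cannot max-scale")
        scaled[c] = table[c] / mx
        factors[c] = mx
    return scaled, factors


def rescale_boundaries(boundaries: Sequence[float], factor: float) -> tuple[float, ...]:
    """Map scaled-domain boundaries back to the original scale."""
    return tuple(float(b) * factor for b in boundaries)


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _aux_columns(table: pd.DataFrame) -> list[str]:
    cols = sorted(
        (c for c in table.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not cols:
        raise ConfigError("table has no auxiliary columns named x1, x2, ...")
    return cols


def _fit_family(values: np.ndarray, family: str) -> FitReport:
    if family == "auto":
        fits = [fit_mle(values, Family.WEIBULL3P), fit_mle(values, Family.GAMMA3P)]
        best = max(fits, key=lambda f: f.log_likelihood)
        log.info(
            "auto family: weibull ll=%.2f, gamma ll=%.2f -> %s",
            fits[0].log_likelihood, fits[1].log_likelihood, best.spec.family.value,
        )
        return best
    return fit_mle(values, Family(family))


def _build_from_table(table: pd.DataFrame, config: RunConfig):
    aux_cols = _aux_columns(table)
    scaled, factors = scale_variables(table, aux_cols)
    fits: dict[str, FitReport] = {}
    for c in aux_cols:
        fam = config.families if isinstance(config.families, str) else config.families.get(c, "auto")
        fits[c] = _fit_family(np.asarray(scaled[c], dtype=float), fam)
        log.info("fitted %s: %s (KS D=%.4f, p=%.3f)", c, fits[c].spec, fits[c].ks_statistic, fits[c].ks_pvalue)

    has_response = config.response in table.columns
    model = None
    if has_response:
        model = fit_regression(scaled, config.response, config.terms, error_mode="rse")
    else:
        raise ConfigError(
            f"response column {config.response!r} absent: supply a parametric "
            "'problem' input (with known coefficients) instead of a CSV"
        )

    # boundary domain on the common scaled axis
    if config.y0 == "auto":
        obs_min = min(float(scaled[c].min()) for c in aux_cols)
        y0 = max(min(f.spec.location for f in fits.values()), obs_min)
        log.info("auto y0 = %.6g (default applied)", y0)
    else:
        y0 = float(config.y0)
    if config.d == "auto":
        obs_max = max(float(scaled[c].max()) for c in aux_cols)
        d = obs_max - y0
        log.info("auto d = %.6g (default applied)", d)
    else:
        d = float(config.d)

    term_keys = [parse_term(t) for t in config.terms]
    by_var: dict[int, dict[int, float]] = {}
    for (var, power), t in zip(term_keys, model.terms):
        by_var.setdefault(var, {})[power] = t.coef
    components = tuple(
        Component(dist=fits[f"x{var}"].spec, terms=powers)
        for var, powers in sorted(by_var.items())
    )
    error_scale = 1.0 if config.error_mode == "unit" else model.error_scale
    problem = StratificationProblem(
        y0=y0, d=d, components=components, error_scale=error_scale,
        grid_step=config.grid_step, min_width=config.min_width,
    )
    rescale = float(np.max(table[config.response])) if has_response else factors[f"x{config.weight_variable}"]
    return problem, fits, model, factors, rescale, scaled


def _solve_one(problem: StratificationProblem, config: RunConfig, L: int):
    prob = problem.with_L(L)
    res = solve(prob)
    if config.refine_factor > 1:
        res = refine(prob, res, config.refine_factor)
    return prob, res


def _allocation_block(prob, res, config: RunConfig, N: int):
    wv = config.weight_variable
    if not 1 <= wv <= len(prob.components):
        raise ConfigError(f"weight_variable x{wv} is not among the problem components")
    weights = [row[wv].weight for row in res.stratum_moments]
    total_w = sum(weights)
    if total_w <= 0:
        raise ConfigError(f"weight variable x{wv} carries no mass on the domain")
    weights = [w / total_w for w in weights]
    N_h = [max(int(round(N * w)), 1) for w in weights]
    alloc = allocate(res.stratum_objectives, config.n, N_h)
    return alloc, weights, N_h


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the full chain and return the (JSON-serializable) bundle."""
    bundle: dict[str, Any] = {"package": "optstrat", "seed": config.seed}

    table = None
    if config.csv_path is not None:
        table = pd.read_csv(config.csv_path)
        log.info("loaded %d rows from %s", len(table), config.csv_path)
    elif config.population is not None:
        table = generate_population(config.population)
        log.info("generated synthetic population of %d rows", len(table))

    if table is not None:
        problem, fits, model, factors, rescale, scaled = _build_from_table(table, config)
        N = config.N if config.N is not None else len(table)
        bundle["scale_factors"] = {k: float(v) for k, v in sorted(factors.items())}
        bundle["rescale_factor"] = rescale
        bundle["distribution_fits"] = {
            c: {
                **_dist_to_dict(f.spec),
                "log_likelihood": f.log_likelihood,
                "ks_statistic": f.ks_statistic,
                "ks_pvalue": f.ks_pvalue,
            }
            for c, f in sorted(fits.items())
        }
        m = model.metrics
        bundle["regression"] = {
            "intercept": model.intercept,
            "terms": [{"var": t.var, "power": t.power, "coef": t.coef} for t in model.terms],
            "error_scale": model.error_scale,
            "metrics": {
                "correlation": m.correlation,
                "rse": m.rse,
                "adj_r2": m.adj_r2,
                "aic": m.aic,
            },
        }
    else:
        problem = config.problem
        N = config.N if config.N is not None else 10_000
        rescale = 1.0
        scaled = None
        log.info("parametric problem input; boundaries reported on the given scale")

    bundle["problem"] = {
        "y0": problem.y0,
        "d": problem.d,
        "grid_step": problem.grid_step,
        "min_width": problem.min_width,
        "error_scale": problem.error_scale,
        "components": [
            {"dist": _dist_to_dict(c.dist), "terms": {str(k): v for k, v in c.terms.items()}}
            for c in problem.components
        ],
    }
    bundle["N"] = int(N)
    bundle["n"] = int(config.n)

    results: dict[str, Any] = {}
    totals: dict[int, float] = {}
    for L in config.L_values:
        prob, res = _solve_one(problem, config, L)
        alloc, weights, N_h = _allocation_block(prob, res, config, N)
        osb_orig = rescale_boundaries(res.boundaries, rescale)
        results[str(L)] = {
            "osb_scaled": list(res.boundaries),
            "osb_original": list(osb_orig),
            "osb_report": [round(b, 2) for b in osb_orig],
            "widths": list(res.widths),
            "stratum_objectives": list(res.stratum_objectives),
            "total_objective": res.total_objective,
            "stratum_weights": weights,
            "N_h": list(alloc.N_h),
            "n_h": list(alloc.n_h),
            "clamped": list(alloc.clamped),
            "warnings": list(res.warnings),
        }
        totals[L] = res.total_objective
        log.info("L=%d: objective %.6g, OSB %s", L, res.total_objective, results[str(L)]["osb_report"])
    bundle["results"] = results

    if config.is_range and len(config.L_values) >= 3:
        Ls = list(config.L_values)
        objs = [totals[L] for L in Ls]
        variances = [o * o / config.n for o in objs]
        prof = design_mod.StrataCountProfile(
            L=tuple(Ls), objective=tuple(objs), variance=tuple(variances), n=config.n
        )
        bundle["profile"] = {
            "L": Ls,
            "objective": objs,
            "variance": variances,
            "suggested_L_threshold": design_mod.suggest_elbow(prof, method="threshold"),
            "suggested_L_curvature": design_mod.suggest_elbow(prof, method="curvature"),
        }

    if config.compare:
        if scaled is None:
            raise ConfigError("comparison baselines need a data table input")
        bundle["comparison"] = _comparison_block(problem, config, scaled, totals, rescale)

    return bundle


def _comparison_block(problem, config, scaled, totals, rescale):
    """Score cum-sqrt-f and geometric baselines under the parametric objective."""
    col = config.response if config.response in scaled.columns else f"x{config.weight_variable}"
    values = np.asarray(scaled[col], dtype=float)
    if col == config.response:
        # the response is kept on its original scale for the regression;
        # bring it onto the common boundary axis for the baseline rules
        values = values / rescale
    lo, hi = problem.y0, problem.y0 + problem.d
    geo_a = max(lo, float(values.min()))
    out: dict[str, Any] = {"baseline_variable": col}
    for L in config.L_values:
        if L < 2:
            continue
        others = {
            "cum_sqrt_f": design_mod.cum_sqrt_f_boundaries(values, L, config.compare_bins),
        }
        if geo_a > 0:
            others["geometric"] = design_mod.geometric_boundaries(geo_a, hi, L)
        block = design_mod.compare_boundaries(problem, others, totals[L])
        for method, vals in config.external_objectives.items():
            if L in vals:
                block[method] = {
                    "objective": vals[L],
                    "efficiency_pct": design_mod.efficiency(vals[L], totals[L]),
                }
        block["dp"] = {"objective": totals[L], "efficiency_pct": 100.0}
        out[str(L)] = block
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bundle(bundle: Mapping[str, Any], outdir: str | Path) -> dict[str, Path]:
    """Write result.json plus the CSV tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["result.json"] = outdir / "result.json"
    paths["result.json"].write_text(json.dumps(bundle, sort_keys=True, indent=2) + "\n")

    rows = []
    for L_str, block in bundle.get("results", {}).items():
        L = int(L_str)
        osb = block["osb_report"] + [""]  # L-th row has no upper interior cut
        for h in range(L):
            rows.append(
                {
                    "L": L,
                    "stratum": h + 1,
                    "OSB": osb[h] if h < L - 1 else "",
                    "n_h": block["n_h"][h],
                    "N_h": block["N_h"][h],
                    "objective": block["total_objective"] if h == 0 else "",
                }
            )
    paths["result.csv"] = outdir / "result.csv"
    pd.DataFrame(rows).to_csv(paths["result.csv"], index=False)

    if "profile" in bundle:
        prof = bundle["profile"]
        paths["profile.csv"] = outdir / "profile.csv"
        pd.DataFrame(
            {"L": prof["L"], "objective": prof["objective"], "variance": prof["variance"]}
        ).to_csv(paths["profile.csv"], index=False)

    if "comparison" in bundle:
        comp_rows = []
        for L_str, block in bundle["comparison"].items():
            if not L_str.isdigit():
                continue
            for method, vals in block.items():
                comp_rows.append(
                    {
                        "L": int(L_str),
                        "method": method,
                        "objective": vals["objective"],
                        "efficiency_pct": vals["efficiency_pct"],
                    }
                )
        paths["comparison.csv"] = outdir / "comparison.csv"
        pd.DataFrame(comp_rows).sort_values(["L", "method"]).to_csv(
            paths["comparison.csv"], index=False
        )
    return paths
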