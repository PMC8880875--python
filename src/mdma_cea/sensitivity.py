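"""One-way (tornado), probabilistic (Monte Carlo) and scenario sensitivity analyses.

Parameter uncertainty follows the distribution families of the published
input table: beta for the intervention-cost total, utilities and the
discount rate; gamma for the per-state medical costs; lognormal for the
mortality relative risks; normal for the cohort mean age; uniform for the
progression risk (scenario analyses only).  Every family is moment-matched
to the printed central value and dispersion.

Dispersion conventions: where only a +/- range is printed (intervention
cost +/-30%, utilities +/-10%) the range is read as a 90% interval, so the
matching SD is ``half_range / 1.645``; conversely, deterministic low/high
bounds for parameters printed with an SD default to ``central +/- 1.645*SD``.
Draws are mutually independent (no correlation structure is published).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .outcomes import CEResult, evaluate
from .params import (
    STATES,
    ModelParams,
    MortalityRR,
    StateAnnualCost,
    UtilitySet,
    ValidationError,
)

log = logging.getLogger(__name__)

Z90 = 1.645  # two-sided 90% normal quantile: printed ranges <-> SDs

FAMILIES = ("beta", "gamma", "lognormal", "normal", "uniform", "fixed")


@dataclass(frozen=True)
class ParamSpec:
    """Uncertainty specification for one scalar model input.

    ``dispersion`` is an SD in the parameter's units; ``low``/``high`` are
    the deterministic one-way bounds.  For a beta family on a scaled
    interval, ``support`` gives the interval (defaults to [0, 1]).
    """

    name: str
    central: float
    family: str
    dispersion: float = 0.0
    low: float | None = None
    high: float | None = None
    support: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError([f"{self.name}: unknown distribution family {self.family!r}"])

    def bounds(self) -> tuple[float, float]:
        if self.low is not None and self.high is not None:
            return self.low, self.high
        half = Z90 * self.dispersion
        return self.central - half, self.central + half


def build_param_specs(params: ModelParams) -> list[ParamSpec]:
    """The published uncertainty set: one spec per uncertain scalar input."""
    specs: list[ParamSpec] = []
    iv = params.intervention
    half = iv.relative_range * iv.total
    specs.append(
        ParamSpec(
            "intervention_total",
            iv.total,
            "beta",
            dispersion=half / Z90,
            low=iv.total - half,
            high=iv.total + half,
            support=(iv.total - half, iv.total + half),
        )
    )
    for i, s in enumerate(STATES):
        specs.append(
            ParamSpec(f"cost_{s}", float(params.costs.mean[i]), "gamma", float(params.costs.sd[i]))
        )
    for i, s in enumerate(STATES):
        if i == 0:
            continue  # asymptomatic RR fixed at 1.0
        specs.append(
            ParamSpec(f"rr_{s}", float(params.rr.mean[i]), "lognormal", float(params.rr.sd[i]))
        )
    for i, s in enumerate(STATES):
        u = float(params.utilities.values[i])
        half_u = params.utilities.relative_range * u
        specs.append(
            ParamSpec(
                f"utility_{s}", u, "beta", dispersion=half_u / Z90, low=u - half_u, high=u + half_u
            )
        )
    specs.append(
        ParamSpec(
            "mean_age",
            params.mean_age,
            "normal",
            params.age_sd,
            support=(18.0, 90.0),
        )
    )
    specs.append(
        ParamSpec("discount_rate", params.discount_rate, "beta", params.discount_rate_sd)
    )
    return specs


def _draw(spec: ParamSpec, rng: np.random.Generator) -> float:
    """One moment-matched draw from ``spec``'s family."""
    m, s = spec.central, spec.dispersion
    if spec.family == "fixed" or s == 0:
        return m
    if spec.family == "gamma":
        if m <= 0:
            raise ValidationError([f"{spec.name}: gamma requires a positive mean"])
        shape = m * m / (s * s)
        scale = s * s / m
        return float(rng.gamma(shape, scale))
    if spec.family == "lognormal":
        if m <= 0:
            raise ValidationError([f"{spec.name}: lognormal requires a positive mean"])
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    if spec.family == "normal":
        lo, hi = spec.support
        for _ in range(1000):  # truncation is far in the tail; rejection is cheap
            x = rng.normal(m, s)
            if lo <= x <= hi:
                return float(x)
        raise ValidationError([f"{spec.name}: truncated-normal rejection failed"])
    if spec.family == "uniform":
        lo, hi = spec.bounds()
        return float(rng.uniform(lo, hi))
    # beta, moment-matched on its support interval
    lo, hi = spec.support
    width = hi - lo
    if width <= 0:
        raise ValidationError([f"{spec.name}: beta support has non-positive width"])
    mu = (m - lo) / width
    var = (s / width) ** 2
    if not (0 < mu < 1) or var >= mu * (1 - mu):
        raise ValidationError(
            [f"{spec.name}: beta moment matching infeasible (mean {m}, sd {s} on [{lo}, {hi}])"]
        )
    nu = mu * (1 - mu) / var - 1
    return lo + width * float(rng.beta(mu * nu, (1 - mu) * nu))


def _apply_draws(base: ModelParams, draws: dict[str, float]) -> ModelParams:
    """Build a parameter set from ``base`` with the drawn values substituted.

    Sampled draws are checked for domain validity (positivity, ranges) but
    not for cross-state ordering: independent draws from the published
    per-state distributions routinely overlap, and enforcing monotonicity
    would truncate the sampled marginals.
    """
    costs = base.costs.mean.copy()
    rr = base.rr.mean.copy()
    util = base.utilities.values.copy()
    changes: dict = {}
    for name, val in draws.items():
        if name == "intervention_total":
            factor = val / base.intervention.total
            changes["intervention"] = replace(
                base.intervention,
                therapists=base.intervention.therapists * factor,
                screening_lab=base.intervention.screening_lab * factor,
                tests_pharmacy=base.intervention.tests_pharmacy * factor,
            )
        elif name.startswith("cost_"):
            costs[STATES.index(name[5:])] = val
        elif name.startswith("rr_"):
            rr[STATES.index(name[3:])] = val
        elif name.startswith("utility_"):
            util[STATES.index(name[8:])] = val
        elif name == "mean_age":
            changes["mean_age"] = val
        elif name == "discount_rate":
            changes["discount_rate"] = val
        elif name == "progression_rate":
            changes["progression_rate"] = val
        else:
            raise ValidationError([f"unknown sampled parameter {name!r}"])
    changes["costs"] = StateAnnualCost(mean=costs, sd=base.costs.sd)
    changes["rr"] = MortalityRR(mean=rr, sd=base.rr.sd)
    changes["utilities"] = UtilitySet(values=util, relative_range=base.utilities.relative_range)
    out = base.replace(**changes)
    probs = (
        out.costs.problems(strict_order=False)
        + out.rr.problems(strict_order=False)
        + out.utilities.problems(strict_order=False)
    )
    if not (0 <= out.discount_rate < 1):
        probs.append("sampled discount rate outside [0, 1)")
    if probs:
        raise ValidationError(probs)
    return out


def sample_params(
    specs: list[ParamSpec],
    rng_seed: int | np.random.Generator,
    base: ModelParams,
) -> ModelParams:
    """One joint parameter draw, deterministic given the seed."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    draws = {spec.name: _draw(spec, rng) for spec in specs}
    return _apply_draws(base, draws)


@dataclass(frozen=True)
class PsaSummary:
    """Distributional summary of a probabilistic sensitivity analysis.

    Percentiles are the empirical 5th/95th: a 90% uncertainty interval.
    """

    n_iter: int
    seed: int
    net_cost_mean: float
    net_cost_p5: float
    net_cost_p95: float
    qalys_gained_mean: float
    qalys_gained_p5: float
    qalys_gained_p95: float
    deaths_averted_mean: float
    n_redraws: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PsaResult:
    summary: PsaSummary
    draws: pd.DataFrame = field(repr=False)


def run_psa(
    params: ModelParams,
    specs: list[ParamSpec] | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    horizon: int | None = None,
    scenario_progression: tuple[float, float] | None = None,
) -> PsaResult:
    """Monte Carlo over the joint input distributions.

    Per iteration: draw a parameter set, run both arms, record net cost,
    QALYs gained and deaths averted at ``horizon``.  With
    ``scenario_progression=(low, high)`` the annual progression risk of the
    treated arm (applied after the progression start year) is additionally
    drawn from a uniform distribution on that interval.  Iterations whose
    draws fail domain validation are re-drawn (counted; a rate above 1%
    logs a warning).  Fully reproducible given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    h = params.horizon if horizon is None else int(horizon)
    if specs is None:
        specs = build_param_specs(params)
    if scenario_progression is not None:
        lo, hi = scenario_progression
        specs = specs + [
            ParamSpec("progression_rate", (lo + hi) / 2, "uniform", low=lo, high=hi)
        ]
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    n_redraws = 0
    for _ in range(n_iter):
        for _attempt in range(100):
            try:
                draws = {spec.name: _draw(spec, rng) for spec in specs}
                p = _apply_draws(params, draws)
                break
            except ValidationError:
                n_redraws += 1
        else:
            raise ValidationError(["PSA iteration failed validation 100 times in a row"])
        prog = draws.get("progression_rate", 0.0)
        res = evaluate(p, h, progression_rate=prog)
        rec = dict(draws)
        rec["net_cost"] = res.net_cost
        rec["qalys_gained"] = res.qalys_gained
        rec["deaths_averted"] = res.deaths_averted
        records.append(rec)
    if n_redraws > 0.01 * n_iter:
        log.warning("PSA re-drew %d parameter sets over %d iterations", n_redraws, n_iter)
    df = pd.DataFrame.from_records(records)
    nc, qg = df["net_cost"].to_numpy(), df["qalys_gained"].to_numpy()
    summary = PsaSummary(
        n_iter=n_iter,
        seed=seed,
        net_cost_mean=float(nc.mean()),
        net_cost_p5=float(np.percentile(nc, 5)),
        net_cost_p95=float(np.percentile(nc, 95)),
        qalys_gained_mean=float(qg.mean()),
        qalys_gained_p5=float(np.percentile(qg, 5)),
        qalys_gained_p95=float(np.percentile(qg, 95)),
        deaths_averted_mean=float(df["deaths_averted"].mean()),
        n_redraws=n_redraws,
    )
    return PsaResult(summary=summary, draws=df)


def one_way_tornado(
    params: ModelParams,
    specs: list[ParamSpec] | None = None,
    horizon: int | None = None,
    metric: str = "net_cost",
) -> pd.DataFrame:
    """Deterministic one-way sensitivity analysis.

    Each parameter is set to its low and high bound in isolation, all others
    held central, and the chosen outcome (default: net cost, the published
    tornado's axis) is re-evaluated.  Returns a table sorted by swing,
    largest first.
    """
    if metric not in ("net_cost", "qalys_gained", "deaths_averted"):
        raise ValueError(f"unknown tornado metric {metric!r}")
    h = params.horizon if horizon is None else int(horizon)
    if specs is None:
        specs = build_param_specs(params)
    base_val = getattr(evaluate(params, h), metric)
    rows = []
    for spec in specs:
        lo, hi = spec.bounds()
        out_lo = getattr(evaluate(_apply_draws(params, {spec.name: lo}), h), metric)
        out_hi = getattr(evaluate(_apply_draws(params, {spec.name: hi}), h), metric)
        rows.append(
            {
                "parameter": spec.name,
                "low": lo,
                "high": hi,
                "output_at_low": out_lo,
                "output_at_high": out_hi,
                "output_at_central": base_val,
                "swing": abs(out_hi - out_lo),
            }
        )
    df = pd.DataFrame(rows).sort_values("swing", ascending=False, ignore_index=True)
    return df


def progression_scenario(
    params: ModelParams, rate: float, horizon: int | None = None
) -> CEResult:
    """Scenario: treated-arm patients relapse toward more severe disease.

    After the progression start year, ``rate`` of each treated-arm state
    moves to the next-more-severe state every cycle; the control arm is
    unchanged (its members already occupy the baseline severities).
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"progression rate must lie in [0, 1], got {rate}")
    return evaluate(params, horizon, progression_rate=rate)
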