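"""Cost-effectiveness outcomes from paired arm traces.

Sign convention: ``net_cost = cost_treated - cost_control``; a negative net
cost is a saving to the payer.  QALYs and costs are discounted; deaths
averted are undiscounted.  When the treated arm is both cheaper and more
effective it *dominates* and no cost-effectiveness ratio is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from scipy.optimize import brentq

from .engine import CohortTrace, control_arm, mdma_arm, run_cohort
from .params import ModelParams, StateAnnualCost

#: Dominance flags returned in place of a numeric ICER.
DOMINANT = "dominant"  # treated arm cheaper and more effective
DOMINATED = "dominated"  # treated arm costlier and less effective


class ComparisonError(ValueError):
    """Arm traces are not comparable (cohort size or horizon mismatch)."""


def icer(net_cost: float, qalys_gained: float) -> float | str | None:
    """Incremental cost-effectiveness ratio, or a dominance flag.

    Returns ``net_cost / qalys_gained`` when the comparison is a genuine
    trade-off (both increments of the same sign), ``DOMINANT`` when the
    treated arm saves money while gaining QALYs, ``DOMINATED`` in the
    opposite corner, and ``None`` (undefined) when no QALYs are gained or
    lost but costs differ.
    """
    if qalys_gained == 0:
        return None if net_cost != 0 else 0.0
    if net_cost < 0 < qalys_gained:
        return DOMINANT
    if qalys_gained < 0 < net_cost:
        return DOMINATED
    return net_cost / qalys_gained


@dataclass(frozen=True)
class CEResult:
    """Paired-arm cost-effectiveness summary at one analytic horizon."""

    horizon: float
    cohort_size: float
    cost_mdma: float
    cost_control: float
    qalys_mdma: float
    qalys_control: float
    deaths_mdma: float
    deaths_control: float

    @property
    def net_cost(self) -> float:
        return self.cost_mdma - self.cost_control

    @property
    def qalys_gained(self) -> float:
        return self.qalys_mdma - self.qalys_control

    @property
    def deaths_averted(self) -> float:
        return self.deaths_control - self.deaths_mdma

    @property
    def icer(self) -> float | str | None:
        return icer(self.net_cost, self.qalys_gained)

    def to_dict(self) -> dict:
        out = asdict(self)
        out.update(
            net_cost=self.net_cost,
            qalys_gained=self.qalys_gained,
            deaths_averted=self.deaths_averted,
            icer=self.icer,
        )
        return out


def compare_arms(
    trace_mdma: CohortTrace, trace_control: CohortTrace, horizon: int | None = None
) -> CEResult:
    """Summarize two traces through ``horizon`` cycles.

    Costs include the treated arm's one-time intervention cost; deaths
    averted are the undiscounted difference in cumulative deaths.
    """
    if abs(trace_mdma.cohort_size - trace_control.cohort_size) > 1e-9:
        raise ComparisonError(
            f"cohort sizes differ: {trace_mdma.cohort_size} vs {trace_control.cohort_size}"
        )
    h = min(trace_mdma.horizon, trace_control.horizon) if horizon is None else int(horizon)
    if h > min(trace_mdma.horizon, trace_control.horizon):
        raise ComparisonError(f"traces do not cover horizon {h}")
    return CEResult(
        horizon=h,
        cohort_size=trace_mdma.cohort_size,
        cost_mdma=trace_mdma.total_cost(h),
        cost_control=trace_control.total_cost(h),
        qalys_mdma=trace_mdma.total_qalys(h),
        qalys_control=trace_control.total_qalys(h),
        deaths_mdma=trace_mdma.total_deaths(h),
        deaths_control=trace_control.total_deaths(h),
    )


def evaluate(
    params: ModelParams,
    horizon: int | None = None,
    *,
    progression_rate: float = 0.0,
    disable_cost_offset: bool = False,
    accrual: str = "survivor",
) -> CEResult:
    """Run both arms under ``params`` and compare them. Convenience wrapper."""
    h = params.horizon if horizon is None else int(horizon)
    tm = run_cohort(
        params,
        mdma_arm(params),
        horizon=h,
        progression_rate=progression_rate,
        disable_cost_offset=disable_cost_offset,
        accrual=accrual,
    )
    tc = run_cohort(params, control_arm(params), horizon=h, accrual=accrual)
    return compare_arms(tm, tc, h)


def break_even_time(
    trace_mdma: CohortTrace, trace_control: CohortTrace, max_horizon: int | None = None
) -> float:
    """First continuous time at which cumulative net cost crosses zero.

    Linear interpolation within the bracketing cycle of the cumulative
    discounted net-cost path (intervention cost charged at time 0).  Returns
    0.0 when the net cost is already non-positive at time 0 and ``math.inf``
    when it never crosses within ``max_horizon``.
    """
    h = min(trace_mdma.horizon, trace_control.horizon) if max_horizon is None else int(max_horizon)
    if h > min(trace_mdma.horizon, trace_control.horizon):
        raise ComparisonError(f"traces do not cover horizon {h}")
    net0 = trace_mdma.intervention_cost - trace_control.intervention_cost
    if net0 <= 0:
        return 0.0
    net = (trace_mdma.cumulative_cost() - trace_control.cumulative_cost())[:h]
    prev = net0
    for t in range(1, h + 1):
        cur = net[t - 1]
        if cur <= 0:
            return (t - 1) + prev / (prev - cur)
        prev = cur
    return math.inf


def cost_scale_threshold(
    params: ModelParams,
    horizon: int | None = None,
    mode: str = "added",
    xtol: float = 1e-4,
) -> float | None:
    """Fraction of base-case medical costs at which net savings vanish.

    Scales the per-state annual medical cost by ``k`` and solves for the
    ``k*`` in (0, 1) where the net cost at ``horizon`` is zero.  With
    ``mode="added"`` (default) only the increment above the asymptomatic
    cost is scaled — the added spending attributable to PTSD; with
    ``mode="all"`` every state's full cost is scaled.  Returns ``None`` when
    net cost does not change sign on [0, 1].
    """
    if mode not in ("added", "all"):
        raise ValueError(f"mode must be 'added' or 'all', got {mode!r}")
    h = params.horizon if horizon is None else int(horizon)
    base = params.costs.mean

    def net_at(k: float) -> float:
        if mode == "added":
            scaled = base[0] + k * (base - base[0])
        else:
            scaled = k * base
        # scaled costs may be flat or zero (k=0): bypass strict-order validation
        p = params.replace(costs=StateAnnualCost(mean=scaled, sd=params.costs.sd))
        return evaluate(p, h).net_cost

    lo, hi = net_at(0.0), net_at(1.0)
    if lo == 0.0:
        return 0.0
    if lo * hi > 0:
        return None
    return float(brentq(net_at, 0.0, 1.0, xtol=xtol))


def gains_at_time(
    trace_mdma: CohortTrace, trace_control: CohortTrace, time: float
) -> tuple[float, float]:
    """(QALYs gained, deaths averted) at a fractional time, by linear interpolation.

    Used to report health benefits accrued at the (generally fractional)
    break-even time.
    """
    import numpy as np

    if time < 0:
        raise ValueError("time must be non-negative")
    cq = np.concatenate([[0.0], np.cumsum(trace_mdma.qalys_disc - trace_control.qalys_disc)])
    cd = np.concatenate([[0.0], np.cumsum(trace_control.deaths - trace_mdma.deaths)])
    grid = np.arange(cq.size, dtype=float)
    return float(np.interp(time, grid, cq)), float(np.interp(time, grid, cd))


def no_savings_icer(params: ModelParams, horizon: int | None = None) -> float | str | None:
    """ICER under the hypothetical that therapy never reduces medical spending.

    In that pessimistic scenario the payer's net cost is exactly the one-time
    intervention cost, so the ratio is the total intervention outlay divided
    by the QALYs gained at ``horizon``.
    """
    res = evaluate(params, horizon)
    return icer(params.intervention.total * params.cohort_size, res.qalys_gained)


# --- regimen comparison ---------------------------------------------------


@dataclass(frozen=True)
class RegimenResult:
    """Minimal arm-vs-standard-care summary used for regimen comparisons."""

    horizon: float
    qalys_gained: float
    net_cost: float
    cohort_size: float = 1000.0


#: Published two-session (phase-2 protocol) regimen summaries vs standard
#: care for a 1,000-patient cohort, re-costed and re-weighted with the
#: phase-3 utilities and prices so the two regimens are comparable.  These
#: are consumed as printed inputs: the two-session efficacy distribution is
#: not re-simulated here.
PHASE2_RESULTS: dict[int, RegimenResult] = {
    1: RegimenResult(1, 218.0, 9_866_694.0),
    5: RegimenResult(5, 1_030.0, -6_634_409.0),
    10: RegimenResult(10, 1_915.0, -34_848_804.0),
    30: RegimenResult(30, 4_248.0, -100_866_525.0),
}


@dataclass(frozen=True)
class RegimenComparison:
    """Incremental comparison of regimen B over regimen A."""

    horizon: float
    qalys_gained: float
    net_cost: float

    @property
    def icer(self) -> float | str | None:
        return icer(self.net_cost, self.qalys_gained)


def regimen_comparison(res_a, res_b) -> RegimenComparison:
    """Incremental QALYs, cost and ICER of regimen ``b`` over regimen ``a``.

    Accepts any objects exposing ``horizon``, ``cohort_size``,
    ``qalys_gained`` and ``net_cost`` (``CEResult`` or ``RegimenResult``).
    """
    if res_a.horizon != res_b.horizon:
        raise ComparisonError(f"horizon mismatch: {res_a.horizon} vs {res_b.horizon}")
    if abs(res_a.cohort_size - res_b.cohort_size) > 1e-9:
        raise ComparisonError(
            f"cohort size mismatch: {res_a.cohort_size} vs {res_b.cohort_size}"
        )
    return RegimenComparison(
        horizon=res_a.horizon,
        qalys_gained=res_b.qalys_gained - res_a.qalys_gained,
        net_cost=res_b.net_cost - res_a.net_cost,
    )
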