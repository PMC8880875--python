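"""Annual-cycle Markov cohort engine for one treatment arm.

Cohort members occupy one of five PTSD severity states.  In the base case
there are no transitions among living states: the treatment effect is the
difference between the intake and follow-up severity mixes, each arm holding
its achieved mix for the whole horizon.  Each cycle, members die with
probability ``min(1, RR(state) * qx(age))`` where ``qx`` is the background
life-table death probability at the member's current age.

Age heterogeneity: the cohort is split into 1-year age strata from a normal
age distribution (base case: mean 41, SD 11.9, truncated to [18, 90] and
renormalised); each stratum ages along its own life-table path.  Because
``qx`` is convex in age, the stratified cohort has higher year-1 mortality
than a single stratum at the mean age.

Cycle accounting (default ``accrual="survivor"``): deaths occur at cycle
end; costs and QALYs accrue to the members who survive the cycle and are
discounted with end-of-cycle factors ``1/(1+r)^t``.  The alternative
``accrual="entrant"`` convention credits everyone alive at cycle start.
There is no half-cycle correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .params import (
    N_STATES,
    STATES,
    LifeTable,
    ModelParams,
    SeverityDistribution,
    SeverityState,
    ValidationError,
)

log = logging.getLogger(__name__)

ACCRUAL_CONVENTIONS = ("survivor", "entrant")


def discount_factor(t: int, r: float) -> float:
    """End-of-cycle discount factor ``1/(1+r)**t`` for cycle ``t`` (1-based)."""
    if t < 1:
        raise ValueError(f"cycle index must be >= 1, got {t}")
    if r < 0:
        raise ValueError(f"discount rate must be non-negative, got {r}")
    return (1.0 + r) ** -t


def death_probability(state, age: float, rr, lt: LifeTable) -> float:
    """Annual death probability for one state at one age: ``min(1, RR * qx)``.

    ``state`` may be a ``SeverityState`` or state label; ages outside the
    life-table range clamp to the nearest tabulated row.
    """
    if isinstance(state, str):
        state = SeverityState(STATES.index(state))
    rr_val = rr.mean[int(state)] if hasattr(rr, "mean") else float(np.asarray(rr)[int(state)])
    return float(min(1.0, rr_val * lt.qx_at(age)))


@dataclass(frozen=True)
class AgeStructure:
    """Cohort age strata: integer-spaced start ages with normalized weights."""

    start_ages: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_normal(
        cls, mean: float, sd: float, lo: float = 18.0, hi: float = 90.0
    ) -> "AgeStructure":
        """Discretize a normal age distribution into 1-year strata on [lo, hi].

        The grid is anchored at integer ages for the reference mean of 41 and
        shifts rigidly with ``mean`` so that a sampled mean age moves every
        stratum by the same offset.
        """
        if sd < 0:
            raise ValueError("age SD must be non-negative")
        offset = mean - 41.0
        grid = np.arange(int(lo), int(hi) + 1, dtype=float)
        if sd == 0:
            return cls(np.array([mean]), np.array([1.0]))
        w = norm.pdf(grid, 41.0, sd)
        w = w / w.sum()
        return cls(grid + offset, w)


@dataclass(frozen=True)
class ArmSpec:
    """One arm of the comparison.

    The control arm's achieved severity mix is the intake distribution
    (standard care leaves patients in their baseline category); the treated
    arm's is the trial's primary-endpoint follow-up distribution and it pays
    the one-time intervention cost.
    """

    label: str
    achieved: SeverityDistribution
    pays_intervention: bool


def mdma_arm(params: ModelParams) -> ArmSpec:
    return ArmSpec("mdma", params.followup, True)


def control_arm(params: ModelParams) -> ArmSpec:
    return ArmSpec("control", params.intake, False)


def savings_delta(params: ModelParams) -> float:
    """Per-capita achievable annual cost reduction.

    The baseline difference between the intake-mix and follow-up-mix
    per-capita annual costs; the intake-to-follow-up mapping of individuals
    is not observed, so the offset is applied at arm level.
    """
    return params.intake.per_capita(params.costs.mean) - params.followup.per_capita(
        params.costs.mean
    )


def annual_medical_cost(
    arm: ArmSpec,
    t: int,
    params: ModelParams,
    occupancy: SeverityDistribution | np.ndarray,
) -> float:
    """Undiscounted medical cost accrued by ``occupancy`` in model year ``t``.

    Control arm: state costs weighted by occupancy.  Treated arm: occupancy
    costs plus, for every living member, the fraction of the achievable
    per-capita saving that the cost-offset ramp has not yet released,
    ``(1 - ramp(t)) * delta``.
    """
    if t < 1:
        raise ValueError(f"cycle index must be >= 1, got {t}")
    counts = occupancy.counts if isinstance(occupancy, SeverityDistribution) else np.asarray(occupancy)
    base = float(counts @ params.costs.mean)
    if not arm.pays_intervention:
        return base
    frac = params.ramp_at(t)
    if not (0.0 <= frac <= 1.0):
        raise ValidationError([f"ramp fraction at year {t} is {frac}, outside [0, 1]"])
    return base + float(counts.sum()) * (1.0 - frac) * savings_delta(params)


def apply_progression(
    occupancy: SeverityDistribution | np.ndarray, rate: float
) -> SeverityDistribution | np.ndarray:
    """Move ``rate`` of each state's occupancy to the next-more-severe state.

    The most severe state has no worse neighbour and retains its mass; total
    mass is conserved.  Accepts a distribution or a bare array (possibly 2-D
    with states on the last axis) and returns the same kind.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"progression rate must lie in [0, 1], got {rate}")
    wrapped = isinstance(occupancy, SeverityDistribution)
    counts = occupancy.counts if wrapped else np.asarray(occupancy, dtype=float)
    out = counts.astype(float).copy()
    moved = out[..., :-1] * rate
    out[..., :-1] -= moved
    out[..., 1:] += moved
    return SeverityDistribution(out) if wrapped else out


@dataclass
class CohortTrace:
    """Per-cycle record of one arm's cohort.

    Arrays are indexed by cycle ``t = 1..horizon`` (python index ``t-1``).
    ``occupancy`` is end-of-cycle living occupancy per state; ``deaths`` are
    undiscounted deaths within the cycle; costs and QALYs are discounted.
    The one-time intervention cost is charged undiscounted at year 0.
    """

    label: str
    cohort_size: float
    horizon: int
    occupancy: np.ndarray  # (horizon, 5)
    deaths: np.ndarray  # (horizon,)
    med_cost_disc: np.ndarray  # (horizon,)
    qalys_disc: np.ndarray  # (horizon,)
    intervention_cost: float = 0.0
    accrual: str = "survivor"

    def _check_horizon(self, horizon: int | None) -> int:
        h = self.horizon if horizon is None else int(horizon)
        if not (1 <= h <= self.horizon):
            raise ValueError(f"horizon {h} not covered by trace of length {self.horizon}")
        return h

    def total_cost(self, horizon: int | None = None) -> float:
        """Discounted medical cost plus the year-0 intervention cost."""
        h = self._check_horizon(horizon)
        return self.intervention_cost + float(self.med_cost_disc[:h].sum())

    def total_qalys(self, horizon: int | None = None) -> float:
        h = self._check_horizon(horizon)
        return float(self.qalys_disc[:h].sum())

    def total_deaths(self, horizon: int | None = None) -> float:
        h = self._check_horizon(horizon)
        return float(self.deaths[:h].sum())

    def cumulative_cost(self) -> np.ndarray:
        """Cumulative discounted cost by cycle, intervention charged up front."""
        return self.intervention_cost + np.cumsum(self.med_cost_disc)

    def living(self, t: int) -> float:
        """Living occupancy at the end of cycle ``t``."""
        return float(self.occupancy[t - 1].sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle/per-state table (cycle, state, occupancy, deaths, cost, qalys).

        Deaths, costs and QALYs are cycle totals repeated within the cycle's
        state rows only for occupancy; scalar cycle quantities appear on the
        asymptomatic row to keep the table tidy-long without double counting.
        """
        rows = []
        for t in range(1, self.horizon + 1):
            for s, name in enumerate(STATES):
                rows.append(
                    {
                        "cycle": t,
                        "state": name,
                        "occupancy": self.occupancy[t - 1, s],
                        "deaths": self.deaths[t - 1] if s == 0 else 0.0,
                        "med_cost_disc": self.med_cost_disc[t - 1] if s == 0 else 0.0,
                        "qalys_disc": self.qalys_disc[t - 1] if s == 0 else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "arm": self.label,
            "horizon": self.horizon,
            "intervention_cost": self.intervention_cost,
            "total_cost": self.total_cost(),
            "total_qalys": self.total_qalys(),
            "total_deaths": self.total_deaths(),
        }


_warned_clamp = False


def run_cohort(
    params: ModelParams,
    arm: ArmSpec,
    *,
    horizon: int | None = None,
    progression_rate: float = 0.0,
    disable_cost_offset: bool = False,
    accrual: str = "survivor",
) -> CohortTrace:
    """Advance one arm's cohort over annual cycles and accrue outcomes.

    For each age stratum the occupancy of every severity state is decremented
    by state- and age-specific mortality each cycle; strata are aggregated by
    weight.  QALYs are utility-weighted person-years; medical costs follow
    ``annual_medical_cost``; the treated arm is charged the per-patient
    intervention cost times the cohort size, undiscounted, at year 0.

    ``progression_rate`` (scenario analyses) shifts that fraction of each
    living state to the next-more-severe state at the start of every cycle
    after ``params.progression_start``.  ``disable_cost_offset`` holds the
    treated arm's medical costs at the intake mix (the hypothetical in which
    the therapy never reduces spending).
    """
    global _warned_clamp
    h = params.horizon if horizon is None else int(horizon)
    if h < 1:
        raise ValueError(f"horizon must be >= 1, got {h}")
    if accrual not in ACCRUAL_CONVENTIONS:
        raise ValueError(f"accrual must be one of {ACCRUAL_CONVENTIONS}, got {accrual!r}")
    if params.life_table is None:
        raise ValidationError(["model parameters carry no life table"])
    lt = params.life_table

    ages = AgeStructure.from_normal(params.mean_age, params.age_sd)
    start = ages.start_ages
    if start.max() + h - 1 > lt.ages.max() and not _warned_clamp:
        log.warning(
            "life table ends at age %.0f; older strata clamp qx at the final row",
            lt.ages.max(),
        )
        _warned_clamp = True

    scale = params.cohort_size / arm.achieved.total
    occ = np.outer(ages.weights, arm.achieved.counts) * scale  # (strata, states)

    rr = params.rr.mean
    util = params.utilities.values
    cost_mean = params.costs.mean
    delta = 0.0 if disable_cost_offset else savings_delta(params)
    intake_pc = params.intake.per_capita(cost_mean)

    occupancy = np.empty((h, N_STATES))
    deaths = np.empty(h)
    med_cost = np.empty(h)
    qalys = np.empty(h)

    for t in range(1, h + 1):
        if progression_rate > 0 and t > params.progression_start:
            occ = apply_progression(occ, progression_rate)
        age_t = start + (t - 1)
        p = np.minimum(1.0, np.outer(lt.qx_at(age_t), np.ones(N_STATES)) * rr)
        died = occ * p
        surv = occ - died
        basis = occ if accrual == "entrant" else surv
        disc = discount_factor(t, params.discount_rate)
        state_counts = basis.sum(axis=0)
        if arm.pays_intervention:
            if disable_cost_offset:
                cost_t = state_counts.sum() * intake_pc
            else:
                frac = params.ramp_at(t)
                cost_t = float(state_counts @ cost_mean) + state_counts.sum() * (1 - frac) * delta
        else:
            cost_t = float(state_counts @ cost_mean)
        med_cost[t - 1] = cost_t * disc
        qalys[t - 1] = float(state_counts @ util) * disc
        deaths[t - 1] = died.sum()
        occupancy[t - 1] = surv.sum(axis=0)
        occ = surv

    trace = CohortTrace(
        label=arm.label,
        cohort_size=params.cohort_size,
        horizon=h,
        occupancy=occupancy,
        deaths=deaths,
        med_cost_disc=med_cost,
        qalys_disc=qalys,
        intervention_cost=(
            params.intervention.total * params.cohort_size if arm.pays_intervention else 0.0
        ),
        accrual=accrual,
    )
    _assert_conservation(trace)
    return trace


def _assert_conservation(trace: CohortTrace) -> None:
    """Living + cumulative dead must equal the cohort size every cycle."""
    living = trace.occupancy.sum(axis=1)
    cum_dead = np.cumsum(trace.deaths)
    err = np.abs(living + cum_dead - trace.cohort_size) / trace.cohort_size
    worst = float(err.max())
    if worst > 1e-9:
        raise AssertionError(f"cohort mass not conserved (max relative error {worst:g})")
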