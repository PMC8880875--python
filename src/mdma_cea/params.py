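"""Model parameters: domain types, validation, and configuration I/O.

The whole analysis is driven by a single flat, human-editable YAML
configuration (one key set, versioned with ``schema_version``); the bundled
defaults are the base case of the published phase-3 economic evaluation.
Severity-state quantities are stored as length-5 numpy arrays ordered from
asymptomatic to extreme; severity counts are real numbers (expected
occupancy of a deterministic cohort model), not integers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical severity-state labels, ordered from least to most severe.
STATES: tuple[str, ...] = ("asymptomatic", "mild", "moderate", "severe", "extreme")

N_STATES = len(STATES)

SCHEMA_VERSION = 1


class SeverityState(enum.IntEnum):
    """PTSD severity categories; the integer order is the progression order."""

    ASYMPTOMATIC = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    EXTREME = 4

    @property
    def label(self) -> str:
        return STATES[self.value]


class ValidationError(ValueError):
    """Raised with *every* violated constraint, not just the first one."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid model parameters:\n  - " + "\n  - ".join(self.problems))


def _as_state_array(values, name: str) -> np.ndarray:
    """Accept a 5-vector or a {state-label: value} mapping."""
    if isinstance(values, Mapping):
        missing = [s for s in STATES if s not in values]
        if missing:
            raise ValidationError([f"{name}: missing states {missing}"])
        arr = np.array([float(values[s]) for s in STATES])
    else:
        arr = np.asarray(values, dtype=float)
        if arr.shape != (N_STATES,):
            raise ValidationError([f"{name}: expected {N_STATES} values, got shape {arr.shape}"])
    return arr


@dataclass(frozen=True)
class SeverityDistribution:
    """Occupancy of the five severity states for a cohort at one time point."""

    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "counts", _as_state_array(self.counts, "severity counts"))

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def per_capita(self, per_state_values: np.ndarray) -> float:
        """Cohort-average of a per-state quantity under this mix."""
        return float(self.counts @ np.asarray(per_state_values, dtype=float) / self.total)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STATES, self.counts.tolist()))

    def problems(self, cohort_size: float | None = None) -> list[str]:
        out = []
        if np.any(self.counts < 0):
            bad = [s for s, c in zip(STATES, self.counts) if c < 0]
            out.append(f"severity counts must be non-negative (negative: {bad})")
        if cohort_size is not None and self.total > 0:
            if abs(self.total - cohort_size) > 1e-6 * max(cohort_size, 1.0):
                out.append(
                    f"severity counts sum to {self.total:g}, expected cohort size {cohort_size:g}"
                )
        return out


@dataclass(frozen=True)
class InterventionCost:
    """One-time per-patient cost of the therapy, by component (2020 USD).

    ``relative_range`` is the deterministic sensitivity half-range on the
    total (the published analysis varies the total by +/-30%).
    """

    therapists: float = 9_828.0
    screening_lab: float = 909.0
    tests_pharmacy: float = 800.0
    relative_range: float = 0.30

    @property
    def total(self) -> float:
        return self.therapists + self.screening_lab + self.tests_pharmacy

    def problems(self) -> list[str]:
        out = []
        for name in ("therapists", "screening_lab", "tests_pharmacy"):
            if getattr(self, name) < 0:
                out.append(f"intervention cost component {name!r} is negative")
        if not (0 <= self.relative_range < 1):
            out.append("intervention relative_range must be in [0, 1)")
        return out


@dataclass(frozen=True)
class StateAnnualCost:
    """Annual all-cause medical cost per person by severity state (2020 USD)."""

    mean: np.ndarray = field(
        default_factory=lambda: np.array([5_032.0, 10_118.0, 15_177.0, 20_236.0, 24_283.0])
    )
    sd: np.ndarray = field(
        default_factory=lambda: np.array([712.0, 1_431.0, 2_146.0, 2_862.0, 3_434.0])
    )

    def __post_init__(self):
        object.__setattr__(self, "mean", _as_state_array(self.mean, "annual cost mean"))
        object.__setattr__(self, "sd", _as_state_array(self.sd, "annual cost sd"))

    def problems(self, strict_order: bool = True) -> list[str]:
        out = []
        if np.any(self.mean <= 0):
            out.append("annual medical cost means must be positive")
        if strict_order and np.any(np.diff(self.mean) <= 0):
            out.append("annual medical cost means must increase strictly with severity")
        if np.any(self.sd <= 0):
            out.append("annual medical cost SDs must be positive")
        return out


@dataclass(frozen=True)
class MortalityRR:
    """Relative risk of death vs background, by severity state."""

    mean: np.ndarray = field(default_factory=lambda: np.array([1.00, 1.74, 2.05, 2.51, 2.76]))
    sd: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.70, 0.80, 1.10, 1.25]))

    def __post_init__(self):
        object.__setattr__(self, "mean", _as_state_array(self.mean, "mortality RR mean"))
        object.__setattr__(self, "sd", _as_state_array(self.sd, "mortality RR sd"))

    def problems(self, strict_order: bool = True) -> list[str]:
        out = []
        if abs(self.mean[0] - 1.0) > 1e-12:
            out.append("asymptomatic mortality RR must be fixed at 1.00")
        if np.any(self.mean <= 0):
            out.append("mortality RRs must be positive")
        if strict_order and np.any(np.diff(self.mean) < 0):
            out.append("mortality RRs must be non-decreasing with severity")
        if np.any(self.sd < 0):
            out.append("mortality RR SDs must be non-negative")
        return out


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities in [0, 1] by severity state.

    ``relative_range`` is the +/- fraction used for deterministic sensitivity
    (published analysis: +/-10%).
    """

    values: np.ndarray = field(default_factory=lambda: np.array([0.90, 0.83, 0.74, 0.61, 0.37]))
    relative_range: float = 0.10

    def __post_init__(self):
        object.__setattr__(self, "values", _as_state_array(self.values, "utilities"))

    def problems(self, strict_order: bool = True) -> list[str]:
        out = []
        if np.any(self.values < 0) or np.any(self.values > 1):
            out.append("utilities must lie in [0, 1]")
        if strict_order and np.any(np.diff(self.values) >= 0):
            out.append("utilities must decrease strictly with severity")
        if not (0 <= self.relative_range < 1):
            out.append("utility relative_range must be in [0, 1)")
        return out


@dataclass(frozen=True)
class LifeTable:
    """Annual background death probabilities ``qx`` by single year of age.

    Lookups outside the tabulated age range clamp to the nearest end; ages
    between grid points are linearly interpolated (strata shifted by a
    sampled mean age land between integer ages).
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "qx", np.asarray(self.qx, dtype=float))

    def qx_at(self, age) -> np.ndarray | float:
        """Annual death probability at ``age`` (scalar or array)."""
        return np.interp(age, self.ages, self.qx)

    def problems(self) -> list[str]:
        out = []
        if self.ages.shape != self.qx.shape or self.ages.size < 2:
            out.append("life table must have matching age/qx columns with >= 2 rows")
            return out
        if np.any(np.diff(self.ages) <= 0):
            out.append("life-table ages must be strictly increasing")
        if self.ages.min() > 18 or self.ages.max() < 100:
            out.append("life table must cover at least ages [18, 100]")
        if np.any(self.qx <= 0) or np.any(self.qx > 1):
            out.append("life-table qx values must lie in (0, 1]")
        over30 = self.ages >= 30
        if np.any(np.diff(self.qx[over30]) < 0):
            out.append("life-table qx must be non-decreasing above age 30")
        anchor = float(np.interp(41.0, self.ages, self.qx))
        if not (0.9 * 0.0020 <= anchor <= 1.1 * 0.0020):
            out.append(f"life-table qx at age 41 is {anchor:g}; expected 0.0020 within +/-10%")
        return out

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"age", "qx"}.issubset(df.columns):
            raise ValidationError([f"life-table CSV {path} must have columns 'age,qx'"])
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        # %.17g keeps the round-trip bit-exact
        pd.DataFrame({"age": self.ages.astype(int), "qx": self.qx}).to_csv(
            path, index=False, float_format="%.17g"
        )


#: Cost-offset ramp: fraction of the achievable medical-cost reduction that is
#: realised in each year since treatment (year 1 first). Beyond the listed
#: years the ramp stays at its final value.
DEFAULT_RAMP: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class ModelParams:
    """The full model input set with uncertainty metadata."""

    intake: SeverityDistribution
    followup: SeverityDistribution
    intervention: InterventionCost = field(default_factory=InterventionCost)
    costs: StateAnnualCost = field(default_factory=StateAnnualCost)
    rr: MortalityRR = field(default_factory=MortalityRR)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    life_table: LifeTable | None = None
    cohort_size: float = 1000.0
    mean_age: float = 41.0
    age_sd: float = 11.9
    discount_rate: float = 0.03
    discount_rate_sd: float = 0.0034
    horizon: int = 30
    ramp: tuple[float, ...] = DEFAULT_RAMP
    progression_rate: float = 0.10
    progression_rate_range: tuple[float, float] = (0.05, 0.15)
    progression_start: int = 5

    def ramp_at(self, t: int) -> float:
        """Offset fraction realised in model year ``t`` (1-based)."""
        if t < 1:
            raise ValueError(f"cycle index must be >= 1, got {t}")
        return self.ramp[min(t - 1, len(self.ramp) - 1)]

    def problems(self, strict_order: bool = True) -> list[str]:
        out = []
        out += self.intake.problems(self.cohort_size)
        out += self.followup.problems(self.cohort_size)
        out += self.intervention.problems()
        out += self.costs.problems(strict_order)
        out += self.rr.problems(strict_order)
        out += self.utilities.problems(strict_order)
        if self.life_table is not None:
            out += self.life_table.problems()
        if self.cohort_size <= 0:
            out.append("cohort_size must be positive")
        if self.horizon < 1:
            out.append("horizon must be >= 1 year")
        if not (0 <= self.discount_rate < 1):
            out.append("discount_rate must lie in [0, 1)")
        if self.discount_rate_sd < 0:
            out.append("discount_rate_sd must be non-negative")
        if not (18 <= self.mean_age <= 90):
            out.append("mean_age must lie in [18, 90]")
        if self.age_sd < 0:
            out.append("age_sd must be non-negative")
        ramp = np.asarray(self.ramp, dtype=float)
        if ramp.size == 0 or np.any(ramp < 0) or np.any(ramp > 1):
            out.append("ramp fractions must lie in [0, 1]")
        elif np.any(np.diff(ramp) < 0) or ramp[-1] != 1.0:
            out.append("ramp fractions must be non-decreasing and reach 1.0")
        lo, hi = self.progression_rate_range
        if not (0 <= lo <= hi <= 1):
            out.append("progression_rate_range must satisfy 0 <= low <= high <= 1")
        if not (0 <= self.progression_rate <= 1):
            out.append("progression_rate must lie in [0, 1]")
        if self.progression_start < 0:
            out.append("progression_start must be non-negative")
        return out

    def validate(self, strict_order: bool = True) -> "ModelParams":
        probs = self.problems(strict_order)
        if probs:
            raise ValidationError(probs)
        return self

    def with_life_table(self, lt: LifeTable) -> "ModelParams":
        return replace(self, life_table=lt)

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)


# --- operations ---------------------------------------------------------


def total_intervention_cost(c: InterventionCost) -> float:
    """Per-patient one-time cost of the therapy: the exact component sum."""
    probs = c.problems()
    if probs:
        raise ValidationError(probs)
    return c.total


#: Decomposition of the therapist component into its activities (fractions of
#: the component, summing to 1): active drug sessions, post-session
#: integration, and the preparatory sessions before the first drug session.
#: Clinician time for screening/intake is costed inside the screening-lab
#: component, so total clinician compensation exceeds the therapist share.
DEFAULT_CLINICIAN_BREAKDOWN: dict[str, float] = {
    "active_sessions": 0.487 / 0.852,
    "integration_sessions": 0.274 / 0.852,
    "preparatory_sessions": 0.091 / 0.852,
}


def cost_component_shares(
    c: InterventionCost,
    clinician_breakdown: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Fractional decomposition of the total intervention cost.

    Returns the therapist share, the non-therapist share, and (when a
    clinician breakdown is given as fractions of the therapist component
    summing to 1) the sub-shares of the total attributable to each clinician
    activity.
    """
    total = total_intervention_cost(c)
    if total == 0:
        raise ValidationError(["cannot compute shares: total intervention cost is zero"])
    shares = {
        "therapists": c.therapists / total,
        "non_therapist": (c.screening_lab + c.tests_pharmacy) / total,
    }
    if clinician_breakdown is not None:
        sub = np.array(list(clinician_breakdown.values()), dtype=float)
        if abs(sub.sum() - 1.0) > 1e-6:
            raise ValidationError(
                [f"clinician breakdown fractions sum to {sub.sum():g}, expected 1"]
            )
        for name, frac in clinician_breakdown.items():
            shares[name] = frac * shares["therapists"]
    return shares


# --- configuration I/O ---------------------------------------------------

_BASE_CONFIG: dict = {
    "schema_version": SCHEMA_VERSION,
    "cohort_size": 1000,
    "severity_at_intake": {
        "asymptomatic": 0,
        "mild": 0,
        "moderate": 0,
        "severe": 714,
        "extreme": 286,
    },
    "severity_at_followup": {
        "asymptomatic": 333,
        "mild": 262,
        "moderate": 262,
        "severe": 119,
        "extreme": 24,
    },
    "intervention_cost": {
        "therapists": 9828,
        "screening_lab": 909,
        "tests_pharmacy": 800,
        "relative_range": 0.30,
    },
    "annual_medical_cost": {
        "mean": {
            "asymptomatic": 5032,
            "mild": 10118,
            "moderate": 15177,
            "severe": 20236,
            "extreme": 24283,
        },
        "sd": {
            "asymptomatic": 712,
            "mild": 1431,
            "moderate": 2146,
            "severe": 2862,
            "extreme": 3434,
        },
    },
    "mortality_relative_risk": {
        "mean": {"asymptomatic": 1.00, "mild": 1.74, "moderate": 2.05, "severe": 2.51, "extreme": 2.76},
        "sd": {"asymptomatic": 0.0, "mild": 0.70, "moderate": 0.80, "severe": 1.10, "extreme": 1.25},
    },
    "utilities": {
        "value": {"asymptomatic": 0.90, "mild": 0.83, "moderate": 0.74, "severe": 0.61, "extreme": 0.37},
        "relative_range": 0.10,
    },
    "mean_age": 41.0,
    "age_sd": 11.9,
    "discount_rate": 0.030,
    "discount_rate_sd": 0.0034,
    "horizon_years": 30,
    "cost_offset_ramp": [0.0, 0.25, 0.50, 0.75, 1.00],
    "progression_rate": 0.10,
    "progression_rate_range": [0.05, 0.15],
    "progression_start_year": 5,
    "life_table": None,
}


def _params_from_config(cfg: Mapping, config_dir: Path | None = None) -> ModelParams:
    merged = dict(_BASE_CONFIG)
    unknown = [k for k in cfg if k not in merged]
    if unknown:
        raise ValidationError([f"unknown configuration key {k!r}" for k in sorted(unknown)])
    merged.update(cfg)

    def sub(key, default):
        block = dict(default)
        got = merged[key] or {}
        bad = [k for k in got if k not in block]
        if bad:
            raise ValidationError([f"unknown key {k!r} under {key!r}" for k in sorted(bad)])
        block.update(got)
        return block

    ic = sub("intervention_cost", _BASE_CONFIG["intervention_cost"])
    amc = sub("annual_medical_cost", _BASE_CONFIG["annual_medical_cost"])
    mrr = sub("mortality_relative_risk", _BASE_CONFIG["mortality_relative_risk"])
    ut = sub("utilities", _BASE_CONFIG["utilities"])

    lt_path = merged["life_table"]
    if lt_path is None:
        from .synthetic import default_life_table

        lt = default_life_table()
    else:
        p = Path(lt_path)
        if config_dir is not None and not p.is_absolute():
            p = config_dir / p
        lt = LifeTable.from_csv(p)

    return ModelParams(
        intake=SeverityDistribution(merged["severity_at_intake"]),
        followup=SeverityDistribution(merged["severity_at_followup"]),
        intervention=InterventionCost(
            therapists=float(ic["therapists"]),
            screening_lab=float(ic["screening_lab"]),
            tests_pharmacy=float(ic["tests_pharmacy"]),
            relative_range=float(ic["relative_range"]),
        ),
        costs=StateAnnualCost(mean=amc["mean"], sd=amc["sd"]),
        rr=MortalityRR(mean=mrr["mean"], sd=mrr["sd"]),
        utilities=UtilitySet(values=ut["value"], relative_range=float(ut["relative_range"])),
        life_table=lt,
        cohort_size=float(merged["cohort_size"]),
        mean_age=float(merged["mean_age"]),
        age_sd=float(merged["age_sd"]),
        discount_rate=float(merged["discount_rate"]),
        discount_rate_sd=float(merged["discount_rate_sd"]),
        horizon=int(merged["horizon_years"]),
        ramp=tuple(float(x) for x in merged["cost_offset_ramp"]),
        progression_rate=float(merged["progression_rate"]),
        progression_rate_range=tuple(float(x) for x in merged["progression_rate_range"]),
        progression_start=int(merged["progression_start_year"]),
    )


def load_params(path) -> ModelParams:
    """Load and fully validate a model configuration.

    Missing optional keys are filled with the base-case defaults; every
    invariant is checked and all violations are reported together.
    """
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError([f"cannot parse {path}: {exc}"]) from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, Mapping):
        raise ValidationError([f"{path}: top level must be a mapping of configuration keys"])
    return _params_from_config(cfg, config_dir=path.parent).validate()


def params_to_config(params: ModelParams, life_table_path: str | None = None) -> dict:
    """The flat-config representation of ``params`` (numeric fields bit-equal)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "cohort_size": params.cohort_size,
        "severity_at_intake": params.intake.as_dict(),
        "severity_at_followup": params.followup.as_dict(),
        "intervention_cost": {
            "therapists": params.intervention.therapists,
            "screening_lab": params.intervention.screening_lab,
            "tests_pharmacy": params.intervention.tests_pharmacy,
            "relative_range": params.intervention.relative_range,
        },
        "annual_medical_cost": {
            "mean": dict(zip(STATES, params.costs.mean.tolist())),
            "sd": dict(zip(STATES, params.costs.sd.tolist())),
        },
        "mortality_relative_risk": {
            "mean": dict(zip(STATES, params.rr.mean.tolist())),
            "sd": dict(zip(STATES, params.rr.sd.tolist())),
        },
        "utilities": {
            "value": dict(zip(STATES, params.utilities.values.tolist())),
            "relative_range": params.utilities.relative_range,
        },
        "mean_age": params.mean_age,
        "age_sd": params.age_sd,
        "discount_rate": params.discount_rate,
        "discount_rate_sd": params.discount_rate_sd,
        "horizon_years": params.horizon,
        "cost_offset_ramp": list(params.ramp),
        "progression_rate": params.progression_rate,
        "progression_rate_range": list(params.progression_rate_range),
        "progression_start_year": params.progression_start,
        "life_table": life_table_path,
    }


def write_params(params: ModelParams, path, life_table_path: str | None = None) -> None:
    """Write ``params`` as a config file round-trippable through ``load_params``.

    If ``life_table_path`` is given the life table is written there as CSV and
    referenced from the config; otherwise the config references the built-in
    synthetic table.
    """
    path = Path(path)
    if life_table_path is not None and params.life_table is not None:
        params.life_table.to_csv(life_table_path)
        rel = str(life_table_path)
    else:
        rel = None
    path.write_text(yaml.safe_dump(params_to_config(params, rel), sort_keys=False))


def base_case(life_table: LifeTable | None = None) -> ModelParams:
    """The published base-case parameter set.

    Uses the bundled synthetic life table unless one is supplied.
    """
    params = _params_from_config({}, None)
    if life_table is not None:
        params = params.with_life_table(life_table)
    return params.validate()
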