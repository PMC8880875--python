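"""Synthetic inputs: a parametric life table and randomized configurations.

The analysis needs a U.S.-style background-mortality table.  The bundled
default is a Gompertz hazard — adult mortality rising log-linearly with age
— anchored so that the annual death probability at age 41 equals the
published 0.0020 and with slope 0.085/year (hazard doubling every ~8.2
years of age).  A real single-year life-table CSV with columns ``age,qx``
can be dropped in with the identical schema.

``random_config`` draws structurally valid parameter sets (ordered costs,
utilities and relative risks; normalized severity mixes) for property-based
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    InterventionCost,
    LifeTable,
    ModelParams,
    MortalityRR,
    SeverityDistribution,
    StateAnnualCost,
    UtilitySet,
    ValidationError,
)


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard: ``h(age) = a * exp(b * (age - reference_age))``.

    ``a`` is the annual hazard at the reference age, ``b`` the log-hazard
    slope per year of age.  Annual death probability is
    ``qx = 1 - exp(-h)``.
    """

    a: float
    b: float
    reference_age: float = 41.0

    @classmethod
    def from_anchor(
        cls, qx_at_ref: float = 0.0020, reference_age: float = 41.0, b: float = 0.085
    ) -> "GompertzParams":
        """Calibrate ``a`` so the death probability at the reference age is exact."""
        if not (0 < qx_at_ref < 1):
            raise ValidationError([f"anchor qx must lie in (0, 1), got {qx_at_ref}"])
        return cls(a=-np.log1p(-qx_at_ref), b=b, reference_age=reference_age)

    def qx(self, age) -> np.ndarray | float:
        h = self.a * np.exp(self.b * (np.asarray(age, dtype=float) - self.reference_age))
        return np.minimum(1.0, -np.expm1(-h))


def make_life_table(gp: GompertzParams, age_range: tuple[int, int] = (0, 110)) -> LifeTable:
    """Tabulate a Gompertz hazard as a single-year life table."""
    lo, hi = age_range
    if not (0 <= lo < hi <= 110):
        raise ValidationError([f"age range must lie within [0, 110], got {age_range}"])
    if gp.a <= 0 or gp.b < 0:
        raise ValidationError(["Gompertz parameters must satisfy a > 0 and b >= 0"])
    ages = np.arange(lo, hi + 1, dtype=float)
    qx = np.asarray(gp.qx(ages))
    if qx[0] >= 1.0:
        raise ValidationError([f"Gompertz parameters give qx >= 1 at age {lo}"])
    return LifeTable(ages=ages, qx=qx)


def default_life_table() -> LifeTable:
    """The bundled synthetic U.S.-style table (anchor 0.0020 at 41, slope 0.085)."""
    return make_life_table(GompertzParams.from_anchor())


def random_config(rng_seed: int, cohort_size: float = 1000.0) -> ModelParams:
    """A randomized, structurally valid parameter set for property testing.

    Ordering constraints are imposed constructively (sorted draws), so any
    seed yields a configuration that passes full validation.
    """
    if cohort_size < 1:
        raise ValidationError([f"cohort_size must be >= 1, got {cohort_size}"])
    rng = np.random.default_rng(rng_seed)

    def mix() -> SeverityDistribution:
        return SeverityDistribution(rng.dirichlet(np.ones(5)) * cohort_size)

    cost_mean = np.sort(rng.uniform(2_000, 40_000, size=5))
    cost_mean += np.arange(5)  # break ties from sorting
    utilities = np.sort(rng.uniform(0.2, 0.99, size=5))[::-1].copy()
    utilities -= np.arange(5) * 1e-6
    rr = np.concatenate([[1.0], np.sort(1.0 + rng.uniform(0.0, 3.0, size=4))])
    gp = GompertzParams.from_anchor(
        qx_at_ref=rng.uniform(0.0019, 0.0021), b=rng.uniform(0.05, 0.11)
    )
    ramp_len = int(rng.integers(2, 8))
    ramp = np.sort(rng.uniform(0, 1, size=ramp_len))
    ramp[0] = 0.0
    ramp[-1] = 1.0
    iv = InterventionCost(
        therapists=float(rng.uniform(1_000, 20_000)),
        screening_lab=float(rng.uniform(0, 2_000)),
        tests_pharmacy=float(rng.uniform(0, 2_000)),
        relative_range=0.30,
    )
    params = ModelParams(
        intake=mix(),
        followup=mix(),
        intervention=iv,
        costs=StateAnnualCost(mean=cost_mean, sd=np.maximum(cost_mean * 0.15, 1.0)),
        rr=MortalityRR(mean=rr, sd=np.concatenate([[0.0], rr[1:] * 0.4])),
        utilities=UtilitySet(values=utilities, relative_range=0.10),
        life_table=make_life_table(gp),
        cohort_size=cohort_size,
        mean_age=float(rng.uniform(25, 60)),
        age_sd=float(rng.uniform(5, 15)),
        discount_rate=float(rng.uniform(0.0, 0.07)),
        discount_rate_sd=0.0034,
        horizon=int(rng.integers(1, 41)),
        ramp=tuple(ramp.tolist()),
        progression_rate=float(rng.uniform(0, 0.3)),
        progression_rate_range=(0.05, 0.15),
        progression_start=int(rng.integers(0, 10)),
    )
    return params.validate()
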