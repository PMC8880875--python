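"""Report generation: result tables, JSON summaries and run manifests.

Currency is rounded to whole dollars and QALYs to whole units in the
formatted tables (matching the published display); full precision is
retained in the JSON files.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .engine import control_arm, mdma_arm, run_cohort
from .outcomes import CEResult, break_even_time, compare_arms
from .params import ModelParams


@dataclass
class RunManifest:
    """Provenance record attached to every emitted result file."""

    command: str
    config: str | None = None
    seed: int | None = None
    horizons: list[int] = field(default_factory=list)
    scenario: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _jsonable(x):
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return x


def base_case_results(
    params: ModelParams, horizons: list[int], accrual: str = "survivor"
) -> tuple[dict[int, CEResult], float]:
    """Paired-arm results for each horizon plus the break-even time."""
    if not horizons:
        raise ValueError("at least one analytic horizon is required")
    hmax = max(max(horizons), params.horizon)
    tm = run_cohort(params, mdma_arm(params), horizon=hmax, accrual=accrual)
    tc = run_cohort(params, control_arm(params), horizon=hmax, accrual=accrual)
    results = {h: compare_arms(tm, tc, h) for h in sorted(horizons)}
    t_star = break_even_time(tm, tc)
    return results, t_star


def results_table(results: dict[int, CEResult], break_even: float | None = None) -> pd.DataFrame:
    """Horizon-by-outcome table mirroring the published results layout."""
    rows = []
    for h, r in sorted(results.items()):
        ic = r.icer
        rows.append(
            {
                "horizon_years": h,
                "cost_mdma": round(r.cost_mdma),
                "cost_control": round(r.cost_control),
                "net_cost": round(r.net_cost),
                "qalys_mdma": round(r.qalys_mdma),
                "qalys_control": round(r.qalys_control),
                "qalys_gained": round(r.qalys_gained),
                "deaths_mdma": round(r.deaths_mdma, 1),
                "deaths_control": round(r.deaths_control, 1),
                "deaths_averted": round(r.deaths_averted, 1),
                "icer": ic if isinstance(ic, str) else (None if ic is None else round(ic)),
            }
        )
    df = pd.DataFrame(rows)
    if break_even is not None:
        df.attrs["break_even_years"] = break_even
    return df


def write_base_case_report(
    results: dict[int, CEResult],
    break_even: float,
    out_dir,
    manifest: RunManifest,
) -> dict:
    """Write the base-case report as CSV + JSON; returns the JSON payload."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_table(results).to_csv(out / "base_case.csv", index=False)
    payload = {
        "break_even_years": _jsonable(break_even),
        "results": {str(h): {k: _jsonable(v) for k, v in r.to_dict().items()}
                    for h, r in results.items()},
        "manifest": asdict(manifest),
    }
    (out / "base_case.json").write_text(json.dumps(payload, indent=2) + "\n")
    manifest.write(out / "manifest.json")
    return payload


def read_base_case_report(path) -> dict[int, CEResult]:
    """Re-read a JSON report into ``CEResult`` objects (round-trip)."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for h, r in payload["results"].items():
        out[int(h)] = CEResult(
            horizon=r["horizon"],
            cohort_size=r["cohort_size"],
            cost_mdma=r["cost_mdma"],
            cost_control=r["cost_control"],
            qalys_mdma=r["qalys_mdma"],
            qalys_control=r["qalys_control"],
            deaths_mdma=r["deaths_mdma"],
            deaths_control=r["deaths_control"],
        )
    return out
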