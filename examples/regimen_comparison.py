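"""Three- vs two-MDMA-session regimens: is the third session worth it?

The three-session arm is simulated by this model; the two-session regimen
enters as published result summaries (its efficacy distribution is not
re-simulated).  Both use the same prices and utilities, so the comparison
isolates the incremental effect of the third session.
"""

import mdma_cea as m
from mdma_cea.outcomes import PHASE2_RESULTS

params = m.base_case()

for h in (1, 10, 30):
    r = m.evaluate(params, h)
    cmp = m.regimen_comparison(
        PHASE2_RESULTS[h], m.RegimenResult(h, r.qalys_gained, r.net_cost)
    )
    verdict = cmp.icer if isinstance(cmp.icer, str) else f"${cmp.icer:,.0f}/QALY"
    print(
        f"{h:>2} y: +{cmp.qalys_gained:6,.0f} QALYs, incremental net cost "
        f"${cmp.net_cost:>14,.0f}  [{verdict}]"
    )

print(
    "\nAt one year the extra session buys QALYs at a finite (still "
    "cost-effective) price; over longer horizons the three-session regimen "
    "is dominant — more health and larger savings."
)
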