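"""One-way sensitivity analysis: which inputs move the 30-year net cost most.

Each parameter is pushed to its low and high bound (90% interval, or the
stated +/- range) with everything else held at its central value.
"""

import mdma_cea as m

params = m.base_case()
df = m.one_way_tornado(params, horizon=30)

print(f"{'parameter':>20} {'net cost at low':>16} {'net cost at high':>17} {'swing':>14}")
for row in df.head(8).itertuples():
    print(
        f"{row.parameter:>20} {row.output_at_low:>16,.0f} "
        f"{row.output_at_high:>17,.0f} {row.swing:>14,.0f}"
    )

print(
    "\nThe cohort's mean age and the cost of treating severe/extreme PTSD "
    "dominate; the therapy's own price barely matters because it is paid "
    "once while the savings recur for decades."
)
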