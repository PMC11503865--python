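"""Compare the three SID-lysine requirement models over one growth curve.

Prints the daily requirement (g/day and % of feed) at a few milestones.
The three recommendation systems disagree most early in the growing phase.
"""

from dailyfit import CohortParams, generate_cohort, mean_curve, requirement_curve

curve = mean_curve(generate_cohort(CohortParams(n=50, seed=1)))

print(f"{'day':>4} {'BW kg':>7} | " + " | ".join(f"{m:>16}" for m in ("BT-2017", "NRC-2012", "AGPIC-2021")))
series = {m: requirement_curve(m, curve) for m in ("bt2017", "nrc2012", "agpic2021")}
for day in (1, 30, 60, 90, 119):
    row = [f"{series[m][day - 1].sid_lys_g_per_day:7.2f} g/d "
           f"{series[m][day - 1].sid_lys_pct_of_feed:4.2f}%" for m in series]
    print(f"{day:>4} {curve.days[day - 1].bw:7.1f} | " + " | ".join(f"{r:>16}" for r in row))
# g/day rises with intake then flattens; the % of feed falls steadily,
# which is why later diets can be less nutrient-dense.
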