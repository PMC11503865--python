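"""Formulate one least-cost phase diet from the bundled corn-soy matrix.

The linear program minimizes price subject to nutrient floors, the energy
pin (3.4 Mcal ME/kg) and ingredient inclusion limits.
"""

from dailyfit import DietSpec, default_ingredients, formulate_least_cost

ingredients = default_ingredients()
spec = DietSpec.with_me_pin(
    "grower",
    {
        "cp": (160.0, None),        # g/kg
        "sid_lys": (11.0, None),
        "sid_met_cys": (6.2, None),
        "sid_thr": (6.9, None),
        "sttd_p": (3.0, None),
        "ca": (7.0, 10.0),
        "na": (1.8, None),
    },
)
diet = formulate_least_cost(ingredients, spec)

print(f"least-cost grower diet: {diet.price:.4f} BRL/kg")
for name, x in sorted(diet.inclusion.items(), key=lambda kv: -kv[1]):
    if x > 1e-6:
        print(f"  {name:24s} {100 * x:6.2f} %")
print("realized contents:")
for k in ("me", "cp", "sid_lys", "sttd_p", "ca"):
    print(f"  {k:10s} {diet.realized.get(k):7.2f}")
# Corn and soybean meal carry the diet; synthetic amino acids top up the
# lysine floor more cheaply than extra soybean meal would.
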