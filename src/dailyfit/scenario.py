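"""Scenario assembly: from a growth curve and a requirement model to a full
CON-vs-DFM comparison.

A *scenario* fixes the requirement model (BT-2017, NRC-2012 or AGPIC-2021)
used to set the lysine floor of each phase diet.  For every phase the SID
lysine minimum is the model's requirement — expressed as % of the feed —
on the phase's **first** day, when the pigs in the phase need the densest
diet.  The other essential amino acids follow the lysine floor through
ideal-protein ratios; crude protein, digestible phosphorus, calcium and
sodium floors follow fixed declining ladders typical of corn–soy
growing-finishing programs.  Dietary energy is pinned at 3.4 Mcal ME/kg in
every phase.

Six diets are formulated per scenario: one least-cost diet per phase plus
a sixth terminal feed obtained by diluting the fifth with the energy
ingredient (corn by default, 15% by mass).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

from .engine import (
    DEFAULT_PHASE_DURATIONS,
    PhaseSchedule,
    SimulationResult,
    simulate_con,
    simulate_dfm,
)
from .growth import GrowthCurve
from .ration import Diet, DietSpec, Ingredient, dilute, formulate_least_cost, read_ingredients
from .report import ComparisonSummary, CurrencyRate, build_summary
from .requirements import (
    LysRequirement,
    NRCParameters,
    RequirementModel,
    requirement_curve,
)

__all__ = [
    "DEFAULT_AA_TO_LYS",
    "DEFAULT_PHASE_FLOORS",
    "default_ingredients",
    "build_diet_specs",
    "formulate_scenario_diets",
    "ScenarioResult",
    "run_scenario",
]

#: ideal-protein ratios of the other essential amino acids to lysine
DEFAULT_AA_TO_LYS: Mapping[str, float] = {
    "sid_met_cys": 0.56,
    "sid_thr": 0.63,
    "sid_trp": 0.18,
    "sid_val": 0.68,
}

#: per-phase minimum contents (g/kg) besides lysine; declining ladders
DEFAULT_PHASE_FLOORS: Mapping[str, tuple[float, ...]] = {
    "cp": (160.0, 145.0, 130.0, 120.0, 110.0),
    "sttd_p": (3.2, 2.9, 2.6, 2.4, 2.2),
    "ca": (7.0, 6.5, 6.0, 5.6, 5.2),
    "na": (1.8, 1.7, 1.6, 1.5, 1.4),
}

#: slack allowed above the calcium floor (g/kg) to keep Ca:P sensible
_CA_BAND = 3.0


def default_ingredients() -> list[Ingredient]:
    """The bundled corn–soybean-meal ingredient matrix (prices in BRL/kg)."""
    with resources.as_file(
        resources.files("dailyfit.data").joinpath("cornsoy_ingredients.csv")
    ) as path:
        return read_ingredients(path)


def phase_start_requirements(
    model: RequirementModel | str,
    curve: GrowthCurve,
    durations: Sequence[int] = DEFAULT_PHASE_DURATIONS,
    params: NRCParameters | None = None,
) -> list[LysRequirement]:
    """The model's requirement on the first day of each feeding phase."""
    reqs = requirement_curve(model, curve, params)
    starts, start = [], 1
    for d in durations:
        starts.append(start)
        start += d
    by_day = {r.day: r for r in reqs}
    return [by_day[s] for s in starts]


def build_diet_specs(
    model: RequirementModel | str,
    curve: GrowthCurve,
    durations: Sequence[int] = DEFAULT_PHASE_DURATIONS,
    params: NRCParameters | None = None,
    floors: Mapping[str, tuple[float, ...]] = DEFAULT_PHASE_FLOORS,
    aa_to_lys: Mapping[str, float] = DEFAULT_AA_TO_LYS,
    me: float = 3.4,
) -> list[DietSpec]:
    """One nutrient-bound spec per phase, anchored on phase-start lysine."""
    phase_reqs = phase_start_requirements(model, curve, durations, params)
    specs = []
    for i, req in enumerate(phase_reqs):
        lys_floor = req.sid_lys_pct_of_feed * 10.0   # % of feed -> g/kg
        bounds: dict[str, tuple[float | None, float | None]] = {
            "sid_lys": (lys_floor, None)
        }
        for aa, ratio in aa_to_lys.items():
            bounds[aa] = (ratio * lys_floor, None)
        for nutrient, ladder in floors.items():
            bounds[nutrient] = (ladder[i], None)
        lo_ca, _ = bounds["ca"]
        bounds["ca"] = (lo_ca, lo_ca + _CA_BAND)
        specs.append(DietSpec.with_me_pin(phase_id=f"phase{i + 1}", bounds=bounds, me=me))
    return specs


def formulate_scenario_diets(
    specs: Sequence[DietSpec],
    ingredients: Sequence[Ingredient] | None = None,
    diluent_name: str = "corn",
    dilution_fraction: float = 0.15,
) -> list[Diet]:
    """Least-cost diets for each phase plus the diluted terminal feed."""
    ingredients = ingredients if ingredients is not None else default_ingredients()
    diets = [formulate_least_cost(ingredients, spec) for spec in specs]
    diluent = next((i for i in ingredients if i.name == diluent_name), None)
    if diluent is None:
        raise ValueError(f"diluent ingredient {diluent_name!r} not in the matrix")
    diets.append(
        dilute(diets[-1], diluent, dilution_fraction, phase_id=f"phase{len(specs) + 1}")
    )
    return diets


@dataclass(frozen=True)
class ScenarioResult:
    model: RequirementModel
    diets: tuple[Diet, ...]
    schedule: PhaseSchedule
    requirements: tuple[LysRequirement, ...]
    con: SimulationResult
    dfm: SimulationResult
    summary: ComparisonSummary


def run_scenario(
    model: RequirementModel | str,
    curve: GrowthCurve,
    ingredients: Sequence[Ingredient] | None = None,
    params: NRCParameters | None = None,
    rate: CurrencyRate = CurrencyRate(),
    durations: Sequence[int] = DEFAULT_PHASE_DURATIONS,
    dilution_fraction: float = 0.15,
) -> ScenarioResult:
    """Formulate, simulate and compare one scenario end to end."""
    model = RequirementModel(model)
    specs = build_diet_specs(model, curve, durations=durations, params=params)
    diets = formulate_scenario_diets(
        specs, ingredients, dilution_fraction=dilution_fraction
    )
    schedule = PhaseSchedule.standard(diets, durations=durations)
    con = simulate_con(curve, schedule)
    dfm = simulate_dfm(curve, schedule)
    summary = build_summary(con, dfm, rate=rate, scenario=model.value)
    return ScenarioResult(
        model=model,
        diets=tuple(diets),
        schedule=schedule,
        requirements=tuple(requirement_curve(model, curve, params)),
        con=con,
        dfm=dfm,
        summary=summary,
    )
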