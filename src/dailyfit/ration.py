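"""Least-cost diet formulation by linear programming.

A diet is an inclusion vector over a set of ingredients.  Formulation
minimizes the inclusion-weighted price subject to per-nutrient minimum and
maximum contents, per-ingredient inclusion bounds, and the simplex
constraint (fractions sum to one).  The LP is solved with the HiGHS
dual simplex via :func:`scipy.optimize.linprog`, which is deterministic
for a fixed instance.

Nutrient contents are per kg as-fed: ``me`` in Mcal/kg, everything else in
g/kg.  The canonical nutrient set covers metabolizable energy, crude
protein, the five first-limiting SID amino acids, digestible phosphorus,
calcium and sodium; profiles are open mappings, so additional nutrients
can be carried without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "CANONICAL_NUTRIENTS",
    "NutrientProfile",
    "Ingredient",
    "DietSpec",
    "Diet",
    "RationError",
    "InfeasibleDietError",
    "formulate_least_cost",
    "dilute",
    "read_ingredients",
    "write_ingredients",
    "read_diet",
    "write_diet",
]

#: canonical nutrient keys; me in Mcal/kg, all others g/kg as-fed
CANONICAL_NUTRIENTS = (
    "me",
    "cp",
    "sid_lys",
    "sid_met_cys",
    "sid_thr",
    "sid_trp",
    "sid_val",
    "sttd_p",
    "ca",
    "na",
)

_SUM_TOL = 1e-9


class RationError(ValueError):
    pass


class InfeasibleDietError(RationError):
    """The nutrient/inclusion constraint set admits no diet."""


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrient contents per kg of as-fed material (open mapping)."""

    contents: Mapping[str, float]

    def __post_init__(self) -> None:
        frozen = dict(self.contents)
        for k, v in frozen.items():
            if v < 0:
                raise RationError(f"nutrient {k!r} has negative content {v}")
        object.__setattr__(self, "contents", frozen)

    def __getitem__(self, key: str) -> float:
        return self.contents[key]

    def get(self, key: str, default: float = 0.0) -> float:
        return self.contents.get(key, default)

    def keys(self):
        return self.contents.keys()

    @staticmethod
    def blend(
        profiles: Sequence["NutrientProfile"], weights: Sequence[float]
    ) -> "NutrientProfile":
        """Mass-weighted linear combination of profiles."""
        keys: set[str] = set()
        for p in profiles:
            keys.update(p.keys())
        return NutrientProfile(
            {
                k: sum(w * p.get(k) for p, w in zip(profiles, weights))
                for k in sorted(keys)
            }
        )


@dataclass(frozen=True)
class Ingredient:
    name: str
    price: float                     # currency per kg as-fed
    profile: NutrientProfile
    min_incl: float = 0.0            # inclusion bounds, fraction of the diet
    max_incl: float = 1.0

    def __post_init__(self) -> None:
        if self.price < 0:
            raise RationError(f"{self.name}: price must be >= 0, got {self.price}")
        if not (0 <= self.min_incl <= self.max_incl <= 1):
            raise RationError(
                f"{self.name}: inclusion bounds must satisfy "
                f"0 <= min <= max <= 1, got ({self.min_incl}, {self.max_incl})"
            )


@dataclass(frozen=True)
class DietSpec:
    """Per-phase nutrient bounds; ``None`` means unbounded on that side."""

    phase_id: str
    bounds: Mapping[str, tuple[float | None, float | None]]

    def __post_init__(self) -> None:
        frozen = {k: (lo, hi) for k, (lo, hi) in dict(self.bounds).items()}
        for k, (lo, hi) in frozen.items():
            if lo is not None and hi is not None and lo > hi:
                raise RationError(f"{self.phase_id}: nutrient {k!r} has min {lo} > max {hi}")
        object.__setattr__(self, "bounds", frozen)

    @classmethod
    def with_me_pin(
        cls,
        phase_id: str,
        bounds: Mapping[str, tuple[float | None, float | None]],
        me: float = 3.4,
        band: float = 0.01,
    ) -> "DietSpec":
        """Spec with dietary energy pinned to ``me`` within ``+/- band`` Mcal/kg."""
        merged = dict(bounds)
        merged["me"] = (me - band, me + band)
        return cls(phase_id=phase_id, bounds=merged)


@dataclass(frozen=True)
class Diet:
    """A formulated feed: inclusion fractions, realized profile and price."""

    phase_id: str
    inclusion: Mapping[str, float]
    realized: NutrientProfile
    price: float

    def __post_init__(self) -> None:
        frozen = dict(self.inclusion)
        total = sum(frozen.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise RationError(
                f"{self.phase_id}: inclusion fractions sum to {total!r}, not 1"
            )
        for name, x in frozen.items():
            if x < -_SUM_TOL:
                raise RationError(f"{self.phase_id}: negative inclusion of {name}: {x}")
        object.__setattr__(self, "inclusion", frozen)

    @classmethod
    def from_inclusion(
        cls,
        phase_id: str,
        ingredients: Sequence[Ingredient],
        fractions: Sequence[float],
    ) -> "Diet":
        """Build a diet from an inclusion vector, deriving profile and price."""
        realized = NutrientProfile.blend([i.profile for i in ingredients], fractions)
        price = float(sum(i.price * x for i, x in zip(ingredients, fractions)))
        return cls(
            phase_id=phase_id,
            inclusion={i.name: float(x) for i, x in zip(ingredients, fractions)},
            realized=realized,
            price=price,
        )

    def satisfies(self, spec: DietSpec, tol: float = 1e-6) -> bool:
        """Post-hoc feasibility check, independent of the solver."""
        for k, (lo, hi) in spec.bounds.items():
            v = self.realized.get(k)
            if lo is not None and v < lo - tol:
                return False
            if hi is not None and v > hi + tol:
                return False
        return True


def _diagnose_impossible(
    ingredients: Sequence[Ingredient], spec: DietSpec
) -> list[str]:
    """List nutrient bounds no blend of the ingredients can ever meet."""
    problems = []
    for k, (lo, hi) in spec.bounds.items():
        contents = [i.profile.get(k) for i in ingredients]
        if lo is not None and max(contents) < lo:
            problems.append(
                f"{k} >= {lo} (best any ingredient offers is {max(contents)})"
            )
        if hi is not None and min(contents) > hi:
            problems.append(
                f"{k} <= {hi} (least any ingredient carries is {min(contents)})"
            )
    return problems


def formulate_least_cost(
    ingredients: Sequence[Ingredient], spec: DietSpec
) -> Diet:
    """Formulate the minimum-cost diet meeting ``spec``.

    Raises
    ------
    InfeasibleDietError
        If no inclusion vector satisfies the constraint set; the message
        names any bounds that are impossible for the ingredient matrix.
    """
    if not ingredients:
        raise RationError("at least one ingredient is required")
    n = len(ingredients)
    c = np.array([i.price for i in ingredients])
    bounds = [(i.min_incl, i.max_incl) for i in ingredients]
    a_ub, b_ub = [], []
    for k, (lo, hi) in spec.bounds.items():
        row = np.array([i.profile.get(k) for i in ingredients])
        if lo is not None:
            a_ub.append(-row)
            b_ub.append(-lo)
        if hi is not None:
            a_ub.append(row)
            b_ub.append(hi)
    res = linprog(
        c,
        A_ub=np.array(a_ub) if a_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.ones((1, n)),
        b_eq=np.array([1.0]),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        impossible = _diagnose_impossible(ingredients, spec)
        detail = "; impossible bounds: " + ", ".join(impossible) if impossible else ""
        raise InfeasibleDietError(
            f"phase {spec.phase_id}: no feasible diet ({res.message}){detail}"
        )
    x = np.where(np.abs(res.x) < 1e-12, 0.0, res.x)
    x = x / x.sum()  # remove the solver's ~1e-10 equality residual
    return Diet.from_inclusion(spec.phase_id, ingredients, x)


def dilute(
    feed5: Diet,
    diluent: Ingredient,
    fraction: float,
    phase_id: str | None = None,
) -> Diet:
    """Blend a terminal feed: ``(1 - fraction)`` of ``feed5`` plus ``fraction``
    of a single diluent ingredient.  Profile and price mix linearly by mass."""
    if not (0 <= fraction <= 1):
        raise RationError(f"dilution fraction must be in [0, 1], got {fraction}")
    inclusion = {k: (1 - fraction) * v for k, v in feed5.inclusion.items()}
    inclusion[diluent.name] = inclusion.get(diluent.name, 0.0) + fraction
    realized = NutrientProfile.blend(
        [feed5.realized, diluent.profile], [1 - fraction, fraction]
    )
    price = (1 - fraction) * feed5.price + fraction * diluent.price
    return Diet(
        phase_id=phase_id or f"{feed5.phase_id}_diluted",
        inclusion=inclusion,
        realized=realized,
        price=price,
    )


# ---------------------------------------------------------------------------
# CSV i/o
# ---------------------------------------------------------------------------

def read_ingredients(path: str | Path) -> list[Ingredient]:
    """Read an ingredient matrix.

    Required columns: ``name``, ``price``.  Optional: ``min_incl``,
    ``max_incl`` (default 0 and 1).  Every other column is a nutrient
    content (me in Mcal/kg, others g/kg).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("name", "price"):
        if col not in df.columns:
            raise RationError(f"{path}: missing required column {col!r}")
    nutrient_cols = [
        c for c in df.columns if c not in ("name", "price", "min_incl", "max_incl")
    ]
    out = []
    for i, row in df.iterrows():
        contents = {k: float(row[k]) for k in nutrient_cols if not pd.isna(row[k])}
        for k, v in contents.items():
            if v < 0:
                raise RationError(
                    f"{path}: row {i} ({row['name']}): negative {k} content {v}"
                )
        if row["price"] < 0:
            raise RationError(f"{path}: row {i} ({row['name']}): negative price")
        out.append(
            Ingredient(
                name=str(row["name"]),
                price=float(row["price"]),
                profile=NutrientProfile(contents),
                min_incl=float(row.get("min_incl", 0.0) if "min_incl" in df.columns else 0.0),
                max_incl=float(row.get("max_incl", 1.0) if "max_incl" in df.columns else 1.0),
            )
        )
    return out


def write_ingredients(ingredients: Sequence[Ingredient], path: str | Path) -> None:
    keys = sorted({k for i in ingredients for k in i.profile.keys()})
    rows = []
    for i in ingredients:
        row = {"name": i.name, "price": i.price}
        row.update({k: i.profile.get(k) for k in keys})
        row.update({"min_incl": i.min_incl, "max_incl": i.max_incl})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_diet(diet: Diet, path: str | Path) -> None:
    """Write a diet as ``phase_id, ingredient, fraction`` rows."""
    pd.DataFrame(
        {
            "phase_id": diet.phase_id,
            "ingredient": list(diet.inclusion.keys()),
            "fraction": list(diet.inclusion.values()),
        }
    ).to_csv(path, index=False)


def read_diet(path: str | Path, ingredients: Sequence[Ingredient]) -> Diet:
    """Rebuild a diet written by :func:`write_diet` against an ingredient matrix."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("phase_id", "ingredient", "fraction"):
        if col not in df.columns:
            raise RationError(f"{path}: missing required column {col!r}")
    by_name = {i.name: i for i in ingredients}
    missing = [n for n in df["ingredient"] if n not in by_name]
    if missing:
        raise RationError(f"{path}: unknown ingredients {missing}")
    order = [by_name[n] for n in df["ingredient"]]
    return Diet.from_inclusion(
        str(df["phase_id"].iloc[0]), order, df["fraction"].to_numpy()
    )
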