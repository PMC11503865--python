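import numpy as np
import pytest

from dailyfit import (
    CohortParams,
    Diet,
    GrowthCurve,
    GrowthDay,
    Ingredient,
    NutrientProfile,
    default_ingredients,
    generate_cohort,
    mean_curve,
)


@pytest.fixture(scope="session")
def small_cohort():
    """25 synthetic barrows; enough to exercise every downstream stage."""
    return generate_cohort(CohortParams(n=25, seed=7))


@pytest.fixture(scope="session")
def mean_growth(small_cohort):
    return mean_curve(small_cohort)


@pytest.fixture(scope="session")
def ingredients():
    return default_ingredients()


@pytest.fixture(scope="session")
def big_cohort():
    """Default-calibration cohort at the reference size (shared: ~5 s to build)."""
    return generate_cohort(CohortParams(n=1000, seed=0))


def make_flat_curve(horizon: int, bw: float = 50.0, adfi: float = 1.0) -> GrowthCurve:
    """Constant-weight, constant-intake curve (ADG identically zero)."""
    return GrowthCurve(
        days=tuple(GrowthDay(day=d, bw=bw, adg=0.0, adfi=adfi) for d in range(1, horizon + 1)),
        label="flat",
    )


def make_diet(phase_id: str, price: float, **contents: float) -> Diet:
    """Single-ingredient diet with the given price and nutrient contents."""
    ing = Ingredient(name=f"mix_{phase_id}", price=price, profile=NutrientProfile(contents))
    return Diet.from_inclusion(phase_id, [ing], [1.0])


def random_increasing_curve(rng: np.random.Generator, horizon: int) -> GrowthCurve:
    """Random but invariant-satisfying growth curve for property tests."""
    bw0 = rng.uniform(18, 30)
    gains = rng.uniform(0.0, 1.3, size=horizon - 1)
    bw = np.concatenate([[bw0], bw0 + np.cumsum(gains)])
    adfi = rng.uniform(0.5, 4.0, size=horizon)
    days = []
    for i in range(horizon):
        adg = bw[i + 1] - bw[i] if i < horizon - 1 else 0.0
        days.append(GrowthDay(day=i + 1, bw=float(bw[i]), adg=float(adg), adfi=float(adfi[i])))
    return GrowthCurve(days=tuple(days), label="random")
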