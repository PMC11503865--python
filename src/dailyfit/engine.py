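"""Day-by-day feeding simulation: conventional phase feeding vs daily fit.

Conventional phase feeding (CON) serves one fixed diet per growth phase.
The daily fit model (DFM) serves, on day ``d`` of a phase of length ``D``,
a mass blend of the phase's diet with the *next* phase's diet:

    anticipated share (%)  PD   = (100 / D) * (d - 1)
    current-feed share     AFI1 = 100 - PD
    next-feed share        AFI2 = PD

so every phase starts on the pure current diet (identical to CON) and
approaches the next diet linearly as the phase progresses.  The terminal
phase anticipates a sixth, diluted feed — this is why six diets exist for
five phases.

Price and every nutrient blend linearly by mass, so the day's feed cost is
``DFI * (AFI1*FP1 + AFI2*FP2)/100`` and the day's intake of nutrient ``k``
is ``DFI`` times the blended content of ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .growth import GrowthCurve
from .ration import Diet, NutrientProfile

__all__ = [
    "Phase",
    "PhaseSchedule",
    "BlendFraction",
    "DailyFeedRecord",
    "SimulationResult",
    "blend_fractions",
    "simulate_con",
    "simulate_dfm",
    "weekly_aggregate",
    "DEFAULT_PHASE_DURATIONS",
    "DEFAULT_WEIGHT_RANGES",
]

#: standard five-phase plan: durations (days) and target weight ranges (kg)
DEFAULT_PHASE_DURATIONS = (24, 29, 29, 16, 22)
DEFAULT_WEIGHT_RANGES = (
    (20.0, 35.0),
    (35.0, 60.0),
    (60.0, 90.0),
    (90.0, 110.0),
    (110.0, math.inf),
)


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class Phase:
    index: int
    duration_days: int
    weight_range: tuple[float, float]
    diet_current: Diet
    diet_next: Diet | None = None    # required for DFM; feed 6 for the last phase

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ScheduleError(f"phase {self.index}: duration must be >= 1 day")


@dataclass(frozen=True)
class PhaseSchedule:
    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        for pos, p in enumerate(self.phases):
            if p.index != pos + 1:
                raise ScheduleError(
                    f"phases must be contiguous from 1; position {pos} has index {p.index}"
                )

    @property
    def horizon(self) -> int:
        return sum(p.duration_days for p in self.phases)

    def phase_of_day(self, day: int) -> tuple[Phase, int]:
        """Map a 1-based production day to ``(phase, day_in_phase)``."""
        if day < 1 or day > self.horizon:
            raise ScheduleError(f"day {day} outside horizon 1..{self.horizon}")
        start = 1
        for p in self.phases:
            if day < start + p.duration_days:
                return p, day - start + 1
            start += p.duration_days
        raise AssertionError("unreachable")

    def phase_start_days(self) -> list[int]:
        starts, start = [], 1
        for p in self.phases:
            starts.append(start)
            start += p.duration_days
        return starts

    @classmethod
    def standard(
        cls,
        diets: Sequence[Diet],
        durations: Sequence[int] = DEFAULT_PHASE_DURATIONS,
        weight_ranges: Sequence[tuple[float, float]] = DEFAULT_WEIGHT_RANGES,
    ) -> "PhaseSchedule":
        """Five-phase schedule from six diets (the sixth is the diluted
        terminal feed anticipated during the last phase)."""
        if len(diets) != len(durations) + 1:
            raise ScheduleError(
                f"need {len(durations) + 1} diets for {len(durations)} phases, "
                f"got {len(diets)}"
            )
        phases = tuple(
            Phase(
                index=i + 1,
                duration_days=int(durations[i]),
                weight_range=tuple(weight_ranges[i]),
                diet_current=diets[i],
                diet_next=diets[i + 1],
            )
            for i in range(len(durations))
        )
        return cls(phases=phases)


@dataclass(frozen=True)
class BlendFraction:
    """Mass shares (%) of the current and anticipated feed on one phase day."""

    day_in_phase: int
    pd_pct: float      # anticipated share of the next diet
    afi1_pct: float    # share of the current diet = 100 - pd_pct
    afi2_pct: float    # share of the next diet   = pd_pct

    def __post_init__(self) -> None:
        if self.afi1_pct + self.afi2_pct != 100.0:
            raise ScheduleError("blend shares must sum to exactly 100")
        if not (0 <= self.pd_pct < 100):
            raise ScheduleError(f"pd_pct must be in [0, 100), got {self.pd_pct}")


def blend_fractions(day_in_phase: int, phase_duration: int) -> BlendFraction:
    """Blend shares on day ``d`` (1-based) of a phase lasting ``D`` days."""
    if not 1 <= day_in_phase <= phase_duration:
        raise ScheduleError(
            f"day_in_phase {day_in_phase} outside 1..{phase_duration}"
        )
    pd_pct = (100.0 / phase_duration) * (day_in_phase - 1)
    return BlendFraction(
        day_in_phase=day_in_phase,
        pd_pct=pd_pct,
        afi1_pct=100.0 - pd_pct,
        afi2_pct=pd_pct,
    )


@dataclass(frozen=True)
class DailyFeedRecord:
    day: int
    phase: int
    blend: BlendFraction
    dfi: float                     # feed intake, kg as-fed
    fp1: float                     # current-diet price, currency/kg
    fp2: float                     # next-diet price, currency/kg
    ctc: float                     # blended price, currency/kg
    cost: float                    # day's feed cost = dfi * ctc
    intake: Mapping[str, float]    # nutrient -> ingested amount (g, or Mcal for me)


@dataclass(frozen=True)
class SimulationResult:
    system: str                    # "CON" or "DFM"
    records: tuple[DailyFeedRecord, ...]
    totals: Mapping[str, float]    # nutrient -> cumulative intake
    total_cost: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "day": r.day,
                "phase": r.phase,
                "afi1_pct": r.blend.afi1_pct,
                "afi2_pct": r.blend.afi2_pct,
                "dfi": r.dfi,
                "fp1": r.fp1,
                "fp2": r.fp2,
                "ctc": r.ctc,
                "cost": r.cost,
            }
            row.update({f"intake_{k}": v for k, v in r.intake.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, system: str) -> "SimulationResult":
        records = []
        intake_cols = [c for c in df.columns if c.startswith("intake_")]
        for row in df.itertuples():
            # re-derive the complementary share so conservation is exact even
            # if the serialized floats were rounded
            afi2 = 100.0 - row.afi1_pct
            blend = BlendFraction(
                day_in_phase=1,  # not recoverable from the frame; placeholder
                pd_pct=afi2,
                afi1_pct=row.afi1_pct,
                afi2_pct=afi2,
            )
            records.append(
                DailyFeedRecord(
                    day=int(row.day),
                    phase=int(row.phase),
                    blend=blend,
                    dfi=row.dfi,
                    fp1=row.fp1,
                    fp2=row.fp2,
                    ctc=row.ctc,
                    cost=row.cost,
                    intake={c[len("intake_"):]: getattr(row, c) for c in intake_cols},
                )
            )
        return cls(
            system=system,
            records=tuple(records),
            totals=_sum_intakes(records),
            total_cost=sum(r.cost for r in records),
        )


def _sum_intakes(records: Sequence[DailyFeedRecord]) -> dict[str, float]:
    totals: dict[str, float] = {}
    for r in records:
        for k, v in r.intake.items():
            totals[k] = totals.get(k, 0.0) + v
    return totals


def _simulate(curve: GrowthCurve, schedule: PhaseSchedule, anticipate: bool) -> SimulationResult:
    if curve.horizon != schedule.horizon:
        raise ScheduleError(
            f"curve horizon ({curve.horizon} days) does not match schedule "
            f"horizon ({schedule.horizon} days)"
        )
    records = []
    for gd in curve.days:
        phase, d = schedule.phase_of_day(gd.day)
        if anticipate:
            if phase.diet_next is None:
                raise ScheduleError(
                    f"phase {phase.index}: daily-fit simulation requires a next diet"
                )
            blend = blend_fractions(d, phase.duration_days)
        else:
            blend = BlendFraction(day_in_phase=d, pd_pct=0.0, afi1_pct=100.0, afi2_pct=0.0)
        cur, nxt = phase.diet_current, phase.diet_next or phase.diet_current
        w1, w2 = blend.afi1_pct / 100.0, blend.afi2_pct / 100.0
        effective = NutrientProfile.blend([cur.realized, nxt.realized], [w1, w2])
        ctc = w1 * cur.price + w2 * nxt.price
        records.append(
            DailyFeedRecord(
                day=gd.day,
                phase=phase.index,
                blend=blend,
                dfi=gd.adfi,
                fp1=cur.price,
                fp2=nxt.price,
                ctc=ctc,
                cost=gd.adfi * ctc,
                intake={k: gd.adfi * effective.get(k) for k in effective.keys()},
            )
        )
    return SimulationResult(
        system="DFM" if anticipate else "CON",
        records=tuple(records),
        totals=_sum_intakes(records),
        total_cost=sum(r.cost for r in records),
    )


def simulate_con(curve: GrowthCurve, schedule: PhaseSchedule) -> SimulationResult:
    """Conventional phase feeding: 100% of the phase diet every day."""
    return _simulate(curve, schedule, anticipate=False)


def simulate_dfm(curve: GrowthCurve, schedule: PhaseSchedule) -> SimulationResult:
    """Daily fit model: a linearly growing share of the next phase's diet."""
    return _simulate(curve, schedule, anticipate=True)


def weekly_aggregate(result: SimulationResult, nutrient: str = "cp") -> pd.DataFrame:
    """Totals of one nutrient (or ``"cost"``) per consecutive 7-day week.

    Weeks run from day 1; a trailing partial week is kept and flagged in
    the ``partial`` column.
    """
    if not result.records:
        raise ValueError("empty simulation result")
    rows = []
    for r in result.records:
        value = r.cost if nutrient == "cost" else r.intake.get(nutrient, 0.0)
        rows.append({"week": (r.day - 1) // 7 + 1, "value": value})
    df = pd.DataFrame(rows)
    out = df.groupby("week").agg(total=("value", "sum"), days=("value", "size"))
    out["partial"] = out["days"] < 7
    return out.reset_index()
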