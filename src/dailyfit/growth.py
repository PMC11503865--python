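"""Synthetic growth and feed-intake curves for growing-finishing barrows.

Body weight follows a Gompertz trajectory — the standard sigmoidal growth
function for pigs — anchored exactly at a drawn initial and final weight.
With a fixed mature-weight asymptote ``A`` the two anchors determine the
remaining Gompertz parameters in closed form:

    BW(t) = A * exp(-b * exp(-k * (t - 1)))        t = 1..horizon
    b     = ln(A / BW_initial)
    k     = -ln( ln(A / BW_final) / b ) / (horizon - 1)

Ad-libitum feed intake is an allometric function of body weight,
``ADFI = a * BW**p``, plus truncated Gaussian day-to-day noise.  Average
daily gain is defined as the forward difference of body weight so that the
trajectory is exactly self-consistent; the final production day carries a
gain of zero (the pig leaves the barn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthDay",
    "GrowthCurve",
    "CohortParams",
    "CalibrationError",
    "CurveValidationError",
    "generate_cohort",
    "mean_curve",
    "read_curves",
    "write_curves",
]

#: tolerance for the BW/ADG self-consistency invariant (kg)
BW_ADG_TOL = 1e-6


class CalibrationError(ValueError):
    """Raised when a sigmoid cannot be anchored (e.g. final BW <= initial BW)."""


class CurveValidationError(ValueError):
    """Raised when curve data violate the growth-curve invariants."""


@dataclass(frozen=True)
class GrowthDay:
    """One production day: body weight, gain and ad-libitum intake."""

    day: int          # 1-based production day
    bw: float         # body weight, kg
    adg: float        # average daily gain, kg/day
    adfi: float       # ad-libitum daily feed intake, kg as-fed/day

    def __post_init__(self) -> None:
        if self.day < 1:
            raise CurveValidationError(f"day must be >= 1, got {self.day}")
        if not self.bw > 0:
            raise CurveValidationError(f"day {self.day}: bw must be > 0, got {self.bw}")
        if not self.adfi > 0:
            raise CurveValidationError(
                f"day {self.day}: adfi must be > 0, got {self.adfi}"
            )
        if self.adg < 0:
            raise CurveValidationError(
                f"day {self.day}: adg must be >= 0, got {self.adg}"
            )


@dataclass(frozen=True)
class GrowthCurve:
    """A full growth/intake trajectory for one pig or a cohort mean."""

    days: tuple[GrowthDay, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.days) < 2:
            raise CurveValidationError("a growth curve needs at least 2 days")
        for i, d in enumerate(self.days):
            if d.day != i + 1:
                raise CurveValidationError(
                    f"days must be consecutive from 1; position {i} has day {d.day}"
                )
        for prev, nxt in zip(self.days, self.days[1:]):
            if abs((nxt.bw - prev.bw) - prev.adg) > BW_ADG_TOL:
                raise CurveValidationError(
                    f"day {prev.day}: bw[t+1]-bw[t]={nxt.bw - prev.bw:.8f} "
                    f"inconsistent with adg={prev.adg:.8f}"
                )
            if nxt.bw < prev.bw:
                raise CurveValidationError(
                    f"day {nxt.day}: body weight decreases ({prev.bw} -> {nxt.bw})"
                )

    @property
    def horizon(self) -> int:
        return len(self.days)

    @property
    def bw(self) -> np.ndarray:
        return np.array([d.bw for d in self.days])

    @property
    def adg(self) -> np.ndarray:
        return np.array([d.adg for d in self.days])

    @property
    def adfi(self) -> np.ndarray:
        return np.array([d.adfi for d in self.days])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": [d.day for d in self.days],
                "bw": [d.bw for d in self.days],
                "adg": [d.adg for d in self.days],
                "adfi": [d.adfi for d in self.days],
            }
        )


@dataclass(frozen=True)
class CohortParams:
    """Population parameters for a synthetic barrow cohort.

    Defaults describe barrows entering the growing-finishing barn at
    20.61 +/- 0.85 kg and leaving at 138.94 +/- 0.90 kg after 120 days.
    ``intake_coeffs`` are ``(a, p)`` of the allometric intake function
    ``ADFI = a * BW**p``; the default pair (0.098, 0.75) puts cumulative
    intake of the mean curve near 300 kg over the 120-day horizon.
    """

    n: int = 1
    seed: int = 0
    bw0_mean: float = 20.61
    bw0_sd: float = 0.85
    bwF_mean: float = 138.94
    bwF_sd: float = 0.90
    horizon: int = 120
    mature_bw: float = 230.0          # Gompertz asymptote, kg
    intake_coeffs: tuple[float, float] = (0.098, 0.75)
    noise_sd: float = 0.10            # day-to-day intake noise, kg
    intake_floor: float = 0.2         # hard lower truncation of ADFI, kg

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.horizon < 2:
            raise ValueError(f"horizon must be >= 2, got {self.horizon}")
        if self.bw0_sd < 0 or self.bwF_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.bwF_mean > self.bw0_mean:
            raise CalibrationError(
                f"final BW mean ({self.bwF_mean}) must exceed initial "
                f"BW mean ({self.bw0_mean})"
            )
        if not self.mature_bw > self.bwF_mean:
            raise CalibrationError(
                f"mature BW ({self.mature_bw}) must exceed final BW mean "
                f"({self.bwF_mean})"
            )


def _gompertz_path(bw0: float, bwF: float, horizon: int, mature_bw: float) -> np.ndarray:
    """Body-weight path anchored at bw0 (day 1) and bwF (day `horizon`)."""
    if not bwF > bw0:
        raise CalibrationError(f"final BW ({bwF:.3f}) must exceed initial BW ({bw0:.3f})")
    if not mature_bw > bwF:
        raise CalibrationError(
            f"mature BW ({mature_bw:.3f}) must exceed final BW ({bwF:.3f})"
        )
    b = np.log(mature_bw / bw0)
    k = -np.log(np.log(mature_bw / bwF) / b) / (horizon - 1)
    t = np.arange(1, horizon + 1)
    return mature_bw * np.exp(-b * np.exp(-k * (t - 1)))


def _curve_from_arrays(
    bw: np.ndarray, adfi: np.ndarray, label: str
) -> GrowthCurve:
    adg = np.empty_like(bw)
    adg[:-1] = np.diff(bw)
    adg[-1] = 0.0  # final production day: pig leaves, no further gain recorded
    days = tuple(
        GrowthDay(day=i + 1, bw=float(bw[i]), adg=float(adg[i]), adfi=float(adfi[i]))
        for i in range(len(bw))
    )
    return GrowthCurve(days=days, label=label)


def generate_cohort(params: CohortParams) -> list[GrowthCurve]:
    """Generate ``params.n`` synthetic growth curves.

    Per pig, initial and final body weights are drawn from the configured
    normal distributions, the Gompertz path is anchored at both, and intake
    noise is added day by day.  The same seed and parameters always produce
    a bit-identical cohort.
    """
    rng = np.random.default_rng(params.seed)
    a, p = params.intake_coeffs
    curves: list[GrowthCurve] = []
    for i in range(params.n):
        bw0 = rng.normal(params.bw0_mean, params.bw0_sd)
        bwF = rng.normal(params.bwF_mean, params.bwF_sd)
        noise = rng.normal(0.0, params.noise_sd, size=params.horizon)
        if bw0 <= 0:
            raise CalibrationError(f"drawn initial BW {bw0:.3f} is non-positive")
        bw = _gompertz_path(bw0, bwF, params.horizon, params.mature_bw)
        adfi = np.maximum(a * bw**p + noise, params.intake_floor)
        curves.append(_curve_from_arrays(bw, adfi, label=f"pig_{i + 1:04d}"))
    return curves


def mean_curve(curves: Sequence[GrowthCurve], label: str = "cohort_mean") -> GrowthCurve:
    """Day-wise cohort mean of BW and ADFI (ADG re-derived from the mean BW)."""
    if not curves:
        raise ValueError("need at least one curve")
    horizons = {c.horizon for c in curves}
    if len(horizons) != 1:
        raise ValueError(f"curves have mixed horizons: {sorted(horizons)}")
    bw = np.mean([c.bw for c in curves], axis=0)
    adfi = np.mean([c.adfi for c in curves], axis=0)
    return _curve_from_arrays(bw, adfi, label=label)


# ---------------------------------------------------------------------------
# CSV i/o: columns label (optional on read), day, bw, adg, adfi
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("day", "bw", "adg", "adfi")


def write_curves(curves: Iterable[GrowthCurve] | GrowthCurve, path: str | Path) -> None:
    if isinstance(curves, GrowthCurve):
        curves = [curves]
    frames = []
    for c in curves:
        df = c.to_frame()
        df.insert(0, "label", c.label)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CurveValidationError(f"{path}: missing required columns {missing}")
    if "label" not in df.columns:
        df = df.assign(label="")
    curves = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.reset_index(drop=True)
        days = grp["day"].to_numpy()
        expected = np.arange(1, len(grp) + 1)
        bad = np.nonzero(days != expected)[0]
        if bad.size:
            i = int(bad[0])
            raise CurveValidationError(
                f"{path}: curve {label!r} has non-consecutive days at row {i} "
                f"(day {days[i]}, expected {expected[i]})"
            )
        neg = grp.index[grp["adfi"] <= 0]
        if len(neg):
            i = int(neg[0])
            raise CurveValidationError(
                f"{path}: curve {label!r} day {grp.loc[i, 'day']} has "
                f"non-positive adfi {grp.loc[i, 'adfi']}"
            )
        try:
            curve = GrowthCurve(
                days=tuple(
                    GrowthDay(int(r.day), float(r.bw), float(r.adg), float(r.adfi))
                    for r in grp.itertuples()
                ),
                label=str(label),
            )
        except CurveValidationError as exc:
            raise CurveValidationError(f"{path}: curve {label!r}: {exc}") from exc
        curves.append(curve)
    return curves
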