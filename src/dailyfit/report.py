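"""CON-vs-DFM comparison: totals, reductions, currency, overlays, figures.

Costs are carried in BRL throughout the simulation and converted to USD
only here, at reporting time.  Percent reductions are
``100 * (CON - DFM) / CON`` and are therefore invariant to the currency
and to any uniform rescaling of diet contents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .engine import PhaseSchedule, SimulationResult
from .requirements import LysRequirement

__all__ = [
    "CurrencyRate",
    "NutrientComparison",
    "ComparisonSummary",
    "reduction_pct",
    "nitrogen_from_cp",
    "to_usd",
    "lys_overlay",
    "phase_start_lys_table",
    "build_summary",
    "plot_weekly_cp",
    "plot_cumulative",
    "plot_lys_overlay",
]

#: conventional crude-protein-to-nitrogen factor (CP = N * 6.25)
CP_TO_N = 6.25


@dataclass(frozen=True)
class CurrencyRate:
    """BRL per USD exchange rate (5.05 in the reference simulations)."""

    brl_per_usd: float = 5.05

    def __post_init__(self) -> None:
        if not self.brl_per_usd > 0:
            raise ValueError(f"exchange rate must be > 0, got {self.brl_per_usd}")


def to_usd(amount_brl: float, rate: CurrencyRate = CurrencyRate()) -> float:
    return amount_brl / rate.brl_per_usd


def reduction_pct(con_total: float, dfm_total: float) -> float:
    """Percent reduction of DFM relative to CON; negative if DFM exceeds CON."""
    if not con_total > 0:
        raise ValueError(
            f"percent reduction undefined for CON total {con_total}"
        )
    return 100.0 * (con_total - dfm_total) / con_total


def nitrogen_from_cp(cp_g: float) -> float:
    """Nitrogen (g) equivalent of a crude-protein mass (g): N = CP / 6.25."""
    if cp_g < 0:
        raise ValueError(f"crude protein mass must be >= 0, got {cp_g}")
    return cp_g / CP_TO_N


@dataclass(frozen=True)
class NutrientComparison:
    con_total: float
    dfm_total: float
    abs_reduction: float
    pct_reduction: float | None   # None when the CON total is zero


@dataclass(frozen=True)
class ComparisonSummary:
    """Tabular comparison of one scenario's CON and DFM runs.

    Costs are reported in USD (converted at ``rate``); the underlying BRL
    totals are kept alongside.
    """

    scenario: str
    nutrients: Mapping[str, NutrientComparison]
    cost_con: float                # USD per pig
    cost_dfm: float                # USD per pig
    cost_reduction_abs: float      # USD per pig
    cost_reduction_pct: float
    cost_con_brl: float
    cost_dfm_brl: float
    rate: CurrencyRate

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item": k,
                "con_total": v.con_total,
                "dfm_total": v.dfm_total,
                "abs_reduction": v.abs_reduction,
                "pct_reduction": v.pct_reduction,
            }
            for k, v in self.nutrients.items()
        ]
        rows.append(
            {
                "item": "cost_usd",
                "con_total": self.cost_con,
                "dfm_total": self.cost_dfm,
                "abs_reduction": self.cost_reduction_abs,
                "pct_reduction": self.cost_reduction_pct,
            }
        )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [f"Scenario {self.scenario}: CON vs DFM"]
        lines.append(
            f"  feed cost $/pig: CON {self.cost_con:.2f}  DFM {self.cost_dfm:.2f}  "
            f"reduction {self.cost_reduction_abs:.2f} ({self.cost_reduction_pct:.2f}%)"
        )
        for k, v in self.nutrients.items():
            pct = f"{v.pct_reduction:.2f}%" if v.pct_reduction is not None else "n/a"
            lines.append(
                f"  {k}: CON {v.con_total:.1f}  DFM {v.dfm_total:.1f}  "
                f"reduction {v.abs_reduction:.1f} ({pct})"
            )
        return "\n".join(lines)


def _check_conservation(result: SimulationResult) -> None:
    cost = sum(r.cost for r in result.records)
    if cost != result.total_cost:
        raise ValueError(
            f"{result.system}: total_cost {result.total_cost} does not equal "
            f"the sum of daily costs {cost}"
        )


def build_summary(
    con: SimulationResult,
    dfm: SimulationResult,
    rate: CurrencyRate = CurrencyRate(),
    scenario: str = "",
) -> ComparisonSummary:
    """Compare two runs nutrient by nutrient and on cost.

    Totals are cross-checked against the daily records before use.  A
    nitrogen row is derived from crude protein with the conventional 6.25
    factor when CP is tracked.
    """
    _check_conservation(con)
    _check_conservation(dfm)
    keys = sorted(set(con.totals) | set(dfm.totals))
    nutrients: dict[str, NutrientComparison] = {}
    for k in keys:
        c, d = con.totals.get(k, 0.0), dfm.totals.get(k, 0.0)
        nutrients[k] = NutrientComparison(
            con_total=c,
            dfm_total=d,
            abs_reduction=c - d,
            pct_reduction=reduction_pct(c, d) if c > 0 else None,
        )
    if "cp" in nutrients:
        cmp_cp = nutrients["cp"]
        nutrients["n"] = NutrientComparison(
            con_total=nitrogen_from_cp(cmp_cp.con_total),
            dfm_total=nitrogen_from_cp(cmp_cp.dfm_total),
            abs_reduction=nitrogen_from_cp(cmp_cp.abs_reduction),
            pct_reduction=cmp_cp.pct_reduction,
        )
    cost_con_usd = to_usd(con.total_cost, rate)
    cost_dfm_usd = to_usd(dfm.total_cost, rate)
    return ComparisonSummary(
        scenario=scenario,
        nutrients=nutrients,
        cost_con=cost_con_usd,
        cost_dfm=cost_dfm_usd,
        cost_reduction_abs=cost_con_usd - cost_dfm_usd,
        cost_reduction_pct=reduction_pct(con.total_cost, dfm.total_cost),
        cost_con_brl=con.total_cost,
        cost_dfm_brl=dfm.total_cost,
        rate=rate,
    )


def lys_overlay(
    result: SimulationResult, requirements: Sequence[LysRequirement]
) -> pd.DataFrame:
    """Per-day dietary SID lysine (% of feed) next to the requirement (%).

    The diet series is the lysine content of the feed actually served that
    day, recovered as intake / DFI; the requirement series comes from the
    chosen model.  For CON the diet series is stepwise-constant within
    phases; for DFM it declines piecewise-linearly.
    """
    req_by_day = {r.day: r for r in requirements}
    rows = []
    for rec in result.records:
        req = req_by_day.get(rec.day)
        diet_pct = rec.intake.get("sid_lys", 0.0) / rec.dfi / 10.0
        rows.append(
            {
                "day": rec.day,
                "phase": rec.phase,
                "diet_lys_pct": diet_pct,
                "requirement_pct": req.sid_lys_pct_of_feed if req else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def phase_start_lys_table(
    overlay: pd.DataFrame, schedule: PhaseSchedule
) -> pd.DataFrame:
    """Diet-vs-requirement lysine on the first day of each feeding phase."""
    starts = schedule.phase_start_days()
    return overlay[overlay["day"].isin(starts)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Figures (pure views over the records; nothing is recomputed)
# ---------------------------------------------------------------------------

def _new_axes(title: str, xlabel: str, ylabel: str):
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib.figure import Figure

    fig = Figure(figsize=(7, 4))
    ax = fig.add_subplot(111)
    ax.set_title(title)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return fig, ax


def plot_weekly_cp(con: SimulationResult, dfm: SimulationResult, title: str = ""):
    from .engine import weekly_aggregate

    wc, wd = weekly_aggregate(con, "cp"), weekly_aggregate(dfm, "cp")
    fig, ax = _new_axes(title or "Weekly crude protein intake", "week", "CP intake (g)")
    width = 0.4
    ax.bar(wc["week"] - width / 2, wc["total"], width, label="CON")
    ax.bar(wd["week"] + width / 2, wd["total"], width, label="DFM")
    ax.legend()
    return fig


def plot_cumulative(
    con: SimulationResult, dfm: SimulationResult, nutrient: str = "cp", title: str = ""
):
    import numpy as np

    fig, ax = _new_axes(
        title or f"Cumulative {nutrient} intake", "production day", f"{nutrient} (cumulative)"
    )
    for res, style in ((con, "-"), (dfm, "--")):
        days = [r.day for r in res.records]
        vals = np.cumsum([r.intake.get(nutrient, 0.0) for r in res.records])
        ax.plot(days, vals, style, label=res.system)
    ax.legend()
    return fig


def plot_lys_overlay(overlay: pd.DataFrame, title: str = ""):
    fig, ax = _new_axes(
        title or "Dietary SID lysine vs requirement", "production day", "SID Lys (% of feed)"
    )
    ax.plot(overlay["day"], overlay["diet_lys_pct"], label="diet")
    ax.plot(overlay["day"], overlay["requirement_pct"], label="requirement")
    ax.legend()
    return fig
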