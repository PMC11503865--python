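"""Factorial SID-lysine requirement models for growing-finishing barrows.

Three published recommendation systems are implemented:

* **BT-2017** (Brazilian tables): maintenance scales with metabolic body
  weight and the growth term is a weight-dependent lysine cost per kg of
  gain, ``SID Lys (g/d) = 0.036*BW^0.75 + Y*ADG`` with
  ``Y = 16.664 + 0.0736*BW - 0.0003*BW^2`` (ADG in kg/day).

* **NRC-2012** (factorial): maintenance covers basal endogenous ileal
  losses (proportional to feed intake) plus integument losses
  (proportional to metabolic weight), both divided by a lysine-use
  efficiency ``e = 0.75 + 0.002*(maxPD - 147.7)``; growth covers the
  lysine retained in whole-body protein deposition (7.10 g Lys per 100 g
  protein), divided by the same efficiency and adjusted by a
  weight-dependent factor ``(1 + 0.0547 + 0.002215*BW)``.  Protein
  deposition for barrows is a genotype-scaled cubic in body weight.

* **AGPIC-2021** (commercial lineage): a quadratic in body weight
  (expressed in pounds) below 40 kg, with a quartic multiplicative
  correction above 40 kg.  This family states the requirement as a
  lysine-to-energy ratio (g SID Lys per Mcal of ME); daily requirements
  follow by multiplying with dietary ME density and daily feed intake.

``requirement_curve`` maps any of the three models over a growth curve,
returning grams per day and the equivalent percentage of the feed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Literal, Sequence

from .growth import GrowthCurve

__all__ = [
    "RequirementModel",
    "NRCParameters",
    "LysRequirement",
    "sid_lys_bt2017",
    "nrc_basal_endogenous_lys",
    "nrc_integument_lys",
    "nrc_pd_barrows",
    "nrc_lys_in_pd",
    "nrc_lysine_efficiency",
    "default_maximum_pd",
    "sid_lys_nrc2012",
    "sid_lys_agpic2021",
    "requirement_curve",
]

LB_PER_KG = 2.204622  # pound conversion used by the AGPIC equations

#: coefficients of the barrow protein-deposition cubic (per unit genotype scalar)
_PD_CUBIC = (0.7078, 0.013764, -0.00014211, 3.2698e-7)


class RequirementModel(str, Enum):
    BT2017 = "bt2017"
    NRC2012 = "nrc2012"
    AGPIC2021 = "agpic2021"


class ConfigurationError(ValueError):
    """Raised for parameter combinations that make a model undefined."""


def _check_nonnegative(**values: float) -> None:
    for name, v in values.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")


def _check_positive(**values: float) -> None:
    for name, v in values.items():
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")


# ---------------------------------------------------------------------------
# BT-2017
# ---------------------------------------------------------------------------

def sid_lys_bt2017(bw: float, adg: float) -> float:
    """SID lysine requirement (g/day), Brazilian-tables factorial model.

    Parameters
    ----------
    bw : body weight, kg.
    adg : average daily gain, kg/day.  The marginal lysine cost ``Y`` is in
        g per kg of gain, so gain enters in kg/day.
    """
    _check_positive(bw=bw)
    _check_nonnegative(adg=adg)
    y = 16.664 + 0.0736 * bw - 0.0003 * bw**2
    return 0.036 * bw**0.75 + y * adg


# ---------------------------------------------------------------------------
# NRC-2012
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NRCParameters:
    """Genotype and diet parameters of the NRC-2012 factorial model.

    maximum_pd
        Maximum whole-body protein deposition of the genotype (g/day).
        ``None`` (the default) resolves to the maximum of the barrow
        protein-deposition curve over the 20-140 kg growing-finishing
        range for the configured ``pdmax_coeff``.
    pdmax_coeff
        Genotype scalar of the protein-deposition cubic (133 for the
        reference barrow genotype).
    me_content
        Dietary metabolizable energy density, Mcal/kg as-fed (3.4 in all
        simulations here).  Also used to convert the AGPIC
        lysine-to-energy ratio into g/day.
    growth_adjustment
        How the weight-dependent factor ``(1 + 0.0547 + 0.002215*BW)``
        enters the growth term: ``"divide"`` (as printed in the source
        equations; the default) or ``"multiply"`` (the NRC monograph's
        own usage).
    """

    maximum_pd: float | None = None
    pdmax_coeff: float = 133.0
    me_content: float = 3.4
    growth_adjustment: Literal["divide", "multiply"] = "divide"

    def __post_init__(self) -> None:
        if self.pdmax_coeff < 0:
            raise ConfigurationError(f"pdmax_coeff must be >= 0, got {self.pdmax_coeff}")
        if not self.me_content > 0:
            raise ConfigurationError(f"me_content must be > 0, got {self.me_content}")
        if self.maximum_pd is not None and not self.maximum_pd > 0:
            raise ConfigurationError(f"maximum_pd must be > 0, got {self.maximum_pd}")
        if self.growth_adjustment not in ("divide", "multiply"):
            raise ConfigurationError(
                f"growth_adjustment must be 'divide' or 'multiply', "
                f"got {self.growth_adjustment!r}"
            )

    def resolved(self) -> "NRCParameters":
        """Return a copy with ``maximum_pd`` filled in if it was None."""
        if self.maximum_pd is not None:
            return self
        return replace(self, maximum_pd=default_maximum_pd(self.pdmax_coeff))


def nrc_basal_endogenous_lys(dfi: float) -> float:
    """Basal endogenous ileal lysine loss (g/day); linear in feed intake (kg/day)."""
    _check_nonnegative(dfi=dfi)
    return dfi * 0.417 * 0.88 * 1.1


def nrc_integument_lys(bw: float) -> float:
    """Integument (skin and hair) lysine loss (g/day); scales with BW^0.75."""
    _check_positive(bw=bw)
    return 0.0045 * bw**0.75


def nrc_pd_barrows(bw: float, params: NRCParameters | None = None) -> float:
    """Whole-body protein deposition of barrows (g/day), clamped at zero."""
    _check_positive(bw=bw)
    params = params or NRCParameters()
    c0, c1, c2, c3 = _PD_CUBIC
    pd = params.pdmax_coeff * (c0 + c1 * bw + c2 * bw**2 + c3 * bw**3)
    return max(pd, 0.0)


def nrc_lys_in_pd(pd: float) -> float:
    """Lysine retained in protein deposition (g/day): 7.10 g per 100 g protein."""
    _check_nonnegative(pd=pd)
    return pd * 7.10 / 100.0


def nrc_lysine_efficiency(maximum_pd: float) -> float:
    """Marginal efficiency of SID lysine use: 0.75 + 0.002*(maxPD - 147.7)."""
    e = 0.75 + 0.002 * (maximum_pd - 147.7)
    if e <= 0:
        raise ConfigurationError(
            f"lysine-use efficiency {e:.4f} <= 0 for maximum_pd={maximum_pd}"
        )
    return e


def default_maximum_pd(
    pdmax_coeff: float = 133.0, bw_range: tuple[float, float] = (20.0, 140.0)
) -> float:
    """Maximum of the barrow protein-deposition cubic over a BW range (g/day).

    The cubic's stationary points are found analytically; the maximum over
    the closed interval is taken over the interior stationary points and
    the endpoints.
    """
    import numpy as np

    lo, hi = bw_range
    _, c1, c2, c3 = _PD_CUBIC
    # derivative c1 + 2*c2*bw + 3*c3*bw^2 = 0
    roots = np.roots([3 * c3, 2 * c2, c1])
    candidates = [lo, hi] + [float(r) for r in roots if np.isreal(r) and lo < r < hi]
    p = NRCParameters(pdmax_coeff=pdmax_coeff)
    return max(nrc_pd_barrows(bw, p) for bw in candidates)


def sid_lys_nrc2012(bw: float, dfi: float, params: NRCParameters | None = None) -> float:
    """SID lysine requirement (g/day), NRC-2012 factorial model.

    Maintenance = (basal endogenous + integument losses) / e, with
    e = 0.75 + 0.002*(maxPD - 147.7).  Growth = lysine retained in protein
    deposition / e, adjusted by (1 + 0.0547 + 0.002215*BW) per
    ``params.growth_adjustment``.
    """
    _check_positive(bw=bw)
    _check_nonnegative(dfi=dfi)
    params = (params or NRCParameters()).resolved()
    e = nrc_lysine_efficiency(params.maximum_pd)
    maintenance = (nrc_basal_endogenous_lys(dfi) + nrc_integument_lys(bw)) / e
    pd = nrc_pd_barrows(bw, params)
    growth = nrc_lys_in_pd(pd) / e
    adjustment = 1 + 0.0547 + 0.002215 * bw
    if params.growth_adjustment == "divide":
        growth /= adjustment
    else:
        growth *= adjustment
    return maintenance + growth


# ---------------------------------------------------------------------------
# AGPIC-2021
# ---------------------------------------------------------------------------

def sid_lys_agpic2021(bw: float) -> float:
    """AGPIC-2021 SID lysine recommendation as a lysine-to-energy ratio.

    Returns the published ratio (g SID Lys per Mcal ME).  Below 40 kg the
    ratio is a quadratic in body weight expressed in pounds; above 40 kg
    the same quadratic is scaled by ``1 + c(BW)`` where ``c`` is a quartic
    in body weight (kg) with coefficients read in descending power order:

        c(BW) = -3.1e-9*BW^4 + 1.3234e-6*BW^3 - 2.087068e-4*BW^2
                + 1.42221655e-2*BW - 0.3126825057

    The correction is a small perturbation (|c| < 4% over 40-140 kg and
    c(40) is nearly 0), so the two branches join almost continuously;
    exact continuity at 40 kg is not guaranteed.  The boundary weight
    itself uses the below-40 branch.
    """
    _check_positive(bw=bw)
    lb = bw * LB_PER_KG
    base = 0.0000255654 * lb**2 - 0.0157978368 * lb + 4.4555073859
    if bw <= 40.0:
        return base
    c = (
        -0.0000000031 * bw**4
        + 0.0000013234 * bw**3
        - 0.0002087068 * bw**2
        + 0.0142221655 * bw
        - 0.3126825057
    )
    return base * (1 + c)


# ---------------------------------------------------------------------------
# Per-day requirement series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LysRequirement:
    """Daily SID lysine requirement in g/day and as % of the feed."""

    day: int
    bw: float
    sid_lys_g_per_day: float
    sid_lys_pct_of_feed: float   # = g/day / (ADFI * 10)


def requirement_curve(
    model: RequirementModel | str,
    curve: GrowthCurve,
    params: NRCParameters | None = None,
) -> list[LysRequirement]:
    """Evaluate a requirement model over every day of a growth curve.

    BT-2017 and NRC-2012 return g/day directly from body weight, gain and
    intake.  The AGPIC-2021 ratio (g/Mcal ME) is converted to g/day as
    ``ratio * me_content * ADFI`` using ``params.me_content``
    (default 3.4 Mcal/kg).
    """
    model = RequirementModel(model)
    params = (params or NRCParameters()).resolved()
    out: list[LysRequirement] = []
    for d in curve.days:
        if model is RequirementModel.BT2017:
            g = sid_lys_bt2017(d.bw, d.adg)
        elif model is RequirementModel.NRC2012:
            g = sid_lys_nrc2012(d.bw, d.adfi, params)
        else:
            g = sid_lys_agpic2021(d.bw) * params.me_content * d.adfi
        out.append(
            LysRequirement(
                day=d.day,
                bw=d.bw,
                sid_lys_g_per_day=g,
                sid_lys_pct_of_feed=g / (d.adfi * 10.0),
            )
        )
    return out


def requirements_to_frame(requirements: Sequence[LysRequirement]):
    """Tabulate a requirement series (columns day, bw, g/day, % of feed)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "day": [r.day for r in requirements],
            "bw": [r.bw for r in requirements],
            "sid_lys_g_per_day": [r.sid_lys_g_per_day for r in requirements],
            "sid_lys_pct_of_feed": [r.sid_lys_pct_of_feed for r in requirements],
        }
    )
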