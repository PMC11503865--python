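# Methods

## Scope and moving parts

`dailyfit` simulates the growing-finishing period of barrows (castrated
males) under two group-feeding systems driven by the same daily feed
intake: conventional five-phase feeding (CON) and a daily fit model (DFM)
that linearly anticipates the next phase's diet. Five stages are chained:
synthetic growth curves → requirement models → least-cost diet
formulation → day-by-day simulation → comparison reporting. Every stage is
usable on its own.

## Synthetic growth curves

Commercial herd growth databases are proprietary, so cohorts are
generated. Body weight follows a Gompertz path, the standard sigmoid for
pig growth. Rather than fitting three free parameters, the asymptote is
fixed at a mature weight `A` (default 230 kg, a typical mature barrow
weight) and the remaining two parameters are solved in closed form so the
path passes exactly through a drawn initial weight on day 1 and a drawn
final weight on the last day:

    b = ln(A/BW0),  k = −ln( ln(A/BWF)/b ) / (H−1)

Per pig, `BW0 ~ N(20.61, 0.85²)` and `BWF ~ N(138.94, 0.90²)` kg over a
`H = 120`-day horizon. The published ± values do not state whether they
are SDs or SEs; they are treated as cohort SDs, which is the conservative
reading for calibration-recovery tests.

ADG is defined as the forward difference of BW, so the consistency
invariant `bw[t+1] − bw[t] = adg[t]` holds exactly and the gains telescope
to `BWF − BW0`. The final day carries `adg = 0` (the pig leaves the barn;
no next-day weight exists). Downstream requirement models therefore see a
maintenance-only final day — a one-day edge with no visible effect on any
phase-level quantity.

Intake is allometric in body weight, `ADFI = a·BW^p + ε`, with `p = 0.75`
(metabolic scaling) and `a = 0.098` chosen once so the mean curve's
cumulative intake over 120 days is ≈300 kg — the realistic mid-range for
modern barrows (0.95 kg/day at 20 kg rising to ≈4.0 kg/day at 139 kg).
Daily noise `ε ~ N(0, 0.1²)` kg is truncated so intake never falls below
a 0.2 kg floor; noise is applied to intake only, never to BW, so the
BW/ADG invariant is exact. All randomness flows from one
`numpy.random.default_rng(seed)`; identical parameters and seed give
bit-identical cohorts.

What the generator does **not** emulate: sex categories other than
barrows, seasonal or health-related intake dips, between-farm variance,
and any correlation between a pig's intake noise and its growth (growth is
anchored independently of realized intake). Tests passing on these curves
show the pipeline's arithmetic and ordering properties, not predictive
validity for a specific commercial herd.

## Requirement models

Three published SID-lysine recommendation systems are implemented exactly
as printed, with three documented repairs where the printed equations are
defective:

* **BT-2017.** `0.036·BW^0.75 + Y·ADG` with
  `Y = 16.664 + 0.0736·BW − 0.0003·BW²`. The units of `Y` (≈17–20) are
  g SID Lys per kg of gain, so ADG enters in kg/day; this yields 12–24
  g/day over the horizon, the plausible range for growing-finishing pigs.
* **NRC-2012.** Maintenance = (basal endogenous ileal losses,
  `DFI·0.417·0.88·1.1`, plus integument losses, `0.0045·BW^0.75`) divided
  by the marginal efficiency `e = 0.75 + 0.002·(maxPD − 147.7)`. The
  printed maintenance equation has unbalanced brackets; the grouping of
  `e` is taken from the growth equation, where the same expression is
  printed grouped. Growth = `PD·7.10/100 / e`, adjusted by
  `(1 + 0.0547 + 0.002215·BW)`. The source prints this factor as a
  divisor and it is implemented that way by default, although the NRC
  monograph multiplies; `NRCParameters(growth_adjustment="multiply")`
  switches the behaviour. Protein deposition for barrows is
  `133·(0.7078 + 0.013764·BW − 0.00014211·BW² + 3.2698e−7·BW³)`, clamped
  at zero — a safety net only, since the printed cubic has a positive
  local minimum (≈44 g/day near 228 kg) and never goes negative.
  `maximum_pd` defaults to the cubic's analytic maximum over the 20–140 kg
  growing-finishing range (≈145.3 g/day at ≈61.5 kg), keeping scalar calls
  deterministic and curve-independent; it is configurable for other
  genotypes.
* **AGPIC-2021.** Below 40 kg a quadratic in BW expressed in pounds
  (conversion factor exactly 2.204622); the boundary weight uses this
  branch. Above 40 kg the printed correction equation is garbled
  (unbalanced brackets, a dangling linear term); it is reconstructed as
  `Eq11·(1 + c(BW))` with the five printed coefficients read once each in
  descending power order, `c(BW) = −3.1e−9·BW⁴ + 1.3234e−6·BW³ −
  2.087068e−4·BW² + 1.42221655e−2·BW − 0.3126825057`. Two observations
  support this reading: `c(40) ≈ −0.001`, so the branches join nearly
  continuously, and `|c| < 4%` over the whole range, i.e. a small
  perturbation — exactly what a correction term should be. Continuity at
  40 kg is *not* asserted anywhere, only measured.

**AGPIC units.** The AGPIC equations evaluate to ≈2.2–4.5 over 20–140 kg.
That is not a g/day scale (BT-2017 gives 12–24 g/day); it is the scale of
a lysine-to-energy ratio, the form this commercial lineage publishes its
recommendations in. Converting BT-2017 to g per Mcal ME at matching
weights lands on nearly the same values (≈2.8 vs ≈2.9 at 60 kg), which
confirms the reading. The scalar function therefore returns the equation
value as printed, documented as g SID Lys per Mcal ME, and
`requirement_curve` converts to g/day as `ratio × ME density × DFI`
(ME density 3.4 Mcal/kg by default). For BT-2017 and NRC-2012 the curve
is the literal per-day map of the scalar operation.

All three models are cross-checked to 1e−9 against a separate
straight-line transcription of the printed equations
(`tests/reference_equations.py`) that shares no code with the package.

## Diet formulation

Each scenario formulates five least-cost diets with
`scipy.optimize.linprog` (HiGHS): minimize inclusion-weighted price
subject to nutrient floors/caps, ingredient inclusion bounds and the
sum-to-one constraint. HiGHS is deterministic for a fixed instance; the
solver's ~1e−10 equality residual is removed by renormalizing the
inclusion vector, and the reported price is recomputed as the
inclusion-price dot product. Feasibility is re-verified post hoc,
independent of the solver, and on small instances the LP cost is checked
against an exhaustive 1e−3 inclusion grid. Infeasible specifications
raise an error that names any bound no blend of the ingredients could
ever meet.

Per-phase bounds: the SID-lysine floor is the scenario model's requirement
as % of feed on the phase's **first** day — the day the phase's pigs need
the densest diet, and the day on which diet and requirement are compared
in reporting. Met+Cys, Thr, Trp and Val floors follow lysine at
ideal-protein ratios (0.56, 0.63, 0.18, 0.68). CP
(160/145/130/120/110 g/kg), STTD P (3.2/2.9/2.6/2.4/2.2), Ca
(7.0→5.2, capped 3 g/kg above the floor to keep Ca:P sensible) and Na
(1.8→1.4) follow fixed declining ladders typical of corn–soy
growing-finishing programs. ME is pinned to 3.4 ± 0.01 Mcal/kg in every
phase. Declining floors make each next diet no denser than the current
one, which is the precondition under which the DFM provably never
increases any nutrient intake.

The sixth feed dilutes the fifth with the energy ingredient (corn) at a
configurable fraction, default 0.15. The source names neither the diluent
nor the factor; any cheap, low-nutrient diluent reproduces the structural
role of feed 6 — the terminal blend the last phase anticipates.

The bundled ingredient matrix (corn, soybean meal, soybean oil,
limestone, dicalcium phosphate, salt, four crystalline amino acids, a
fixed 0.3% premix) is a representative corn–soy matrix with plausible
Brazilian prices in BRL/kg; it is a synthetic stand-in for a proprietary
ingredient table, bundled so every stage is testable offline. Nutrient
contents are per kg as-fed: ME in Mcal/kg, everything else in g/kg.

## Feeding engine

Phase boundaries are the fixed default durations
(24, 29, 29, 16, 22 days), not realized BW crossings — the durations were
defined *from* the weight ranges a priori, and fixed durations keep CON
and DFM on identical calendars. The blend rule is

    PD = (100/D)·(d − 1),  AFI1 = 100 − PD,  AFI2 = PD

the only reading of the published symbol table in which day 1 of each
phase is 100% current feed (so DFM coincides with CON at every phase
start) and the blend approaches the next diet as the phase ends. The
share pair is exactly conserving in floating point (verified exhaustively
for all phase lengths up to 200 days). Price and all nutrients blend
linearly by mass; the day's cost is `DFI·Ctc` and intake of nutrient k is
`DFI` times the blended content. CON records carry the next diet's price
with a zero share so that phase-start records are bit-identical between
systems. An alternative printed total-cost form `Σ (D × F × I)` would
double-count days if I were per-phase total intake; totals are computed
as price times the phase's summed daily intake, and the daily loop is
verified against this closed form on randomized instances.

Costs are carried in BRL internally and converted to USD only in
reporting (default 5.05 BRL/USD). Weeks are consecutive 7-day blocks from
day 1; a trailing partial week is kept and flagged. Nitrogen is derived
from crude protein with the conventional factor 6.25, so N and CP percent
reductions coincide by construction; an accounting in which they differ
would need an unstated nitrogen model, and none is guessed at.

## Problem sizes and numerical choices

The reference cohort is n = 1000 pigs (calibration anchors recover to
within 3 standard errors); scenario runs use the cohort mean curve, and
tests use n = 25–1000 as appropriate. The full three-scenario study runs
in a few seconds. Tolerances: 1e−9 for arithmetic oracles and cost
identities, 1e−6 kg for the BW/ADG invariant and post-hoc diet
feasibility, exact equality where floating-point exactness is guaranteed
(blend conservation, shared feed mass, record sums). CSV round-trips use
pandas' round-trip float parser so written curves and diets reload
field-for-field identical.

## Known limitations

* Reductions depend on the diet ladders declining; a scenario whose
  requirement rises with age (none of the three here) could make a next
  diet denser and DFM would then report a negative reduction — reported,
  not clipped.
* ME intake is pinned by formulation, so its CON−DFM difference is a
  rounding-scale artifact of the ±0.01 Mcal/kg band, not a reduction
  claim; the comparison tracks CP, amino acids, N, STTD P and cost.
* The models cover barrows only; gilts, entire males and
  ractopamine-supplemented deposition are out of scope.
* Excretion is not modelled — the package accounts for nutrient *intake*;
  excretion reductions in the literature (e.g. ≈1.5% less N excreted per
  percentage-unit CP reduction) can be applied downstream but are not
  computed here.
* Absolute costs and reduction percentages depend on the ingredient
  prices and growth curves supplied; the bundled fixtures give
  reductions of the same order as published group-feeding studies
  (cost ≈2–3%, lysine ≈7–10%), but reproducing any specific herd's
  dollar figures requires that herd's curves and prices.
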