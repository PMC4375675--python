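# Methods

`wormbudget` simulates populations of the compost earthworm *Eisenia fetida*
as a collection of individuals, each carrying its own energy budget, living
on a grid of soil patches whose food stocks they deplete.  This note
documents the model, its parameters, the numerical choices, and what the
synthetic experiments used in the test suite do and do not demonstrate.

## The individual energy budget

Each hatched individual is described by its life-cycle stage (juvenile or
adult), structural mass `M` (g), stored reserve energy (kJ, glycogen), and an
accumulating reproduction pool.  Each simulated day the individual:

1. **Ingests** food at the type II functional response rate
   `IGmax · f(T) · X/(h+X) · M^(2/3)` (g/day), never more than the patch
   holds, and assimilates a fixed fraction `Ae` of its energy content `Ex`.
   `f(T) = exp((−E/k_B)(1/T − 1/Tref))` is the Arrhenius correction relative
   to the reference temperature.
2. **Pays maintenance** `B = B0 · M^(3/4) · exp(−E/(k_B T))` (the absolute
   Arrhenius form), first from assimilated energy, then from reserve — but
   only down to half the reserve capacity `M·Ec`.
3. **Reproduces** (adults with another adult on the same patch) up to
   `rm · f(T) · M` kJ/day, funded from remaining assimilated energy and,
   when food is short, from reserve above the same half-capacity threshold;
   each `Mc (Ec + Es)` kJ accumulated converts to one cocoon carrying an
   energy endowment `Mc·Ec`.
4. **Grows** up to the von Bertalanffy daily increment
   `rB · f(T) · (Mm^(1/3) M^(2/3) − M)` at a cost of `Ec + Es` kJ per gram,
   funded from assimilated energy only.
5. **Stores** any remainder as reserve, capped at `M·Ec`; energy beyond the
   cap is discarded (treated as unassimilated).
6. **Catabolises tissue** at `Ec` kJ/g for any maintenance still unpaid
   (the starvation state), and dies if its mass falls below the birth mass
   `Mb`.

Reproduction having priority over growth in adults is a deliberate departure
from fixed-partition ("kappa-rule") energy budgets: it reproduces the
observations that unmated worms grow larger and that cocoon production
continues through periods of weight loss.  Every step is logged in an
itemised `EnergyLedger`; the test suite checks that each day's ledger closes
to better than 1e−9 kJ for arbitrary states.

Cocoons neither feed nor move; they pay maintenance (at cocoon mass `Mc`)
from their endowment, accumulate development at `f(T)/T0` per day, hatch as
`Mb`-mass juveniles carrying the residual endowment, and die if the
endowment runs out first.  Juveniles become adults at the maturity mass
`Mp`.

### Parameters

Defaults (per-gram/per-day units, temperatures in kelvin): `Ae` 0.50,
`B0` 967 kJ/day, `E` 0.25 eV, `k_B` 8.62e−5 eV/K, `Ec` 7 kJ/g, `Es` 3.6
kJ/g, `Ex` 21.2 kJ/g, `IGmax` 0.70 g/day/g, `h` 3.5 g/0.01 m², `Mb` 0.011 g,
`Mc` 0.015 g, `Mp` 0.25 g, `Mm` 0.50 g, `rB` 0.177 /day, `rm` 0.182
kJ/g/day, `T0` 23 days, `Tref` 298.15 K.  All are literature-derived
species-level constants, not fitted quantities; the simulator treats them as
a frozen, validated dataclass.

## The landscape and scheduler

The arena is a rectangle of 0.01 m² patches (the factorisation closest to
square for the configured area).  Worms move 5 cm/day with turning angles
uniform on ±90°, reflecting at the walls.  Each day, agents are processed in
freshly shuffled order (ingestion competition is first-come within the
day), cocoons incubate, and — in field scenarios — juveniles and adults face
a daily background mortality probability given by an empirical regression in
soil moisture (%) and temperature (K), clamped at zero.  Laboratory presets
run without background mortality: that regression describes field
populations, and laboratory survival in the replicated experiments was
complete.  Population regulation is emergent: the only interactions are
shared food depletion and mating.

Field scenarios draw daily soil temperature (SD 5 °C) and moisture (SD 10
points, truncated to [0, 100]) around seasonal means (autumn/winter/spring/
summer soil values 9/8/17/21 °C and 60/40/70/45 %), and reset patch food at
season boundaries to draws around the seasonal manure stock (10/15/50/5
kg/m², SD 10 % of the mean).  Season lengths are 91/91/92/91 days.  The
soil temperature of the manure heap adds a 5 °C composting warming to
ambient temperatures above 10 °C, rounded to whole degrees.  Resetting (not
topping up) the food stock at season boundaries reflects a managed manure
heap, dumped in bulk and largely removed in late spring; whether
replenishment is pulsed or continuous is not observable from the data the
model is built on, and the pulse choice is the simpler one.

## Toxicity submodels and model selection

Sublethal dose-response is summarised as `R(C) = exp(k_tox · C)`, fitted by
regressing `ln(value/control mean)` on concentration *without intercept*, so
`R(0) = 1` by construction.  Submodels map trait curves onto parameters:
T1 scales `IGmax` (growth curve); T2 scales `IGmax` and `rm`; T3 scales `rB`
and `rm`; T4 leaves parameters untouched up to 100 mg/kg and sets
`B0 → B0 · 0.01 · C` above it (the discontinuity at the threshold is part of
the rule).  Exposure is constant and spatially uniform, matching laboratory
tests; no toxicokinetics are modelled.

Submodels are compared by small-sample AIC on normalised residuals
`(model − observed)/observed`: `AICc = n ln(σ̂²) + 2n′n/(n−n′−1)` with
`σ̂² = Σε̂²/n` and `n′` the number of toxicity coefficients (1 for T1/T4, 2
for T2/T3).  A perfect fit reports `−inf` as a sentinel.  Evidence ratios
are `exp(Δᵢ/2)`.  Stochastic model outputs are averaged over the scenario's
replicates before residuals are computed.

A caveat established while testing: T1's textbook signature (growth reduced
more than reproduction) appears only while ingestion *rate* is the binding
constraint.  In closed scenarios where a fixed food ration is eventually
consumed, a lower `IGmax` merely delays depletion, and late in the run dosed
worms can end heavier than famine-crashed controls.  The submodel-recovery
experiment therefore observes growth early (days 7–28) and reproduction
late (days 28–55), and evaluates candidates with the generating
coefficients; under that design the AICc comparison identifies the
generating submodel in 20/20 seeded trials.

## Local sensitivity analysis

The one-at-a-time design perturbs each physiological parameter, and the
environmental baselines, by +10 % and reports the elasticity
`(%ΔOutput)/(%ΔParameter)` of year-mean outputs against a baseline arm with
shared random streams (paired replicates; the standard error is computed
over paired per-replicate elasticities).  The scenario is the 1 m² field
arena (50 adults, 100 juveniles, 100 cocoons at start, stage-consistent
uniform masses) run for one year with all seasonal means pinned to the
baselines: soil temperature 25 °C, moisture 60 %, food 20 g/patch at each
seasonal reset; daily variability is kept at the field SDs.  Temperature
quantities (Tref, the soil-temperature baseline) are perturbed on the kelvin
scale.  Outputs are per-individual: the time-mean of the daily mean adult
and juvenile body mass, and cumulative cocoons per time-mean adult count.
Per-individual outputs are bounded by the physiology, so their elasticities
measure parameter effects rather than the amplitude of population booms and
crashes, and they match the per-individual character of the reproduction
output.

Two caveats.  First, a +10 % kelvin perturbation is a ~30 K shock (the
relative Arrhenius factor moves by a factor ~2.4); elasticities measured at
that amplitude are far outside the linear-response regime.  Second, under
the 20 g/patch baseline the population runs through pronounced feast–famine
cycles within each season, and juvenile mean mass in particular is dominated
by starving hatchling cohorts during the famine phase, which makes its
temperature elasticity large.  Both effects are properties of the stated
design, not numerical artefacts; the default replicate count is 100, and
the bundled analyses use 20 to keep a full run in minutes on one CPU.

## Numerical choices

- One-day explicit time step throughout, matching the daily resolution of
  the growth increment.  Daily stepping of the growth equation undershoots
  the continuous closed-form curve by up to ~7 % around day 5 from the
  hatchling mass, where the growth timescale is comparable to the step,
  converging to <0.1 % by day 100; from 0.1 g the trajectory stays within
  1 % of the closed form to maturity.  Trajectory comparisons in the tests
  are therefore anchored at 0.1 g.
- Cocoon development accumulates `f(T)/T0` per day with a 1e−9 hatching
  tolerance so that `T0` steps at `Tref` hatch exactly on day `T0`.
- Reserve capacity shrinks with mass; reserve in excess of the shrunken
  capacity is clamped off and the loss is recorded in the ledger.
- Worms created at scenario start receive reserve at 50 % of capacity —
  exactly the starvation threshold — so they neither starve instantly nor
  fund reproduction from their initial endowment.
- All randomness flows from one master seed through named sub-streams
  (initialisation, environment, movement, mortality, shuffling) spawned per
  replicate; results are bit-reproducible given (config, seed), and paired
  perturbation arms reuse the baseline's streams.

## What the synthetic experiments show

The dose-response fixture generator produces replicated concentration–trait
tables with multiplicative lognormal noise around an exact exponential
decline; recovery tests on it exercise the fitting pipeline, not field
realism.  The synthetic submodel-recovery study demonstrates that the four
physiological pathways leave distinguishable signatures in simulated
experiments of realistic size — it does not show that real experimental
noise levels allow the same discrimination.  Laboratory presets reproduce
the published protocols' printed conditions, but starting body masses are
mostly unreported in the sources and are documented guesses in the preset
files; simulated trajectories should be compared with published data with
that in mind.

## Known limitations

No senescence, no individual parameter variation, no vertical soil
structure, no chemical degradation or transport, no multi-egg cocoons, and
movement costs are folded into maintenance.  Density dependence arises only
through food depletion and mate finding.  The background mortality
regression extrapolates poorly far outside the field conditions it came
from and is clamped at zero rather than refitted.
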