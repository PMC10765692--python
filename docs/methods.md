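# Methods

## Model structure

The simulation state is a list of stand cohorts, each defined by region,
forest type, integer age (years), area (ha) and a per-hectare carbon
pool vector. The pool vector has 14 named slots — merchantable stem
(incl. bark), other wood, foliage, coarse roots (≥5 mm), fine roots
(<5 mm), snag stems, snag branches, medium DOM (coarse woody debris on
the ground), aboveground fast/very fast/slow DOM, belowground
fast/very fast/slow DOM — and each cohort carries a softwood/hardwood
flag on its leading species. Because a cohort populates exactly one of
the duplicated softwood/hardwood live and snag families, the 14-slot
vector is an exact encoding of the 21-pool CBM-CFS3 scheme. IPCC
categories aggregate as: living biomass = the five live pools; deadwood
= snags + medium DOM + belowground fast (dead coarse roots in mineral
soil); litter = aboveground fast + very fast + slow (the F/H/O
horizons); soil = belowground very fast + slow. The pool table we
follow lists the aboveground fast pool twice and omits an explicit
aboveground slow row; we assign the F/H/O horizons to the aboveground
slow pool, which is the standard CBM reading.

Ages are tracked in integer years; 10-year classes appear only in
reporting. Total forest area is constant over the whole projection —
every cleared hectare is replanted within the year; afforestation and
deforestation are out of scope.

### Annual dynamics

The fixed sub-annual order is **grow → turnover → decay →
disturbances**. No sub-annual ordering is prescribed by the underlying
modelling tradition; this order is a documented choice and the tests pin
it.

Growth is yield-driven: the merchantable volume increment v(a+1) − v(a)
of the cohort's curve is converted to carbon with the forest type's
carbon density and expanded to the other live pools with fixed component
ratios. Defaults: density 0.22 t C/m³ (softwoods) and 0.28 (hardwoods);
ratios of stem carbon (other wood, foliage, coarse roots, fine roots) =
(0.30, 0.05, 0.20, 0.02) for softwoods and (0.35, 0.03, 0.22, 0.025)
for hardwoods. Beyond the tabulated domain a curve sits on its plateau.

Turnover fractions per year: stems 0.005 → snag stems; other wood 0.04
→ aboveground fast; foliage 0.10 (softwood) or 1.0 (hardwood) →
aboveground very fast; coarse roots 0.02 → belowground fast; fine roots
0.64, split equally between aboveground and belowground very fast.
Turnover is mass conserving (no atmospheric flux).

Decay is first-order with simultaneous update (losses computed on the
pre-step stocks, so an isolated pool follows s·(1−k)ⁿ exactly). Rates
per year: very fast 0.355, fast 0.14, medium 0.037, slow 0.015, snags
0.03. Of each decayed amount, 83% is emitted; the remainder humifies
into the slow pool of its side (aboveground → aboveground slow,
belowground → belowground slow). Slow pools emit 100% of their decay —
the belowground slow pool is terminal. These magnitudes follow the
published European CBM parameter archives; an exact national calibration
is out of scope, and every value is overridable through a structured
config. Climate modifiers on growth or decay are deliberately absent:
the carbon budget at this scale is dominated by management and
disturbance, and climate effects on increment are treated as
quantitatively neutral.

### Disturbance matrices

Eight event types; targets are t C of merchantable carbon except
standing mortality and reforestation, which are area-defined (ha).

| id | event | key transfers |
|----|-------|----------------|
| 2 | thinning | proportional removal of 10–30% of stand biomass (default intensity 20%), ages 20–59; merch → products |
| 3a | salvage with clear-cut | 100% of merch of the affected area → products; 20% of aboveground residues extracted; stand resets to CLEARCUT |
| 3b | salvage without clear-cut | selective removal (≤30% per cohort-year), no stand reset |
| 4 | final cut | 95% of merch → products, 5% seed trees stay live; residue extraction 25%; resets; eligibility age ≥ rotation |
| 5 | clear-cut with slash burn | spinup only: 85% merch → products, 15% falls as coarse debris, slash burned |
| 6 | standing mortality | merch → snag stems, branches → snag branches, stand becomes the standing-dead type (SPx) |
| 7 | snag harvest | snag stemwood → products |
| 8 | reforestation | age-0 cohorts per replanting composition, DOM inherited per hectare |

Felled residues route: branches/stumps → medium DOM, foliage →
aboveground very fast, coarse roots → belowground fast, fine roots split
between the very fast pools. Burn fractions for 3a/4 default to zero
(configurable); no value is documented for them. Every source row of
every matrix sums to one, and every applied event closes its mass
balance (retained + products + extracted residues + atmosphere = before)
to 1e-9 relative — both are tested, the latter over randomized cohorts.

Salvage (3a/3b) and mortality events only attack stands of age ≥ 40:
bark beetles infest mature spruce, and newly replanted stands are not
yet susceptible. Final-cut eligibility is age ≥ rotation (100 yr
conifers, 120 yr broadleaves by default); the underlying event tables
prescribe minimum ages without printing values, so these are defaults,
not calibrations.

### Standing dead spruce and the snag backlog

Stands that die unprocessed (insufficient logging capacity) become the
SPx type: merchantable carbon sits in the snag stem pool and does not
grow. In the year after their creation, 90% of the snag stemwood is
harvested (event 7) and the stand is replanted under the sanitary
species-change rule; the remaining 10% is left to decompose. This regime
applies to dead stands created 2017–2021, i.e. executions 2018–2022 with
the one-year delay (the source material dates the executions both
"2018–2021" and "2018–2022"; the window is configurable with this
default). Initial-inventory SPx area is treated as created in 2017.

### DOM spinup

DOM pools start at the fixed point of a historic regime: grow to the
rotation age, clear-cut with slash burn, repeat, until the belowground
slow pool changes by <1e-6 (relative) between cycles; then regrow to
each cohort's inventory age. Live pools always match the inventory
volume; the spinup only fills DOM. Clear-cut cohorts take the
immediately-post-disturbance DOM; SPx cohorts take spruce DOM at their
age plus the standing-mortality conversion of the curve-implied crown
and roots. The historic rotation (spinup return interval) is the same
100/120 yr default; the source does not state one. Convergence is
geometric with ratio (1−k_slow)^rotation ≈ 0.22 per cycle, so ~10 cycles
suffice; the fixed point matches the affine-map closed form
U/(1−(1−k)^R) exactly when upstream pools are made memoryless, which is
the test oracle.

## Scenario engines

Demand is a mapping (year, region, forest type, disturbance type) →
merchantable carbon. 2018–2021 reproduce the observed series verbatim in
every scenario, so the four runs are identical over the known period (a
tested invariant).

**Calamity curve fitting.** Each region's total harvest series 2012–2021
is fitted with v(t) = A·exp(−(t−μ)²/2σ²) by least squares
(deterministic initial guesses A = max, μ = argmax year, σ = 2). The
peak μ is constrained to the observation window: the extrapolation
presumes the episode culminated within the observed years — without this
constraint a region still rising in 2021 extrapolates an unbounded
future pulse. An all-zero series yields a flagged zero-amplitude fit.

**Sustainable logging potential.** Per (region, type): the merchantable
carbon of final-cut-eligible stands is amortised over a 20-yr planning
window, with stands reaching rotation inside the window prorated by the
eligible fraction of the window (sustained-yield smoothing — this keeps
the potential continuous and non-decreasing on a growing stock, which is
tested on the default state); thinning contributes one intensity per
10-yr interval over the in-window thinnable share, capped at the
increment carbon so thinning never draws down stock. The potential-regime
demand splits each type's potential as 15% salvage-with-clear-cut, 10%
selective salvage, 25% thinning, 50% final cut — the sanitary share
(25%) honours the rule that sanitary logging stays below one-third of
the total under ordinary planned management. The split is scaled down
nationally so total demand never exceeds the scenario's removal target
(17 Mm³/yr Green, 16 Mm³/yr otherwise); potential below the target is
used as-is.

**Green** (optimistic, old-growth retention): 2022–2029 regional totals
= max(fitted curve, potential-regime floor), split over (type, event)
cells by exponential interpolation of the volume shares between the 2021
observation and the potential-regime structure, s(t) =
s₀(s₁/s₀)^((t−2021)/10), renormalised, with zero shares floored at 1e-6;
from 2030 the demand equals the sustainable potential at an annual time
step, recomputed from the current state. From 2025, healthy stands of
age ≥120 (conifers) / ≥140 (broadleaves) are flagged retained and
excluded from salvage and final cut.

**Red**: each region keeps its observed 2021 demand per (type, event)
until its configured episode end-year (2021–2047), then switches to the
potential regime. The alternative trigger "harvest limit of mature
spruce reached" is not quantified in the source; exhaustion of eligible
spruce surfaces as allocation deficit instead of a second switch.

**Black**: as Red, with spruce sanitary demand ×1.2 in the
calamity-spread regions.

**Black rep.**: as Black, plus two-year episodes every ten years from
2038 (2038/39, 2048/49, 2058/59, 2068/69). During an episode all spruce
harvest is sanitary at the mean of the 2018 and 2019 observed spruce
harvest volumes; between episodes spruce follows the potential. Planned
demand (thinning, final cut) of species other than fir and spruce is
multiplied by 1.10 / 1.15 / 1.20 in 2038–47 / 2048–57 / 2058–70. "End of
the 2030s" for the first episode is fixed at 2038, consistent with the
escalation periods.

**Allocation** fills, per year and region: salvage-with-clear-cut, then
selective salvage, then standing mortality, then thinning, then final
cut. Within a cell, eligible non-retained cohorts are taken oldest
first (a proxy for the most vulnerable, highest-volume stands; no
intra-type ordering is prescribed by the source). Events are clipped to
availability; deficit = demand − allocated, exactly, and is data rather
than an error. Cleared spruce areas are replanted in the same year:
sanitary clearings as 20% beech, 30% the region's enhanced species (fir
or oak by the regional metadata), 10% the other of the two, 20%
long-lived and 20% short-lived broadleaves; final-cut clearings as 50%
spruce, 10% fir, 20% beech, 20% long-lived broadleaves. Non-spruce
origins are replanted to their own type. Seed trees (5% of final-cut
merch) remain as a live per-hectare residual carried into the replanted
cohorts — carbon-identical to a separate cohort and simpler to book.
Initial clear-cut area in the inventory (recent calamity clearings) is
replanted in the first simulated year under the sanitary rule.

After each year, cohorts with identical (region, type, age, flags) are
merged area-weighted; this conserves carbon and area exactly and keeps
the cohort count bounded (~1 200 initial, ~3 000 by 2070).

## Synthetic data

The generator emulates the documented national structure, not any real
regional dataset:

- 14 regions with their real areas, forest-cover shares, mean altitudes
  (286–684 m), enhanced replanting species, episode end-years
  (2021–2047) and spread flags;
- forest-type area shares SP 0.496, PI 0.202, BE 0.086, OA 0.074,
  LLB 0.061, SLB 0.053, AA 0.014, CLEARCUT 0.012, SPx 0.002 on a
  2 610 kha total, allocated to whole hectares by largest remainder so
  the total is exact; the regional spruce share scales with
  altitude^1.5, reflecting the habitat gradient;
- ages at 10-yr class midpoints with weights (2,4,6,8,9,9,8,6,4,3,2,1)
  over classes 0–11, favouring classes 3–6 as in the pre-calamity
  national age structure (the exact distribution is not public);
- Chapman–Richards yield curves v(a) = Vmax(1−e^(−ka))^p with per-type
  shapes; asymptotes are calibrated so the area-weighted spruce NAI on
  this age structure is 11 m³/ha/yr and the type volume shares match the
  documented column (SP 59.5%, …). Inventory volumes lie exactly on the
  curves;
- harvest series 2012–2021: a 15.5 Mm³ planned baseline distributed by
  standing volume (split 25% thinning, 50% final cut, 15%/10% the two
  salvage types), plus a regional Gaussian spruce-sanitary pulse whose
  peak year (2019–2021) and width follow the episode end-years. Planned
  harvest is crowded out as exp(−pulse/baseline), and the pulse scale is
  solved (Brent root find) so the 2020 national total is 35.8 Mm³ —
  yielding a ≈95% sanitary share at the peak. 8% of the 2018–2021 pulse
  is reported as unprocessed standing mortality. Multiplicative Gaussian
  noise (sd 5%) is applied with the given seed; everything else is
  deterministic from the config.

**What the synthetic world does not reproduce.** Calibrating NAI = 11
m³/ha/yr on this (fairly old) age structure forces a mean standing stock
of ≈440 m³/ha — roughly 1.6× the real national density — because any
monotone yield curve integrates the increment over age. Absolute carbon
stocks, emission levels and recovery percentages therefore differ from
the national projections (which would require the non-public inventory
and the national model calibration); e.g. the simulated calamity-period
emissions are several times the reported ones. What the tests assert are
the structural and relational results: the exact accounting arithmetic,
the inventory shares, the calamity-peak harvest structure, conservation
laws, and the qualitative scenario orderings (sink timing, 2070 spruce
shares, recurrence emission peaks, growing deficit share). Passing them
shows the machinery and the scenario logic are right, not that the
national magnitudes are reproduced.

## Numerical choices

- Spinup tolerance 1e-6 relative on the belowground slow pool, cycle cap
  200 (non-convergence is an error with the last residual).
- Curve fitting: scipy least squares with bounds A ≥ 0, μ within the
  observation window, σ ∈ [0.05, 50].
- Allocation determinism: demand cells and cohort orderings are fully
  sorted (age descending, then area); reruns are bit-identical, and the
  run-level seed only labels the inputs.
- Tiny negative pool values from float cancellation (<1e-9) are clamped
  to zero after validated transfers.
- Share interpolation floors zero shares at 1e-6 before taking the
  geometric path, then renormalises.
- Degenerate inputs: empty stand tables load to an empty state; zero
  demand produces no events; an all-zero harvest series fits to a
  flagged zero-amplitude pulse.

## Problem sizes

The default configuration runs ~1 200 cohorts over 53 years; spinup
takes well under a second (grouped by forest type and age), one scenario
≈10 s and the full four-scenario pipeline with reporting ≈1 min on one
CPU. The two-region, three-type mini preset used by the unit tests runs
the same pipeline in ~3 s. These sizes are the package's chosen desk
scale: large enough for the regional demand/allocation structure to
matter, small enough to iterate on.

## Known limitations

- Harvested-wood-product pools are not modelled; HWP and afforestation
  enter only as exogenous scalar offsets in the accounting arithmetic.
- No spatial contagion of beetle spread — regional demand scaling is the
  only spread mechanism, as in the source scenarios.
- Species-specific allometry is reduced to two wood-class parameter
  sets; national biomass functions are out of scope.
- The Red/Black regime switch uses the configured end-years rather than
  an endogenous mature-spruce exhaustion criterion.
- Merged cohorts lose within-key heterogeneity (area-weighted pooling);
  carbon and area are conserved exactly.
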