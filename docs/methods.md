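# Methods

## Scope and philosophy

`graspasim` implements the *management* science of grassland carrying
capacity — harvest rules, stocking-rate optimization, adaptive herd
adjustment, factorial trend attribution and regional evaluation — on top of a
deliberately minimal daily grass-growth substrate. The substrate is a
contract, not a contribution: any model producing daily NPP and shoot biomass
that responds positively to light, temperature (up to an optimum), CO2 and
nitrogen addition, and negatively to water stress, can replace the default
implementation behind the same interface. Everything downstream of the
substrate (thresholds, balances, optimization, adaptation, attribution
arithmetic) is exact bookkeeping and is tested as such.

## Growth substrate

State per cell: shoot biomass and root biomass (kg DM ha⁻¹), a bucket soil
water store (mm), and an annual NPP accumulator (g C m⁻²). Leaf area index is
diagnosed from shoot carbon via the maximum specific leaf area
(LAI = SLA_max · C_shoot). Dry matter is 45% carbon; 1 g C m⁻² = 10 kg C ha⁻¹
(both constants configurable).

Daily gross photosynthesis:

    GPP = min(A_light, A_rubisco) · f_T · f_W · f_CO2 · f_h

- A_light = LUE · (Jmax/110) · PAR · (1 − e^(−k·LAI)), with PAR = 0.48 of
  shortwave, k = 0.5, and LUE = 1.0 g C MJ⁻¹ at the standard Jmax.
- A_rubisco = 0.20 · Vcmax · (1 − e^(−k·LAI)) g C m⁻² d⁻¹.
- f_T = clip(1 − ((T − 18)/20)², 0, 1): zero below −2 °C and above 38 °C,
  optimum 18 °C — a temperate C3 grass.
- f_W = clip(W / (0.4·W_cap), 0, 1): stress below 40% of the 150 mm bucket.
- f_CO2 = (C/(C+K)) / (380/(380+K)), K = 300 ppm: saturating, normalized to 1
  at 380 ppm.
- f_h = 0.7 + 0.3·RH: a mild vapor-deficit surrogate.

Autotrophic respiration is 25% of GPP (growth) plus maintenance at 1%/day of
live carbon (shoot + half of root), Q10 = 2 around 18 °C. Positive NPP is
allocated 60:40 shoot:root; deficits are paid from root reserves first, then
shoot. Shoot senesces at 1%/day (plus 3%/day below 0 °C), roots at ~1/yr.
When the shoot falls below 500 kg DM ha⁻¹ and conditions permit growth, 2%/day
of root reserves mobilize to the shoot — the spring-regrowth/tillering pathway
without which an overwintered or heavily defoliated sward could never
recover. Evapotranspiration scales with radiation, canopy cover and
temperature, capped by supply.

The nitrogen effect is the saturating response
N_add = N_addmax (1 − a^(N_amount/30)) applied multiplicatively to both
Vcmax_opt and Jmax_opt as (1 + N_add); N_add is recomputed annually from that
year's total input (organic + mineral + deposition). Defaults a = 0.75,
N_addmax = 0.6, so capacity saturates 60% above base. Legume N fixation, a
prognostic N cycle, SLA or allocation responses to N are not modeled.

**Calibration.** The free constants (LUE, Rubisco rate, respiration,
turnover) were set in one pass so that a moderately fertilized temperate cell
produces annual NPP of roughly 500–700 g C m⁻² with cut yields of 4–6 t DM
ha⁻¹ and 3–4 cuts per year, a Mediterranean cell is water-limited, and a cold
cell season-limited — the magnitudes reported for managed European
grasslands. No constant was adjusted against any test outcome afterwards.

## Management rules

Each cell is an idealized self-sufficient grass-fed farm; a parcel is either
cut or grazed for the whole year (no mixed use).

- **Mowing**: whenever shoot biomass exceeds the trigger (2000 kg DM ha⁻¹)
  everything above the residual stubble (500) is harvested; a salvage cut at
  year end recovers anything above residual + 50. The trigger/residual pair
  was chosen to yield ~2–4 cuts per year under favorable forcing.
- **Grazing**: daily ingestion is min(IC·S, biomass above 300 kg DM ha⁻¹),
  with IC = 13 kg DM LSU⁻¹ d⁻¹. Grazing stops below 300 and resumes only
  after 15 consecutive days above it. Trampling/defoliation losses are one
  use-efficiency factor: ingestion is 70% of the biomass removed from the
  sward; the remainder is lost to litter. Applied to total shoot biomass.
- **Ledger**: every simulated year closes an exact mass balance
  (initial + grown − senesced − harvested − removed = final), property-tested
  to 1e-6 relative.

**Indoor period.** Two definitions coexist deliberately. The diagnostic
`indoor_period` is 365 minus the longest run of days with positive
(5-day-smoothed) shoot growth. The farm balances (optimizer and adaptive
rule) instead use the *animal-centric* indoor period: 365 minus the days
grazing is actually permitted. The two differ by the spring start-up delay
(biomass must exceed 300 kg DM ha⁻¹ for 15 days before grazing resumes);
using the growth-trace definition in the balances would make the grazing
balance structurally infeasible in marginal cells, whereas the animal-centric
one keeps the winter-feed and grazing balances mutually consistent with the
year-end adaptive bookkeeping.

## Stocking-rate optimization

Given mean cut yield Y_cut (computed once per cell — cut land carries no
animals) and the grazed-yield response Y_graze(S), the solver finds the
largest S whose herd can be fully fed from grazing during the grazable
season, then solves the grazed fraction from the winter-feed balance
F = Y_cut / (IC·T_farm·S + Y_cut); D_opt = S·F. Numerics: geometric sweep
(×1.25) to bracket, then bisection; the default feasibility slack is 2% of
the seasonal demand (1e-6 for analytic yield functions). Simulated yields are
measured after one warm-up management cycle and averaged over two measuring
cycles, because grazing suspensions near carrying capacity settle into
multi-year limit cycles that bias a single-cycle sample by a few percent.
Degenerate cells (no grazable season, or no cut forage with a nonzero indoor
period) return S = F = D = 0. An exhaustive (S, F)-lattice search over both
balance inequalities serves as an independent oracle in the tests.

## Adaptive density

At each year end the farm compares conserved forage X' = Y_cut(1−F) with
indoor demand X = IC·T_farm·S·F and realizes a fraction α of the maximal
density change: ΔD = α (X'−X)/IC/365, applied at fixed S by moving F
(overflow past F = 1 raises S; density floors at 0). α = 0.2 corresponds to
responding to a ~5-year mean productivity rather than to single-year
anomalies; the update itself is the literal single-year rule scaled by α, not
a windowed mean. With stationary yields the iteration contracts geometrically
(factor ≈ 1 − α when cut and grazed flows are comparable), so a ±20%
perturbation relaxes to within 1% of the re-optimized density in well under
25 years.

## Experiment protocol

Spin-up (E1) recycles the first decade of forcing at the period-start CO2
until the plant-carbon pool balance — the proxy for long-term net ecosystem
exchange in a model without prognostic soil carbon — changes by less than
1 g C m⁻² yr⁻¹ per recycle loop. E2 establishes reference S_opt/F_opt with
the optimizer; E3 runs a historical transient with adaptive management; E4
the analysis transient. E5–E7 branch from E3's end state and are identical to
E4 except one driver held at its analysis-start level: CO2 (E5), climate
(E6, recycling the first five analysis years), nitrogen (E7). Productivity is
the annual cut yield per hectare of mown grassland (t DM ha⁻¹ yr⁻¹),
area-weighted over cells; trends are OLS slopes with t-test p-values
(constant series: slope 0, p = 1 by convention). Driver contributions are
trend differences T_E4 − T_Ei with percentages relative to T_E4; the drivers
are not independent, so percentages may exceed 100% in total.

Desk-scale defaults: a 10×10 grid, 10 spin-up + 10 historical + 50 analysis
years; the full chain runs in well under a minute per configuration.

## Parameter ensemble

Four factors at two levels each — the response-shape constant a, the
asymptote N_addmax, the capacities Vcmax/Jmax (perturbed jointly, preserving
the 1:2 ratio), and SLA_max — give 2⁴ = 16 member configurations. Levels are
±20% of the standard value, except N_addmax at ±0.20 absolute. Uncertainty of
any output is the sample standard deviation (ddof = 1) across members.

## Synthetic forcing

365-day years, no leap days. Temperature is a sinusoid (minimum mid-January)
plus AR(1) noise (ρ = 0.7, SD 2 °C); precipitation a Bernoulli–gamma wet/dry
process; shortwave follows day-of-year solar geometry at the cell latitude,
damped on wet days; humidity is higher on wet days. Per-zone defaults (cold
4 °C/11 °C amplitude, temperate 9/9, Mediterranean 15/8, wet-day
probabilities 0.45/0.42/0.22) give cold season-limited, temperate favorable
and Mediterranean drought-limited grasslands. Climate zones are latitude
bands standing in for a Köppen classification. CO2 starts at 296 ppm (the
~1900 level) with linear or exponential growth. Nitrogen reconstruction:
organic fertilizer constant; mineral zero before 1951, ramping linearly from
1/10 of the reference rate in 1951 to the full 1961 level, then following a
scaling series; deposition factors interpolate linearly between decadal
anchors placed at decade *midpoints* (anchor placement is not standardized;
the midpoint reading treats each decadal value as that decade's mean).

What the generator does *not* emulate: real geography and orography, spatial
correlation of weather between cells, multi-day synoptic structure beyond
AR(1), observed CO2/N trajectories, or land-use change. Passing tests
therefore demonstrate the internal consistency and qualitative responses of
the management chain, not agreement with any specific observed region.

## Regional evaluation

Head counts convert to livestock units (1 dairy cow = 1 LSU, heifer/beef
0.8, sheep/goat 0.1). The observed grass-fed herd is the diet-fraction
weighted sum over species; the simulated herd combines the area-weighted
regional density D_reg with grassland areas by type, supported at 100%
(temporary), 80% (permanent) and 10% (rough grazing) of D_reg. Diet
fractions are user-supplied per region. Agreement metrics: Pearson r with
two-sided p (optionally after linear detrending, for interannual-variability
comparisons), CV = 100·SD/mean (sample SD), and a through-origin regression
slope Σ(m·o)/Σ(o²) with uncentred R². Normalized series comparisons divide
by the series mean over the window. No multiple-testing correction is
applied.

## Numerical and design choices

- Winter-balance time constant: the "(1 − T_farm)" factor of the grazing
  balance is read as (365 − T_farm) days, for dimensional consistency with
  the IC·T_farm winter term.
- Optimizer tie-break: the bisection returns the largest feasible S; at a
  plateau of D this is the infimum of the infeasible set.
- Spin-up tolerance 1 g C m⁻² yr⁻¹; the pools relax within a few recycle
  loops because turnover times are short (no slow soil pool).
- `update_farm` keeps D continuous on overflow by raising S once F hits 1.
- Pools are floored at zero; herd extinction (D → 0) is allowed and sticky
  only while forage deficits persist.
- Seeds: every stochastic component takes an explicit seed; identical seeds
  give bit-identical forcing and outputs.

## Known limitations

- No soil carbon or energy balance; NEE equilibrium is a plant-pool proxy.
- No mixed cut-then-graze use of one parcel within a year.
- No inter-cell forage trade, economics, soil pH/phosphorus limits or
  palatability effects; the simulated density is a biological potential and
  exceeds actual densities where those factors bind.
- The CO2 and temperature responses are smooth aggregates; no acclimation.
- Zone assignment by latitude band ignores continentality and orography.
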