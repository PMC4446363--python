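# graspasim

Grassland carrying-capacity simulation: how many grass-fed livestock can a
hectare of European-style grassland support, and how does that capacity
respond to rising CO2, climate variability and nitrogen fertilization?

`graspasim` is aimed at agroecosystem modellers who want the management layer
of a grassland model — mowing, grazing, stocking-rate optimization, adaptive
herd adjustment, trend attribution — as a self-contained, testable package
that runs on seeded synthetic forcing, with no data downloads.

## The model

A minimal daily grass-growth substrate supplies net primary productivity and
shoot biomass per cell: gross photosynthesis is the minimum of a
light-limited (Jmax) and a Rubisco-limited (Vcmax) canopy rate, scaled by a
parabolic temperature optimum, a bucket-soil water-stress factor and a
saturating CO2 response normalized to 1 at 380 ppm. Annual nitrogen addition
N_amount (fertilizer + deposition, kg N ha⁻¹ yr⁻¹) raises photosynthetic
capacity through a saturating response,

    N_add  = N_addmax (1 − a^(N_amount/30)),        a = 0.75, N_addmax = 0.6
    Vcmax_opt = (1 + N_add) Vcmax_opt*,   Jmax_opt = (1 + N_add) Jmax_opt*

so capacity saturates ~60% above its base value under very high N supply.

Management idealizes each cell as a self-sufficient grass-fed farm. Mown land
is harvested above a trigger biomass (residual stubble left standing); grazed
land feeds S LSU ha⁻¹ at intake capacity IC = 13 kg DM LSU⁻¹ d⁻¹, with
grazing suspended below 300 kg DM ha⁻¹ and resumed only after 15 days of
recovery. The optimal stocking rate S_opt, grazed fraction F_opt and
potential density D_opt = S_opt·F_opt solve the two balances

    IC · T_farm · S_opt · F_opt = Y_cut (1 − F_opt)        (indoor feed)
    IC · (365 − T_farm) · S_opt = Y_graze(S_opt)           (grazing season)

by a geometric sweep plus bisection, verified against an exhaustive lattice
oracle. Year to year, a farmer adjusts density by a fraction α = 0.2 of the
maximal change implied by the cut-forage surplus or deficit
(ΔD = α·ΔM/IC/365), the moderate-risk response to a ~5-year mean
productivity. A factorial protocol (spin-up, reference optimization,
historical and analysis transients, plus runs with CO2, climate or nitrogen
held fixed) attributes the productivity trend to each driver, and a 2⁴
parameter ensemble (a, N_addmax, Vcmax/Jmax, SLA_max at ±20%) quantifies
parametric uncertainty. A regional-evaluation module aggregates densities to
regions and compares observed vs simulated grass-fed herd sizes.

## Worked example

```python
import numpy as np
from graspasim.synthetic_forcing import generate_grid, generate_meteo
from graspasim.grass_growth import (GrassState, GrowthParams,
                                    PhotosynthesisParams,
                                    effective_photosynthesis_params,
                                    nitrogen_response)
from graspasim.management import ManagementParams, YearForcing
from graspasim.experiments import spinup
from graspasim.farm_optimizer import optimize_cell_batch

grid = generate_grid(1, 3, seed=1, lat_range=(57.0, 60.0))   # cold zone
meteo = generate_meteo(grid, 1, seed=2)
pp, gp, mp = PhotosynthesisParams(), GrowthParams(), ManagementParams()
n_add = nitrogen_response(60.0, pp)            # 60 kg N/ha/yr
vc, jm = effective_photosynthesis_params(pp, n_add)
forcing = [YearForcing.from_meteo(meteo, 0, 380.0, vc, jm)]

state = GrassState.initial(3, shoot=800.0)
eq = spinup(state, forcing, pp, gp, tol=1.0)
farms = optimize_cell_batch(eq.state.copy(), forcing, pp, gp, mp)
for i, f in enumerate(farms):
    print(f"cell {i}: S_opt={f.s_opt:.2f} LSU/ha, F_opt={f.f_opt:.2f}, "
          f"D_opt={f.d_opt:.2f} LSU/ha, Y_cut={f.y_cut:.0f} kg DM/ha")
```

prints

```
cell 0: S_opt=1.56 LSU/ha, F_opt=0.56, D_opt=0.87 LSU/ha, Y_cut=4600 kg DM/ha
cell 1: S_opt=1.32 LSU/ha, F_opt=0.63, D_opt=0.82 LSU/ha, Y_cut=4552 kg DM/ha
cell 2: S_opt=1.55 LSU/ha, F_opt=0.57, D_opt=0.89 LSU/ha, Y_cut=4567 kg DM/ha
```

i.e. each hectare of this cold-zone grassland can feed ~0.8–0.9 LSU when
roughly 60% of the land is grazed in season and the remaining 40% is mown
(~4.6 t DM ha⁻¹ yr⁻¹) for winter feed.

A command-line interface wraps the same functions:

```bash
graspasim gen-forcing --years 10 --nlat 4 --nlon 4 --seed 1 --out forcing/
graspasim optimize --seed 1 --out optimize_out/
graspasim run --seed 1 --out run_out/
graspasim ensemble --out ensemble.csv
```

Every subcommand writes a JSON run manifest (config, seed, outputs) so runs
can be reproduced bit-identically.

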