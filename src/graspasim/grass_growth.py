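"""Minimal daily grass carbon/biomass dynamics.

The management layer (mowing, grazing, stocking-rate optimization) only needs
a substrate that produces daily net primary productivity and shoot biomass
responding positively to light, temperature, CO2 and nitrogen addition, and
negatively to soil-water stress.  This module provides such a substrate: a
big-leaf canopy whose gross photosynthesis is the minimum of a light-limited
(electron-transport, Jmax) and a Rubisco-limited (Vcmax) rate, modulated by a
piecewise-optimum temperature response, a bucket-soil water-stress factor, a
saturating (Michaelis-type) CO2 response normalized to 1 at 380 ppm, and a
humidity factor.  Nitrogen addition acts through a saturating response N_add
that multiplies both photosynthetic capacity parameters by (1 + N_add).

It is deliberately not a full land-surface scheme: any implementation with
the same qualitative responses can replace it behind the same interface.

Units: biomass pools in kg DM ha-1, carbon fluxes in g C m-2 d-1, water in
mm.  Dry matter is 45% carbon by mass; 1 g C m-2 = 10 kg C ha-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CARBON_FRACTION = 0.45          # g C per g DM
KG_HA_PER_G_M2 = 10.0           # 1 g/m2 = 10 kg/ha
#: kg DM ha-1 equivalent to 1 g C m-2
KGDM_HA_PER_GC_M2 = KG_HA_PER_G_M2 / CARBON_FRACTION

N_HALF_SAT_RATE = 30.0          # kg N ha-1 yr-1 scale of the saturating curve
CO2_REFERENCE_PPM = 380.0


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Photosynthetic capacity and its nitrogen response.

    vcmax_opt_base  maximum Rubisco carboxylation rate at zero N addition
                    (umol m-2 s-1)
    jmax_opt_base   maximum electron transport rate at zero N addition
                    (umol m-2 s-1)
    sla_max         maximum specific leaf area (m2 per g C)
    a               shape constant of the saturating nitrogen response, in (0,1)
    n_addmax        asymptote of the nitrogen response (fractional capacity
                    increase at very high N supply), in (0,1]
    """

    vcmax_opt_base: float = 55.0
    jmax_opt_base: float = 110.0
    sla_max: float = 0.048
    a: float = 0.75
    n_addmax: float = 0.6

    def __post_init__(self) -> None:
        for name in ("vcmax_opt_base", "jmax_opt_base", "sla_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"a must be in (0,1), got {self.a}")
        if not 0.0 < self.n_addmax <= 1.0:
            raise ValueError(f"n_addmax must be in (0,1], got {self.n_addmax}")


@dataclass(frozen=True)
class GrowthParams:
    """Constants of the growth substrate (defaults calibrated to temperate
    European grassland magnitudes: annual NPP of order 500 g C m-2 and cut
    yields of up to ~10 t DM ha-1 under favorable forcing)."""

    lue: float = 1.0             # g C per MJ absorbed PAR at standard Jmax
    vcmax_rate: float = 0.20     # g C m-2 d-1 per (umol m-2 s-1) Vcmax at full canopy
    k_ext: float = 0.5           # canopy light-extinction coefficient
    par_fraction: float = 0.48   # PAR fraction of shortwave
    t_opt: float = 18.0          # degC optimum of the temperature response
    t_width: float = 20.0        # degC half-width of the parabolic response
    co2_half_sat: float = 300.0  # ppm Michaelis constant of the CO2 response
    growth_resp_frac: float = 0.25
    maint_resp_rate: float = 0.010   # d-1 of live carbon at t_opt
    q10: float = 2.0
    alloc_shoot: float = 0.6     # shoot fraction of positive NPP
    shoot_turnover: float = 0.010  # d-1 background senescence
    cold_turnover: float = 0.030   # extra d-1 below 0 degC
    root_turnover: float = 0.0027  # d-1 (~1/yr)
    soil_cap_mm: float = 150.0
    stress_frac: float = 0.4     # stress sets in below this fraction of capacity
    pet_scale_mm: float = 3.5    # mm/d at reference radiation, full canopy
    regrow_threshold: float = 500.0  # kg DM ha-1 shoot below which reserves mobilize
    regrow_frac: float = 0.02    # d-1 of root reserves moved to shoot in spring


@dataclass
class GrassState:
    """Per-cell daily state acted on by the management rules (vector over
    cells)."""

    shoot: np.ndarray        # kg DM ha-1
    root: np.ndarray         # kg DM ha-1
    soil_water: np.ndarray   # mm
    annual_npp: np.ndarray   # g C m-2 accumulated since last reset

    @classmethod
    def initial(cls, n_cells: int, shoot: float = 500.0, root: float = 500.0,
                water: float = 100.0) -> "GrassState":
        full = np.full
        return cls(full(n_cells, shoot, float), full(n_cells, root, float),
                   full(n_cells, water, float), np.zeros(n_cells))

    def copy(self) -> "GrassState":
        return GrassState(self.shoot.copy(), self.root.copy(),
                          self.soil_water.copy(), self.annual_npp.copy())

    def lai(self, params: PhotosynthesisParams) -> np.ndarray:
        """Leaf area index from shoot biomass via SLA (m2 m-2)."""
        shoot_c = self.shoot * CARBON_FRACTION / KG_HA_PER_G_M2  # g C m-2
        return params.sla_max * shoot_c

    def total_carbon(self) -> np.ndarray:
        """Plant carbon stock, g C m-2."""
        return (self.shoot + self.root) / KGDM_HA_PER_GC_M2

    def reset_annual(self) -> None:
        self.annual_npp[:] = 0.0


@dataclass
class DailyFluxes:
    """Diagnosed fluxes of one daily step (vector over cells)."""

    gpp: np.ndarray          # g C m-2 d-1
    resp: np.ndarray         # g C m-2 d-1 autotrophic respiration
    npp: np.ndarray          # g C m-2 d-1, = gpp - resp
    senescence: np.ndarray   # kg DM ha-1 d-1 shoot loss
    shoot_alloc: np.ndarray  # kg DM ha-1 d-1 actual shoot increment (may be < 0)
    et: np.ndarray           # mm d-1


def nitrogen_response(n_amount, params: PhotosynthesisParams):
    """Fractional photosynthetic-capacity increase from annual N addition.

    N_add = N_addmax * (1 - a**(N_amount/30)) with N_amount in kg N ha-1 yr-1.
    Monotone non-decreasing, zero at zero addition, saturating at N_addmax.
    """
    n_amount = np.asarray(n_amount, dtype=float)
    if np.any(n_amount < 0):
        raise ValueError("N_amount must be non-negative")
    out = params.n_addmax * (1.0 - params.a ** (n_amount / N_HALF_SAT_RATE))
    return out if out.ndim else float(out)


def effective_photosynthesis_params(params: PhotosynthesisParams, n_add):
    """(Vcmax_opt, Jmax_opt) after the additive nitrogen effect:
    each equals (1 + N_add) times its base value."""
    n_add = np.asarray(n_add, dtype=float)
    if np.any((n_add < 0) | (n_add > params.n_addmax + 1e-12)):
        raise ValueError("N_add outside [0, N_addmax]")
    vc = (1.0 + n_add) * params.vcmax_opt_base
    jm = (1.0 + n_add) * params.jmax_opt_base
    if n_add.ndim == 0:
        return float(vc), float(jm)
    return vc, jm


def co2_response(co2_ppm, gp: GrowthParams):
    """Saturating Michaelis-type CO2 factor, normalized to 1 at 380 ppm."""
    c = np.asarray(co2_ppm, dtype=float)
    k = gp.co2_half_sat
    return (c / (c + k)) * ((CO2_REFERENCE_PPM + k) / CO2_REFERENCE_PPM)


def temperature_response(temp, gp: GrowthParams):
    """Parabolic optimum curve: 1 at t_opt, zero beyond t_opt +/- t_width
    (hence zero below -2 degC for the defaults)."""
    t = np.asarray(temp, dtype=float)
    return np.clip(1.0 - ((t - gp.t_opt) / gp.t_width) ** 2, 0.0, 1.0)


def step_day(
    state: GrassState,
    temp: np.ndarray,
    precip: np.ndarray,
    swdown: np.ndarray,
    rh: np.ndarray,
    co2_ppm: float,
    vcmax: np.ndarray | float,
    jmax: np.ndarray | float,
    pparams: PhotosynthesisParams,
    gp: GrowthParams,
) -> DailyFluxes:
    """Advance the state by one day in place and return the fluxes.

    GPP is min(light-limited, Rubisco-limited) x temperature x water stress x
    CO2 x humidity; NPP = GPP - respiration, allocated 60:40 shoot:root when
    positive and drawn from shoot then root when negative.  Pools never go
    negative.
    """
    for arr in (temp, precip, swdown, rh):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite meteorology")

    lai = state.lai(pparams)
    fapar = 1.0 - np.exp(-gp.k_ext * lai)
    par_mj = np.asarray(swdown) * 86400e-6 * gp.par_fraction

    a_light = gp.lue * (np.asarray(jmax) / 110.0) * par_mj * fapar
    a_rub = gp.vcmax_rate * np.asarray(vcmax) * fapar

    f_t = temperature_response(temp, gp)
    f_w = np.clip(state.soil_water / (gp.stress_frac * gp.soil_cap_mm), 0.0, 1.0)
    f_c = co2_response(co2_ppm, gp)
    f_h = 0.7 + 0.3 * np.asarray(rh)

    gpp = np.minimum(a_light, a_rub) * f_t * f_w * f_c * f_h

    live_c = (state.shoot + 0.5 * state.root) / KGDM_HA_PER_GC_M2
    resp = (gp.growth_resp_frac * gpp
            + gp.maint_resp_rate * live_c
            * gp.q10 ** ((np.asarray(temp) - gp.t_opt) / 10.0) * (f_t > 0))
    npp = gpp - resp
    npp_dm = npp * KGDM_HA_PER_GC_M2

    cold = np.asarray(temp) < 0.0
    senesce = (gp.shoot_turnover + gp.cold_turnover * cold) * state.shoot
    root_sen = gp.root_turnover * state.root

    sh = state.shoot - senesce
    rt = state.root - root_sen
    pos = npp_dm > 0
    alloc_sh = np.where(pos, gp.alloc_shoot * npp_dm, 0.0)
    alloc_rt = np.where(pos, (1 - gp.alloc_shoot) * npp_dm, 0.0)
    # carbon deficits are paid from root reserves first, then shoot
    deficit = np.where(pos, 0.0, -npp_dm)
    from_root = np.minimum(deficit, np.maximum(rt, 0.0))
    from_shoot = np.minimum(deficit - from_root, np.maximum(sh, 0.0))
    # spring regrowth: reserves mobilize to rebuild a defoliated/overwintered
    # sward whenever conditions allow growth at all
    regrow = np.where((sh < gp.regrow_threshold) & (f_t > 0.2) & (f_w > 0.2),
                      gp.regrow_frac * np.maximum(rt - from_root, 0.0), 0.0)
    shoot_alloc = alloc_sh - from_shoot + regrow
    state.shoot = np.maximum(sh + shoot_alloc, 0.0)
    state.root = np.maximum(rt + alloc_rt - from_root - regrow, 0.0)

    pet = (gp.pet_scale_mm * np.asarray(swdown) / 250.0
           * (0.3 + 0.7 * fapar) * np.clip((np.asarray(temp) + 5.0) / 20.0, 0.0, 1.5))
    et = np.minimum(state.soil_water, pet * np.maximum(f_w, 0.1))
    state.soil_water = np.clip(state.soil_water + precip - et, 0.0, gp.soil_cap_mm)

    state.annual_npp += npp
    return DailyFluxes(gpp=gpp, resp=resp, npp=npp, senescence=senesce,
                       shoot_alloc=shoot_alloc, et=et)


def dm_carbon_convert(value, direction: str):
    """Convert between carbon areal density and dry matter.

    ``direction="c_to_dm"``: g C m-2 -> t DM ha-1.
    ``direction="dm_to_c"``: t DM ha-1 -> g C m-2.
    Uses a 0.45 carbon fraction of dry matter and 1 g m-2 = 10 kg ha-1.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("value must be non-negative")
    if direction == "c_to_dm":
        out = v * KG_HA_PER_G_M2 / CARBON_FRACTION / 1000.0
    elif direction == "dm_to_c":
        out = v * 1000.0 * CARBON_FRACTION / KG_HA_PER_G_M2
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return out if out.ndim else float(out)
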