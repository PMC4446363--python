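"""Simulation protocol, trend attribution and the parameter ensemble.

The full experiment chain mirrors a standard land-surface attribution
protocol: a spin-up to carbon equilibrium under recycled early-period
forcing and pre-industrial-era CO2 (E1), a reference optimization of
stocking rate and grazed fraction (E2), a historical transient with the
adaptive-management rule (E3), an analysis transient (E4), and three
factorial runs identical to E4 except that one driver is held at its
analysis-start level: CO2 (E5), climate (E6, recycling the first five
analysis years), or nitrogen inputs (E7).  The trend difference between E4
and each fixed run attributes the productivity trend to that driver.

Parameter uncertainty uses a 2^4 two-level factorial: the nitrogen-response
shape constant a, its asymptote N_addmax, the photosynthetic capacities
Vcmax/Jmax (perturbed jointly), and SLA_max, each at -20%/+20% of the
standard value (N_addmax at +/-0.20 absolute), giving 16 member
configurations whose across-member standard deviation measures the
parametric uncertainty of any output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .adaptive_management import DEFAULT_ALPHA, adapt_year
from .farm_optimizer import FarmOptimum, optimize_cell_batch
from .grass_growth import (
    GrassState,
    GrowthParams,
    PhotosynthesisParams,
    effective_photosynthesis_params,
    nitrogen_response,
    step_day,
)
from .management import (
    ManagementParams,
    YearForcing,
    simulate_cut_year,
    simulate_grazed_year,
    vegetation_window,
)
from .synthetic_forcing import AnnualDrivers, DailyMeteo, ForcingGrid


@dataclass
class ProtocolConfig:
    """Windows and numerical settings of the experiment chain."""

    spinup_years: int = 10           # recycled window length for E1/E2
    spinup_max_loops: int = 60
    equilibrium_tol: float = 1.0     # g C m-2 yr-1 on the carbon-pool balance
    historical_years: int = 10       # E3 length
    analysis_years: int = 50         # E4-E7 length
    climate_recycle_years: int = 5   # E6 recycles this many analysis years
    alpha: float = DEFAULT_ALPHA
    optimizer_years: int = 3         # forcing years averaged in E2
    optimizer_tol: float = 0.02
    attribution: bool = True         # also run E5-E7

    def __post_init__(self) -> None:
        if self.spinup_years < 1 or self.analysis_years < 1:
            raise ValueError("window lengths must be >= 1")


@dataclass
class SpinupResult:
    state: GrassState
    loops: int
    converged: bool
    nee: np.ndarray   # g C m-2 yr-1 pool imbalance of the last loop


def spinup(
    state: GrassState,
    forcings: list[YearForcing],
    pparams: PhotosynthesisParams,
    gparams: GrowthParams,
    tol: float = 1.0,
    max_loops: int = 60,
) -> SpinupResult:
    """Recycle the forcing window until the plant carbon pools equilibrate.

    The equilibrium criterion is the pool-balance proxy for long-term net
    ecosystem exchange: mean annual change of total plant carbon over one
    recycle loop below ``tol`` (g C m-2 yr-1) in every cell.  Raises
    RuntimeError if the criterion is not met within ``max_loops`` (a
    tolerance of zero is unreachable by construction).
    """
    years = len(forcings)
    for loop in range(1, max_loops + 1):
        c0 = state.total_carbon()
        for forcing in forcings:
            for d in range(forcing.temp.shape[0]):
                step_day(state, forcing.temp[d], forcing.precip[d],
                         forcing.swdown[d], forcing.rh[d], forcing.co2,
                         forcing.vcmax, forcing.jmax, pparams, gparams)
        nee = (state.total_carbon() - c0) / years
        if np.all(np.abs(nee) < tol):
            return SpinupResult(state, loop, True, nee)
    raise RuntimeError(
        f"spin-up did not reach |pool balance| < {tol} g C m-2 yr-1 "
        f"within {max_loops} loops (last max |NEE| = {np.abs(nee).max():.3g})")


@dataclass
class TransientResult:
    """Per-year, per-cell outputs of one transient experiment."""

    years: np.ndarray           # calendar years, (n_years,)
    y_cut: np.ndarray           # kg DM ha-1 yr-1, (n_years, n_cells)
    y_graze: np.ndarray
    npp: np.ndarray             # g C m-2 yr-1 on cut land
    d_opt: np.ndarray           # LSU ha-1
    f_opt: np.ndarray
    s_opt: np.ndarray
    t_farm: np.ndarray

    def productivity(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Area-weighted mean cut-grassland productivity, t DM ha-1 yr-1."""
        w = np.ones(self.y_cut.shape[1]) if weights is None else weights
        return (self.y_cut @ w) / w.sum() / 1000.0


def run_transient(
    cut_state: GrassState,
    graze_state: GrassState,
    farms: list[FarmOptimum],
    forcings: list[YearForcing],
    years: np.ndarray,
    pparams: PhotosynthesisParams,
    gparams: GrowthParams,
    mparams: ManagementParams,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[TransientResult, list[FarmOptimum]]:
    """Run consecutive adaptive-management years on a cell batch.

    Cut and grazed parcels of each cell evolve as separate states; at each
    year end the per-cell farm density is adapted from the cut-forage
    surplus or deficit.  Returns the annual records and the final farms.
    """
    n_years, n = len(forcings), cut_state.shoot.size
    out = {k: np.zeros((n_years, n)) for k in
           ("y_cut", "y_graze", "npp", "d_opt", "f_opt", "s_opt", "t_farm")}
    farms = list(farms)
    for i, forcing in enumerate(forcings):
        cut_state.reset_annual()
        graze_state.reset_annual()
        harvest_c, _, trace = simulate_cut_year(cut_state, forcing, pparams,
                                                gparams, mparams)
        window = vegetation_window(trace)
        s_vec = np.array([f.s_opt for f in farms])
        harvest_g, _, _ = simulate_grazed_year(graze_state, forcing, s_vec,
                                               pparams, gparams, mparams,
                                               graze_window=window)
        # indoor period consistent with the optimizer: the year minus the
        # days the herd could actually graze
        t_farm = 365.0 - harvest_g.grazing_days
        out["y_cut"][i] = harvest_c.y_cut
        out["y_graze"][i] = harvest_g.y_graze
        out["npp"][i] = cut_state.annual_npp
        out["t_farm"][i] = t_farm
        out["d_opt"][i] = [f.d_opt for f in farms]
        out["f_opt"][i] = [f.f_opt for f in farms]
        out["s_opt"][i] = [f.s_opt for f in farms]
        farms = [
            adapt_year(f, float(harvest_c.y_cut[c]), float(t_farm[c]),
                       int(years[i]), mparams, alpha)[0]
            for c, f in enumerate(farms)
        ]
    return TransientResult(years=np.asarray(years), **out), farms


def _year_forcings(
    meteo: DailyMeteo,
    meteo_indices: np.ndarray,
    co2: np.ndarray,
    total_n: np.ndarray,
    pparams: PhotosynthesisParams,
) -> list[YearForcing]:
    """Assemble YearForcing objects, applying the nitrogen response of each
    year's total N input to the photosynthetic capacity."""
    forcings = []
    for i, mi in enumerate(meteo_indices):
        n_add = nitrogen_response(total_n[i], pparams)
        vc, jm = effective_photosynthesis_params(pparams, n_add)
        forcings.append(YearForcing.from_meteo(meteo, int(mi), co2[i], vc, jm))
    return forcings


@dataclass
class ProtocolResult:
    spinup: SpinupResult
    reference_farms: list[FarmOptimum]     # E2
    historical: TransientResult            # E3
    analysis: dict[str, TransientResult]   # E4 (+E5-E7 if attribution)


def run_protocol(
    grid: ForcingGrid,
    meteo: DailyMeteo,
    co2: np.ndarray,
    drivers: AnnualDrivers,
    pparams: PhotosynthesisParams,
    gparams: GrowthParams,
    mparams: ManagementParams,
    config: ProtocolConfig,
) -> ProtocolResult:
    """Run the full experiment chain on one forcing set.

    ``meteo``/``co2``/``drivers`` must cover spinup + historical + analysis
    years in that order.  E5-E7 branch from the end state of E3.
    """
    n = grid.n_cells
    n_total = config.spinup_years + config.historical_years + config.analysis_years
    if meteo.n_years < n_total or co2.size < n_total:
        raise ValueError(f"forcing must cover {n_total} years")
    total_n = drivers.total_n
    years = np.arange(n_total)

    spin_idx = np.arange(config.spinup_years)
    spin_forcings = _year_forcings(meteo, spin_idx,
                                   np.full(config.spinup_years, co2[0]),
                                   total_n[spin_idx], pparams)
    state = GrassState.initial(n)
    spin = spinup(state, spin_forcings, pparams, gparams,
                  tol=config.equilibrium_tol, max_loops=config.spinup_max_loops)

    opt_forcings = spin_forcings[:config.optimizer_years]
    farms = optimize_cell_batch(spin.state.copy(), opt_forcings, pparams,
                                gparams, mparams, tol=config.optimizer_tol)

    hist_idx = config.spinup_years + np.arange(config.historical_years)
    hist_forcings = _year_forcings(meteo, hist_idx, co2[hist_idx],
                                   total_n[hist_idx], pparams)
    cut_state, graze_state = spin.state.copy(), spin.state.copy()
    historical, farms_e3 = run_transient(cut_state, graze_state, farms,
                                         hist_forcings, years[hist_idx],
                                         pparams, gparams, mparams,
                                         alpha=config.alpha)
    e3_end = (cut_state, graze_state, farms_e3)

    ana_idx = (config.spinup_years + config.historical_years
               + np.arange(config.analysis_years))
    variants: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {
        "E4": (ana_idx, co2[ana_idx], total_n[ana_idx]),
    }
    if config.attribution:
        recyc = ana_idx[np.arange(config.analysis_years)
                        % config.climate_recycle_years]
        variants["E5"] = (ana_idx, np.full(ana_idx.size, co2[ana_idx[0]]),
                          total_n[ana_idx])
        variants["E6"] = (recyc, co2[ana_idx], total_n[ana_idx])
        variants["E7"] = (ana_idx, co2[ana_idx],
                          np.broadcast_to(total_n[ana_idx[0]],
                                          (ana_idx.size, n)))
    analysis = {}
    for name, (midx, co2_v, n_v) in variants.items():
        forcings = _year_forcings(meteo, midx, co2_v, n_v, pparams)
        cs, gs = e3_end[0].copy(), e3_end[1].copy()
        res, _ = run_transient(cs, gs, list(e3_end[2]), forcings,
                               years[ana_idx], pparams, gparams, mparams,
                               alpha=config.alpha)
        analysis[name] = res
    return ProtocolResult(spin, farms, historical, analysis)


@dataclass
class TrendResult:
    slope: float             # units of the series per year
    percent_per_year: float  # 100 * slope / series mean
    p_value: float


def trend(series: np.ndarray, years: np.ndarray | None = None) -> TrendResult:
    """OLS trend of an annual series with a two-sided p-value.

    A constant series returns slope 0 with p = 1 by convention.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValueError("trend needs at least 3 years")
    x = np.arange(y.size, dtype=float) if years is None else np.asarray(
        years, dtype=float)
    if np.ptp(y) == 0.0:
        return TrendResult(0.0, 0.0, 1.0)
    fit = stats.linregress(x, y)
    mean = y.mean()
    pct = 100.0 * fit.slope / mean if mean != 0 else np.nan
    return TrendResult(float(fit.slope), float(pct), float(fit.pvalue))


@dataclass
class AttributionResult:
    """Factorial decomposition of the E4 productivity trend."""

    t_e4: float
    t_e5: float
    t_e6: float
    t_e7: float
    co2_contribution: float       # T_E4 - T_E5, same units as the trends
    climate_contribution: float   # T_E4 - T_E6
    nitrogen_contribution: float  # T_E4 - T_E7
    co2_percent: float
    climate_percent: float
    nitrogen_percent: float
    total_contribution: float
    total_percent: float


def attribute(t_e4: float, t_e5: float, t_e6: float, t_e7: float) -> AttributionResult:
    """Attribute the E4 trend to CO2, climate and nitrogen.

    Contribution of a driver is the trend difference between E4 and the run
    with that driver fixed; percentages are relative to T_E4.  The three
    drivers are not independent, so the total may exceed 100%.
    """
    if t_e4 == 0.0:
        raise ValueError("T_E4 is zero; percentage attribution undefined")
    c_co2, c_cli, c_n = t_e4 - t_e5, t_e4 - t_e6, t_e4 - t_e7
    pct = lambda c: 100.0 * c / t_e4
    total = c_co2 + c_cli + c_n
    return AttributionResult(t_e4, t_e5, t_e6, t_e7, c_co2, c_cli, c_n,
                             pct(c_co2), pct(c_cli), pct(c_n), total,
                             pct(total))


ENSEMBLE_FACTORS = ("a", "n_addmax", "capacity", "sla_max")


@dataclass
class EnsembleDesign:
    """Two-level factorial design over the four uncertain parameters."""

    standard: PhotosynthesisParams
    levels: dict[str, tuple[float, float]]        # factor -> (min, max)
    members: list[PhotosynthesisParams]           # 16 configs
    signs: list[tuple[int, ...]]                  # 0=min, 1=max per factor


def build_ensemble(standard: PhotosynthesisParams) -> EnsembleDesign:
    """All 2^4 = 16 combinations of min/max parameter levels.

    a, Vcmax/Jmax (jointly) and SLA_max vary by +/-20% of their standard
    values; N_addmax by +/-0.20 absolute.
    """
    levels = {
        "a": (standard.a * 0.8, standard.a * 1.2),
        "n_addmax": (standard.n_addmax - 0.2, standard.n_addmax + 0.2),
        "capacity": (0.8, 1.2),   # joint multiplier on Vcmax and Jmax
        "sla_max": (standard.sla_max * 0.8, standard.sla_max * 1.2),
    }
    members, signs = [], []
    for combo in itertools.product((0, 1), repeat=4):
        a, nmax, cap, sla = (levels[f][s]
                             for f, s in zip(ENSEMBLE_FACTORS, combo))
        members.append(replace(standard, a=a, n_addmax=nmax,
                               vcmax_opt_base=standard.vcmax_opt_base * cap,
                               jmax_opt_base=standard.jmax_opt_base * cap,
                               sla_max=sla))
        signs.append(combo)
    return EnsembleDesign(standard, levels, members, signs)


def ensemble_sd(member_values: np.ndarray, axis: int = 0) -> np.ndarray:
    """1-sigma spread of an output across ensemble members (sample SD)."""
    vals = np.asarray(member_values, dtype=float)
    return np.std(vals, axis=axis, ddof=1)
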