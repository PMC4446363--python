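"""Mowing and grazing rules on the grass-growth substrate.

Two mutually exclusive uses of a parcel within a year are simulated: cut
grassland, harvested whenever standing shoot biomass exceeds a trigger
(leaving a residual stubble, with an end-of-year salvage cut), and grazed
grassland, where animals at stocking rate S (LSU ha-1) ingest up to their
daily intake capacity IC (default 13 kg DM LSU-1 d-1).  Grazing stops when
shoot biomass falls below 300 kg DM ha-1 and resumes only after biomass has
stayed above that threshold for at least 15 consecutive days.  Trampling and
defoliation losses are represented by a grazing-use efficiency: only a
fraction of the biomass removed from the sward is actually ingested.

The indoor-feeding period T_farm is the part of the year outside the
vegetation period, defined as the longest run of days with positive
(5-day-smoothed) shoot growth.

Every simulated year carries a mass ledger (grown, senesced, harvested,
removed) that closes exactly against the change in standing biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grass_growth import (
    GrassState,
    GrowthParams,
    PhotosynthesisParams,
    step_day,
)
from .synthetic_forcing import DAYS_PER_YEAR, DailyMeteo


@dataclass(frozen=True)
class ManagementParams:
    """Management constants.

    intake_capacity     IC, kg DM per LSU per day (grazing and indoor alike)
    graze_threshold     kg DM ha-1: grazing stops below, resumes above
    recovery_days       days biomass must stay above the threshold to resume
    mow_residual        stubble left after a cut, kg DM ha-1
    mow_trigger         standing biomass that triggers a cut, kg DM ha-1
    use_efficiency      fraction of grazing-removed biomass actually ingested
    min_removable       minimum harvestable excess for a salvage cut, kg DM ha-1
    """

    intake_capacity: float = 13.0
    graze_threshold: float = 300.0
    recovery_days: int = 15
    mow_residual: float = 500.0
    mow_trigger: float = 2000.0
    use_efficiency: float = 0.7
    min_removable: float = 50.0

    def __post_init__(self) -> None:
        if self.intake_capacity <= 0:
            raise ValueError("intake capacity must be positive")
        if min(self.graze_threshold, self.mow_residual, self.min_removable) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.mow_residual >= self.mow_trigger:
            raise ValueError("mowing residual must be below the trigger")
        if not 0.0 < self.use_efficiency <= 1.0:
            raise ValueError("use efficiency must be in (0,1]")


@dataclass
class YearForcing:
    """One year of forcing for a batch of cells: daily meteorology arrays of
    shape (365, n_cells), the annual CO2 level and per-cell effective
    photosynthetic capacity (already including the nitrogen response)."""

    temp: np.ndarray
    precip: np.ndarray
    swdown: np.ndarray
    rh: np.ndarray
    co2: float
    vcmax: np.ndarray | float
    jmax: np.ndarray | float

    @classmethod
    def from_meteo(cls, meteo: DailyMeteo, year_index: int, co2: float,
                   vcmax, jmax) -> "YearForcing":
        return cls(meteo.temp[year_index], meteo.precip[year_index],
                   meteo.swdown[year_index], meteo.rh[year_index],
                   float(co2), vcmax, jmax)


@dataclass
class AnnualHarvest:
    """Annual harvest accounting per cell (vector fields)."""

    y_cut: np.ndarray        # kg DM ha-1 yr-1 harvested by mowing
    y_graze: np.ndarray      # kg DM ha-1 yr-1 ingested while grazing
    mow_events: np.ndarray   # cuts per year
    grazing_days: np.ndarray  # days grazing was permitted
    t_farm: np.ndarray       # days of indoor feeding


@dataclass
class MassLedger:
    """Exact per-cell shoot-biomass bookkeeping over one simulated year."""

    initial: np.ndarray
    grown: np.ndarray      # net shoot allocation from NPP (signed)
    senesced: np.ndarray
    harvested: np.ndarray
    removed: np.ndarray    # biomass removed from the sward by grazing
    final: np.ndarray

    def residual(self) -> np.ndarray:
        """initial + grown - senesced - harvested - removed - final."""
        return (self.initial + self.grown - self.senesced - self.harvested
                - self.removed - self.final)


def _smooth5(trace: np.ndarray) -> np.ndarray:
    """Centred 5-day moving average along axis 0 (edges use shorter windows)."""
    n = trace.shape[0]
    csum = np.cumsum(np.concatenate([np.zeros((1,) + trace.shape[1:]), trace]),
                     axis=0)
    lo = np.maximum(np.arange(n) - 2, 0)
    hi = np.minimum(np.arange(n) + 3, n)
    return (csum[hi] - csum[lo]) / (hi - lo).reshape((-1,) + (1,) * (trace.ndim - 1))


def _longest_positive_run(mask: np.ndarray) -> np.ndarray:
    """Length of the longest run of True along axis 0."""
    run = np.zeros(mask.shape[1:], dtype=int)
    best = np.zeros_like(run)
    for t in range(mask.shape[0]):
        run = (run + 1) * mask[t]
        best = np.maximum(best, run)
    return best


def indoor_period(growth_trace: np.ndarray) -> np.ndarray:
    """Indoor feeding period T_farm (days) from a daily shoot-growth trace.

    T_farm = 365 minus the vegetation period, the longest run of days with
    positive growth after 5-day smoothing.  Shape (365, n_cells) -> (n_cells,).
    """
    smoothed = _smooth5(np.asarray(growth_trace, dtype=float))
    return DAYS_PER_YEAR - _longest_positive_run(smoothed > 0.0)


def simulate_cut_year(
    state: GrassState,
    forcing: YearForcing,
    pparams: PhotosynthesisParams,
    gparams: GrowthParams,
    mparams: ManagementParams,
) -> tuple[AnnualHarvest, MassLedger, np.ndarray]:
    """Simulate one year of cut-grassland use, mutating ``state``.

    Biomass above the residual stubble is harvested whenever the standing
    shoot exceeds the mowing trigger; a final salvage cut recovers whatever
    exceeds residual + min_removable at year end.  Returns the harvest record
    (grazing fields zero), the mass ledger and the daily growth trace used to
    derive T_farm.
    """
    n = state.shoot.size
    initial = state.shoot.copy()
    grown = np.zeros(n)
    senesced = np.zeros(n)
    harvested = np.zeros(n)
    events = np.zeros(n)
    trace = np.zeros((DAYS_PER_YEAR, n))

    for d in range(DAYS_PER_YEAR):
        fx = step_day(state, forcing.temp[d], forcing.precip[d],
                      forcing.swdown[d], forcing.rh[d], forcing.co2,
                      forcing.vcmax, forcing.jmax, pparams, gparams)
        grown += fx.shoot_alloc
        senesced += fx.senescence
        trace[d] = fx.shoot_alloc

        cut = state.shoot > mparams.mow_trigger
        if np.any(cut):
            take = np.where(cut, state.shoot - mparams.mow_residual, 0.0)
            harvested += take
            events += cut
            state.shoot = state.shoot - take

    salvage = state.shoot > mparams.mow_residual + mparams.min_removable
    if np.any(salvage):
        take = np.where(salvage, state.shoot - mparams.mow_residual, 0.0)
        harvested += take
        events += salvage
        state.shoot = state.shoot - take

    t_farm = indoor_period(trace)
    harvest = AnnualHarvest(y_cut=harvested, y_graze=np.zeros(n),
                            mow_events=events, grazing_days=np.zeros(n),
                            t_farm=t_farm)
    ledger = MassLedger(initial, grown, senesced, harvested, np.zeros(n),
                        state.shoot.copy())
    return harvest, ledger, trace


def simulate_grazed_year(
    state: GrassState,
    forcing: YearForcing,
    stocking_rate: np.ndarray | float,
    pparams: PhotosynthesisParams,
    gparams: GrowthParams,
    mparams: ManagementParams,
    graze_window: np.ndarray | None = None,
) -> tuple[AnnualHarvest, MassLedger, np.ndarray]:
    """Simulate one year of grazed-grassland use, mutating ``state``.

    Daily ingestion is min(IC x S, biomass available above the grazing
    threshold); sward removal is ingestion divided by the use efficiency.
    Grazing stops below the threshold and resumes only after the recovery
    persistence is met.  ``graze_window`` optionally restricts grazing to a
    (365, n_cells) boolean vegetation window; grazing days count every
    permitted day.  Returns (harvest record, ledger, growth trace).
    """
    s = np.broadcast_to(np.asarray(stocking_rate, dtype=float),
                        state.shoot.shape).copy()
    if np.any(s < 0):
        raise ValueError("stocking rate must be non-negative")
    n = state.shoot.size
    if graze_window is None:
        graze_window = np.ones((DAYS_PER_YEAR, n), dtype=bool)

    initial = state.shoot.copy()
    grown = np.zeros(n)
    senesced = np.zeros(n)
    removed = np.zeros(n)
    ingested = np.zeros(n)
    graze_days = np.zeros(n)
    trace = np.zeros((DAYS_PER_YEAR, n))

    active = state.shoot > mparams.graze_threshold
    recovery = np.zeros(n, dtype=int)
    demand_removal = mparams.intake_capacity * s / mparams.use_efficiency

    for d in range(DAYS_PER_YEAR):
        fx = step_day(state, forcing.temp[d], forcing.precip[d],
                      forcing.swdown[d], forcing.rh[d], forcing.co2,
                      forcing.vcmax, forcing.jmax, pparams, gparams)
        grown += fx.shoot_alloc
        senesced += fx.senescence
        trace[d] = fx.shoot_alloc

        permitted = active & graze_window[d]
        avail = np.maximum(state.shoot - mparams.graze_threshold, 0.0)
        removal = np.where(permitted, np.minimum(demand_removal, avail), 0.0)
        state.shoot = state.shoot - removal
        removed += removal
        ingested += removal * mparams.use_efficiency
        graze_days += permitted

        below = state.shoot < mparams.graze_threshold
        stop = active & below
        active &= ~stop
        recovery = np.where(stop, 0, recovery)
        above = ~active & ~below
        recovery = np.where(above, recovery + 1, np.where(~active, 0, recovery))
        resume = ~active & (recovery >= mparams.recovery_days)
        active |= resume

    t_farm = indoor_period(trace)
    harvest = AnnualHarvest(y_cut=np.zeros(n), y_graze=ingested,
                            mow_events=np.zeros(n), grazing_days=graze_days,
                            t_farm=t_farm)
    ledger = MassLedger(initial, grown, senesced, np.zeros(n), removed,
                        state.shoot.copy())
    return harvest, ledger, trace


def vegetation_window(growth_trace: np.ndarray) -> np.ndarray:
    """Boolean (365, n_cells) mask of the longest positive-growth run per
    cell (5-day smoothed), i.e. the vegetation period grazing is tied to."""
    smoothed = _smooth5(np.asarray(growth_trace, dtype=float))
    pos = smoothed > 0.0
    n_days, n = pos.shape
    window = np.zeros_like(pos)
    run = np.zeros(n, dtype=int)
    best = np.zeros(n, dtype=int)
    best_end = np.zeros(n, dtype=int)
    for t in range(n_days):
        run = (run + 1) * pos[t]
        improved = run > best
        best = np.where(improved, run, best)
        best_end = np.where(improved, t, best_end)
    for c in range(n):
        if best[c] > 0:
            window[best_end[c] - best[c] + 1: best_end[c] + 1, c] = True
    return window
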