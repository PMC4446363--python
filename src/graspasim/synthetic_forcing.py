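"""Seeded synthetic forcing: grid, daily weather, CO2 and nitrogen drivers.

The simulator needs gridded daily meteorology, an annual atmospheric CO2
trajectory, annual nitrogen-addition rates and a grassland/region map.  This
module generates all of them from a seed with the statistical structure the
management model assumes: a sinusoidal seasonal temperature cycle with AR(1)
noise, a Bernoulli-gamma wet/dry precipitation process, radiation from
day-of-year solar geometry damped on wet days, a rising CO2 trajectory
starting near the early-20th-century level (296 ppm), and the historical
nitrogen-input reconstruction rules (constant organic fertilizer, mineral
fertilizer ramping linearly from zero in 1951 to its reference level in 1961,
deposition interpolated between decadal anchors).

All calendars are 365-day (no leap years), matching the annual bookkeeping
T_year = 365 used by the management layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DAYS_PER_YEAR = 365

#: Latitude band edges separating the three climate-zone labels.  A stand-in
#: for a Koeppen classification: south of 44N "mediterranean", north of 55N
#: "cold", "temperate" between.
ZONE_LAT_EDGES = (44.0, 55.0)
ZONES = ("mediterranean", "temperate", "cold")

EARTH_RADIUS_M = 6.371e6


@dataclass(frozen=True)
class ZoneClimate:
    """Climate-profile entry for one zone.

    mean_temp      mean annual air temperature (degC)
    amplitude      seasonal half-range of the temperature sinusoid (degC)
    noise_sd       innovation SD of the AR(1) daily temperature noise (degC)
    ar1            lag-1 autocorrelation of the daily noise
    wet_prob       probability a day is wet
    wet_mean_mm    mean precipitation on a wet day (mm)
    """

    mean_temp: float
    amplitude: float
    noise_sd: float = 2.0
    ar1: float = 0.7
    wet_prob: float = 0.4
    wet_mean_mm: float = 4.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.wet_prob <= 1.0:
            raise ValueError(f"wet_prob must be in [0,1], got {self.wet_prob}")
        if self.wet_mean_mm < 0 or self.noise_sd < 0:
            raise ValueError("wet_mean_mm and noise_sd must be >= 0")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError(f"ar1 must be in (-1,1), got {self.ar1}")


#: Default per-zone climates, loosely European: cool short-season north,
#: mild temperate middle, warm dry-summer south.
DEFAULT_CLIMATE: dict[str, ZoneClimate] = {
    "cold": ZoneClimate(4.0, 11.0, wet_prob=0.45, wet_mean_mm=3.5),
    "temperate": ZoneClimate(9.0, 9.0, wet_prob=0.42, wet_mean_mm=4.5),
    "mediterranean": ZoneClimate(15.0, 8.0, wet_prob=0.22, wet_mean_mm=5.0),
}


@dataclass
class ForcingGrid:
    """Flattened lat/lon grid with per-cell attributes.

    Cells are ordered row-major (lat outer, lon inner).  ``area_ha`` is the
    spherical cell area, ``grass_frac`` the grassland fraction in [0,1],
    ``region_id`` an integer partition label and ``zone`` one of
    cold/temperate/mediterranean assigned by latitude band.
    """

    lat: np.ndarray          # (n_lat,) degrees, strictly increasing
    lon: np.ndarray          # (n_lon,) degrees, strictly increasing
    area_ha: np.ndarray      # (n_cells,)
    grass_frac: np.ndarray   # (n_cells,)
    region_id: np.ndarray    # (n_cells,) int
    zone: np.ndarray         # (n_cells,) str

    @property
    def n_cells(self) -> int:
        return self.lat.size * self.lon.size

    @property
    def cell_lat(self) -> np.ndarray:
        """Latitude of every cell in flattened (row-major) order."""
        return np.repeat(self.lat, self.lon.size)

    def validate(self) -> None:
        if np.any(np.diff(self.lat) <= 0) or np.any(np.diff(self.lon) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if np.any((self.grass_frac < 0) | (self.grass_frac > 1)):
            raise ValueError("grassland fraction outside [0,1]")
        if self.region_id.shape != (self.n_cells,):
            raise ValueError("region_id must cover every cell exactly once")


@dataclass
class DailyMeteo:
    """Daily meteorology, shape (n_years, 365, n_cells)."""

    temp: np.ndarray      # degC
    precip: np.ndarray    # mm/day, >= 0
    swdown: np.ndarray    # W/m2, >= 0
    rh: np.ndarray        # relative humidity in [0,1]

    @property
    def n_years(self) -> int:
        return self.temp.shape[0]

    def year(self, i: int) -> "DailyMeteo":
        """View of a single year, shape (1, 365, n_cells)."""
        s = slice(i, i + 1)
        return DailyMeteo(self.temp[s], self.precip[s], self.swdown[s], self.rh[s])

    def validate(self) -> None:
        for name in ("temp", "precip", "swdown", "rh"):
            arr = getattr(self, name)
            if arr.shape != self.temp.shape or arr.ndim != 3:
                raise ValueError("meteo fields must share shape (years, 365, cells)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if self.temp.shape[1] != DAYS_PER_YEAR:
            raise ValueError("years must have 365 days")
        if np.any(self.precip < 0) or np.any(self.swdown < 0):
            raise ValueError("precip and radiation must be non-negative")
        if np.any((self.rh < 0) | (self.rh > 1)):
            raise ValueError("relative humidity outside [0,1]")


@dataclass
class AnnualDrivers:
    """Annual CO2 (ppm) plus per-cell annual nitrogen inputs (kg N/ha/yr)."""

    years: np.ndarray        # (n_years,) int
    co2: np.ndarray          # (n_years,) ppm
    organic_n: np.ndarray    # (n_years, n_cells)
    mineral_n: np.ndarray    # (n_years, n_cells)
    deposition_n: np.ndarray  # (n_years, n_cells)

    @property
    def total_n(self) -> np.ndarray:
        """N_amount = organic + mineral + deposition, the quantity the
        photosynthesis nitrogen response consumes."""
        return self.organic_n + self.mineral_n + self.deposition_n

    def validate(self) -> None:
        if np.any(self.co2 <= 0):
            raise ValueError("CO2 must be positive")
        for name in ("organic_n", "mineral_n", "deposition_n"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")


def zone_for_lat(lat: np.ndarray) -> np.ndarray:
    """Categorical climate-zone label from latitude bands."""
    lat = np.asarray(lat, dtype=float)
    out = np.where(lat < ZONE_LAT_EDGES[0], "mediterranean",
                   np.where(lat < ZONE_LAT_EDGES[1], "temperate", "cold"))
    return out.astype(object)


def _cell_area_ha(lat: np.ndarray, dlat: float, dlon: float) -> np.ndarray:
    """Spherical cell area in hectares for cells centred at ``lat``."""
    lat_r = np.deg2rad(lat)
    dlat_r, dlon_r = np.deg2rad(dlat), np.deg2rad(dlon)
    area_m2 = (EARTH_RADIUS_M ** 2) * dlon_r * (
        np.sin(lat_r + dlat_r / 2) - np.sin(lat_r - dlat_r / 2)
    )
    return area_m2 / 1e4


def generate_grid(
    n_lat: int,
    n_lon: int,
    seed: int,
    *,
    lat_range: tuple[float, float] = (37.0, 68.0),
    lon_range: tuple[float, float] = (-10.0, 30.0),
    n_regions: int | None = None,
) -> ForcingGrid:
    """Generate a deterministic synthetic grid.

    Regions partition the grid into contiguous latitudinal blocks; grassland
    fractions are Beta-distributed.  Deterministic for a given seed.
    """
    if n_lat < 1 or n_lon < 1:
        raise ValueError("grid dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    lat = np.linspace(*lat_range, n_lat) if n_lat > 1 else np.array(
        [np.mean(lat_range)])
    lon = np.linspace(*lon_range, n_lon) if n_lon > 1 else np.array(
        [np.mean(lon_range)])
    dlat = float(lat[1] - lat[0]) if n_lat > 1 else lat_range[1] - lat_range[0]
    dlon = float(lon[1] - lon[0]) if n_lon > 1 else lon_range[1] - lon_range[0]

    n_cells = n_lat * n_lon
    cell_lat = np.repeat(lat, n_lon)
    area = _cell_area_ha(cell_lat, abs(dlat), abs(dlon))
    grass = rng.beta(2.0, 2.0, size=n_cells)
    if n_regions is None:
        n_regions = max(1, min(n_lat, 8))
    # contiguous blocks of rows -> every cell gets exactly one region id
    row_region = np.minimum((np.arange(n_lat) * n_regions) // n_lat,
                            n_regions - 1)
    region = np.repeat(row_region, n_lon).astype(int)
    grid = ForcingGrid(lat=lat, lon=lon, area_ha=area, grass_frac=grass,
                       region_id=region, zone=zone_for_lat(cell_lat))
    grid.validate()
    return grid


def _daylength_factor(lat_deg: np.ndarray, doy: np.ndarray) -> np.ndarray:
    """Relative top-of-atmosphere insolation from solar geometry, in [0,1]."""
    decl = np.deg2rad(23.44) * np.sin(2 * np.pi * (doy[..., None] - 80) / 365.0)
    lat_r = np.deg2rad(lat_deg)[None, :]
    cos_h0 = np.clip(-np.tan(lat_r) * np.tan(decl), -1.0, 1.0)
    h0 = np.arccos(cos_h0)
    rel = (h0 * np.sin(lat_r) * np.sin(decl)
           + np.cos(lat_r) * np.cos(decl) * np.sin(h0)) / np.pi
    return np.clip(rel, 0.0, None)


def generate_meteo(
    grid: ForcingGrid,
    years: int,
    seed: int,
    climate_profile: dict[str, ZoneClimate] | None = None,
) -> DailyMeteo:
    """Generate seeded daily weather for every cell of ``grid``.

    Temperature is a sinusoidal seasonal cycle (minimum in mid-January) plus
    AR(1) noise; precipitation a Bernoulli-gamma wet/dry process; shortwave
    radiation follows day-of-year solar geometry at the cell latitude damped
    by a cloudiness factor on wet days; relative humidity is higher on wet
    days.  All DailyMeteo invariants hold by construction.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    profile = dict(DEFAULT_CLIMATE if climate_profile is None else climate_profile)
    for z in set(grid.zone):
        if z not in profile:
            raise ValueError(f"climate profile missing zone {z!r}")

    rng = np.random.default_rng(seed)
    n_cells = grid.n_cells
    cell_lat = grid.cell_lat
    doy = np.arange(DAYS_PER_YEAR, dtype=float)

    mean_t = np.array([profile[z].mean_temp for z in grid.zone])
    amp = np.array([profile[z].amplitude for z in grid.zone])
    noise_sd = np.array([profile[z].noise_sd for z in grid.zone])
    ar1 = np.array([profile[z].ar1 for z in grid.zone])
    wet_p = np.array([profile[z].wet_prob for z in grid.zone])
    wet_mm = np.array([profile[z].wet_mean_mm for z in grid.zone])

    # seasonal cycle: coldest near day 15, warmest near day 197
    seasonal = -np.cos(2 * np.pi * (doy[:, None] - 15) / 365.0)
    n_days = years * DAYS_PER_YEAR
    temp = np.empty((n_days, n_cells))
    # AR(1) noise, stationary start
    innov_sd = noise_sd * np.sqrt(np.clip(1 - ar1 ** 2, 1e-12, None))
    eps = rng.standard_normal((n_days, n_cells))
    noise = np.empty_like(eps)
    noise[0] = eps[0] * noise_sd
    for t in range(1, n_days):
        noise[t] = ar1 * noise[t - 1] + innov_sd * eps[t]
    seas_tiled = np.tile(seasonal, (years, 1))
    temp = mean_t[None, :] + amp[None, :] * seas_tiled + noise

    wet = rng.random((n_days, n_cells)) < wet_p[None, :]
    # gamma with shape 1.5, scale chosen so the wet-day mean matches
    amounts = rng.gamma(1.5, 1.0, size=(n_days, n_cells)) * (wet_mm[None, :] / 1.5)
    precip = np.where(wet, amounts, 0.0)

    rel = _daylength_factor(cell_lat, doy)          # (365, n_cells)
    rel_tiled = np.tile(rel, (years, 1))
    clearness = np.where(wet, 0.35, 0.70)
    swdown = 1361.0 * rel_tiled * clearness
    rh = np.clip(np.where(wet, 0.85, 0.65)
                 + 0.05 * rng.standard_normal((n_days, n_cells)), 0.0, 1.0)

    shape = (years, DAYS_PER_YEAR, n_cells)
    meteo = DailyMeteo(temp.reshape(shape), precip.reshape(shape),
                       swdown.reshape(shape), rh.reshape(shape))
    meteo.validate()
    return meteo


def tile_climatology(meteo: DailyMeteo, years: int) -> DailyMeteo:
    """Repeat the first year of ``meteo`` to build a stationary climatology."""
    y0 = meteo.year(0)
    return DailyMeteo(*(np.tile(getattr(y0, f), (years, 1, 1))
                        for f in ("temp", "precip", "swdown", "rh")))


def co2_series(
    start_year: int,
    end_year: int,
    base_ppm: float = 296.0,
    growth: float = 0.0,
    mode: str = "linear",
) -> np.ndarray:
    """Annual atmospheric CO2 trajectory.

    ``mode="linear"``: base + growth*(year-start), growth in ppm/yr.
    ``mode="exponential"``: base*(1+growth)**(year-start), growth as a
    fraction per year.  The first value equals ``base_ppm``; the series is
    non-decreasing for growth >= 0.
    """
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    if base_ppm <= 0:
        raise ValueError("base_ppm must be positive")
    t = np.arange(end_year - start_year + 1, dtype=float)
    if mode == "linear":
        return base_ppm + growth * t
    if mode == "exponential":
        return base_ppm * (1.0 + growth) ** t
    raise ValueError(f"unknown CO2 growth mode {mode!r}")


MINERAL_RAMP_START = 1951
MINERAL_RAMP_FULL = 1961


def nitrogen_timeline(
    grid: ForcingGrid,
    reference_rates: dict[str, np.ndarray],
    start_year: int,
    end_year: int,
    mineral_scaling: dict[int, float] | None = None,
    deposition_anchors: dict[int, float] | None = None,
) -> tuple[np.ndarray, AnnualDrivers]:
    """Reconstruct annual nitrogen inputs per cell.

    Rules: organic fertilizer constant over time; mineral fertilizer zero
    before 1951, ramping linearly from 1/10 of the reference rate in 1951 to
    the full reference level in 1961, then following ``mineral_scaling``
    (a {year: multiplier-of-reference} mapping, interpolated, default 1);
    deposition equals the reference rate scaled by factors linearly
    interpolated between decadal anchors placed at decade midpoints
    (``deposition_anchors`` maps decade-start year -> factor, default 1).

    Returns (years, AnnualDrivers) with CO2 left as ones (filled by caller).
    """
    ref_org = np.asarray(reference_rates["organic"], dtype=float)
    ref_min = np.asarray(reference_rates["mineral"], dtype=float)
    ref_dep = np.asarray(reference_rates["deposition"], dtype=float)
    for name, arr in (("organic", ref_org), ("mineral", ref_min),
                      ("deposition", ref_dep)):
        if np.any(arr < 0):
            raise ValueError(f"negative reference {name} rate")
    years = np.arange(start_year, end_year + 1)
    n_years, n_cells = years.size, grid.n_cells

    organic = np.broadcast_to(ref_org, (n_years, n_cells)).copy()

    frac = np.zeros(n_years)
    for i, y in enumerate(years):
        if y < MINERAL_RAMP_START:
            frac[i] = 0.0
        elif y < MINERAL_RAMP_FULL:
            frac[i] = (y - (MINERAL_RAMP_START - 1)) / 10.0
        else:
            frac[i] = 1.0
    if mineral_scaling:
        ys = np.array(sorted(mineral_scaling))
        vs = np.array([mineral_scaling[int(y)] for y in ys])
        post = years >= MINERAL_RAMP_FULL
        frac[post] = np.interp(years[post], ys, vs)
    mineral = frac[:, None] * ref_min[None, :]

    if deposition_anchors:
        anchor_years = np.array(sorted(deposition_anchors), dtype=float) + 5.0
        anchor_vals = np.array([deposition_anchors[int(y)]
                                for y in sorted(deposition_anchors)])
        dep_factor = np.interp(years.astype(float), anchor_years, anchor_vals)
    else:
        dep_factor = np.ones(n_years)
    deposition = dep_factor[:, None] * ref_dep[None, :]

    drivers = AnnualDrivers(years=years, co2=np.ones(n_years),
                            organic_n=organic, mineral_n=mineral,
                            deposition_n=deposition)
    drivers.validate()
    return years, drivers
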