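"""Regional aggregation and model-data agreement statistics.

Links the gridded potential livestock density to regional census statistics:
head counts are converted to livestock units (LSU), the observed grass-fed
herd is the diet-fraction-weighted sum over species, the simulated herd
combines the area-weighted regional density D_reg with grassland areas by
type (temporary, permanent, rough grazing) supported at 100%, 80% and 10% of
D_reg respectively.  Agreement metrics are the Pearson correlation (with
optional linear detrending for interannual-variability comparisons), the
coefficient of variation, and a through-origin regression of model on data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: LSU per head (Eurostat-style coefficients).
DEFAULT_LSU_COEFFICIENTS = {
    "dairy_cows": 1.0,
    "heifers": 0.8,
    "beef_cattle": 0.8,
    "sheep": 0.1,
    "goats": 0.1,
}

#: Fraction of the regional potential density each grassland type supports.
DEFAULT_SUPPORT_FRACTIONS = {"temp": 1.0, "perm": 0.8, "rough": 0.1}


@dataclass
class RegionRecord:
    """Census inputs and model density for one region."""

    region_id: int
    area_temp_ha: float
    area_perm_ha: float
    area_rough_ha: float
    n_beef: float       # LSU
    n_dairy: float      # LSU
    n_sheep: float      # LSU
    n_goats: float      # LSU
    f_beef: float       # grass fraction of diet, [0,1]
    f_dairy: float
    f_sheep: float
    f_goats: float
    d_reg: float = 0.0  # area-weighted model density, LSU ha-1
    climate_zone: str = "temperate"

    def validate(self) -> None:
        for a in (self.area_temp_ha, self.area_perm_ha, self.area_rough_ha):
            if a < 0:
                raise ValueError("areas must be non-negative")
        for f in (self.f_beef, self.f_dairy, self.f_sheep, self.f_goats):
            if not 0.0 <= f <= 1.0:
                raise ValueError("diet fractions must be in [0,1]")


def lsu_convert(head_counts: dict[str, float],
                coefficients: dict[str, float] | None = None) -> float:
    """Total livestock units from per-species head counts."""
    coeff = DEFAULT_LSU_COEFFICIENTS if coefficients is None else coefficients
    total = 0.0
    for species, heads in head_counts.items():
        if heads < 0:
            raise ValueError(f"negative head count for {species}")
        if species not in coeff:
            raise KeyError(f"no LSU coefficient for {species!r}")
        total += heads * coeff[species]
    return total


def grass_fed_observed(region: RegionRecord) -> float:
    """Observed grass-fed herd: diet-fraction weighted sum of LSU counts."""
    region.validate()
    return (region.n_beef * region.f_beef + region.n_dairy * region.f_dairy
            + region.n_sheep * region.f_sheep + region.n_goats * region.f_goats)


def aggregate_density(d_opt: np.ndarray, weights: np.ndarray,
                      region_id: np.ndarray) -> pd.Series:
    """Area-weighted mean potential density per region.

    ``weights`` is typically grassland area per cell (ha).  A region whose
    total weight is zero has no grassland support and is flagged by raising.
    """
    d = np.asarray(d_opt, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    df = pd.DataFrame({"d": d, "w": w, "region": np.asarray(region_id)})
    wsum = df.groupby("region")["w"].sum()
    empty = wsum[wsum <= 0.0]
    if len(empty):
        raise ValueError(
            f"regions with zero grassland weight: {list(empty.index)}")
    num = (df["d"] * df["w"]).groupby(df["region"]).sum()
    out = num / wsum
    out.name = "d_reg"
    return out


def grass_fed_simulated(region: RegionRecord,
                        support: dict[str, float] | None = None) -> float:
    """Simulated grass-fed herd from regional density and areas by type."""
    region.validate()
    f = DEFAULT_SUPPORT_FRACTIONS if support is None else support
    return region.d_reg * (f["temp"] * region.area_temp_ha
                           + f["perm"] * region.area_perm_ha
                           + f["rough"] * region.area_rough_ha)


def density_productivity_ratio(density: float, productivity: float) -> float:
    """Livestock density per 10 t DM of productivity: 10 * D / productivity.

    ``density`` in LSU ha-1, ``productivity`` in t DM ha-1 yr-1.
    """
    if productivity <= 0:
        raise ValueError("productivity must be positive")
    return 10.0 * density / productivity


def detrend(series: np.ndarray) -> np.ndarray:
    """Remove the OLS linear component (returns residuals plus the mean)."""
    y = np.asarray(series, dtype=float)
    x = np.arange(y.size, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept) + y.mean()


@dataclass
class AgreementStats:
    r: float
    p_value: float
    cv_model: float         # %
    cv_obs: float           # %
    origin_slope: float     # through-origin regression model ~ slope * obs
    origin_r2: float
    model: np.ndarray       # (possibly detrended) series actually compared
    obs: np.ndarray


def coefficient_of_variation(series: np.ndarray) -> float:
    """CV = 100 * SD / mean (sample SD)."""
    y = np.asarray(series, dtype=float)
    m = y.mean()
    if m == 0:
        raise ValueError("CV undefined for zero-mean series")
    return 100.0 * y.std(ddof=1) / m


def agreement(model: np.ndarray, obs: np.ndarray,
              detrend_flag: bool = False) -> AgreementStats:
    """Model-data agreement: Pearson r (optionally on detrended series),
    CVs, and a through-origin regression slope = sum(m*o)/sum(o^2) with its
    (uncentred) R^2."""
    m = np.asarray(model, dtype=float)
    o = np.asarray(obs, dtype=float)
    if m.size != o.size or m.size < 3:
        raise ValueError("series must have equal length >= 3")
    # CV is a scale-relative measure; undefined (NaN) for zero-mean series
    cv_m = coefficient_of_variation(m) if m.mean() != 0 else np.nan
    cv_o = coefficient_of_variation(o) if o.mean() != 0 else np.nan
    if detrend_flag:
        m, o = detrend(m), detrend(o)
    if np.ptp(m) == 0 or np.ptp(o) == 0:
        r, p = (1.0, 0.0) if np.allclose(m, o) else (np.nan, np.nan)
    else:
        r, p = stats.pearsonr(m, o)
    denom = float(np.sum(o * o))
    slope = float(np.sum(m * o) / denom) if denom > 0 else np.nan
    ss_res = float(np.sum((m - slope * o) ** 2)) if np.isfinite(slope) else np.nan
    ss_tot = float(np.sum(m * m))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return AgreementStats(float(r), float(p), cv_m, cv_o, slope, r2, m, o)


def regions_from_frame(df: pd.DataFrame) -> list[RegionRecord]:
    """Build RegionRecords from a table with the documented CSV columns
    (region_id, area_temp_ha, area_perm_ha, area_rough_ha, lsu_beef,
    lsu_dairy, lsu_sheep, lsu_goats, diet_frac_beef, diet_frac_dairy,
    diet_frac_sheep, diet_frac_goats[, d_reg, climate_zone])."""
    records = []
    for _, row in df.iterrows():
        rec = RegionRecord(
            region_id=int(row["region_id"]),
            area_temp_ha=float(row["area_temp_ha"]),
            area_perm_ha=float(row["area_perm_ha"]),
            area_rough_ha=float(row["area_rough_ha"]),
            n_beef=float(row["lsu_beef"]), n_dairy=float(row["lsu_dairy"]),
            n_sheep=float(row["lsu_sheep"]), n_goats=float(row["lsu_goats"]),
            f_beef=float(row["diet_frac_beef"]),
            f_dairy=float(row["diet_frac_dairy"]),
            f_sheep=float(row["diet_frac_sheep"]),
            f_goats=float(row["diet_frac_goats"]),
            d_reg=float(row.get("d_reg", 0.0)),
            climate_zone=str(row.get("climate_zone", "temperate")),
        )
        rec.validate()
        records.append(rec)
    return records


def evaluate_regions(records: list[RegionRecord],
                     support: dict[str, float] | None = None) -> pd.DataFrame:
    """N_obs, N_sim and their ratio for every region, as a table."""
    rows = []
    for rec in records:
        n_obs = grass_fed_observed(rec)
        n_sim = grass_fed_simulated(rec, support)
        rows.append({"region_id": rec.region_id, "n_obs": n_obs,
                     "n_sim": n_sim, "climate_zone": rec.climate_zone,
                     "d_reg": rec.d_reg})
    return pd.DataFrame(rows)
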