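"""Year-end adaptive adjustment of livestock density.

After each simulated year the farm compares the forage it conserved from cut
land, X' = Y_cut * (1 - F), with the indoor feed its herd required,
X = IC * T_farm * S * F (both per hectare of farm).  A surplus (deficit)
dM = X' - X would allow the density to change by at most dM / IC / 365; the
farmer realizes only a fraction alpha of that maximal step (default 0.2,
equivalent to responding to the mean productivity of roughly the previous
five years rather than to a single year).  The density update is applied at
fixed stocking rate by changing the grazed fraction F; if F would exceed 1
the stocking rate itself is raised, and density is floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .farm_optimizer import FarmOptimum, T_YEAR
from .management import AnnualHarvest, ManagementParams

DEFAULT_ALPHA = 0.2


def alpha_for_averaging_window(years: int) -> float:
    """Realized fraction equivalent to responding to the previous N years'
    mean productivity: alpha = 1/N (N=5 gives the default 0.2)."""
    if years < 1:
        raise ValueError("averaging window must be >= 1 year")
    return 1.0 / years


@dataclass
class AdaptiveStep:
    """Record of one year-end adaptation."""

    year: int
    x_prod: float      # X': cut-forage production, kg DM ha-1 of farm
    x_demand: float    # X: indoor feed demand, kg DM ha-1 of farm
    delta_m: float     # X' - X
    delta_d: float     # realized density change, LSU ha-1
    d_before: float
    d_after: float


def forage_balance(y_cut: float, farm: FarmOptimum,
                   mparams: ManagementParams,
                   t_farm: float | None = None) -> tuple[float, float, float]:
    """(X', X, dM) for a year with cut yield ``y_cut`` on the farm ``farm``.

    X' = Y_cut * (1 - F); X = IC * T_farm * S * F.  ``t_farm`` defaults to
    the farm's stored indoor period.
    """
    tf = farm.t_farm if t_farm is None else t_farm
    x_prod = y_cut * (1.0 - farm.f_opt)
    x_demand = mparams.intake_capacity * tf * farm.s_opt * farm.f_opt
    return x_prod, x_demand, x_prod - x_demand


def density_step(delta_m: float, mparams: ManagementParams,
                 alpha: float = DEFAULT_ALPHA) -> float:
    """Realized density change: dD = dM / IC / T_year * alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0,1]")
    return delta_m / mparams.intake_capacity / T_YEAR * alpha


def update_farm(farm: FarmOptimum, delta_d: float) -> FarmOptimum:
    """Apply a density change at fixed stocking rate.

    D_new = max(0, D + dD) is realized through F = D_new / S; if that would
    exceed 1 (all land grazed) the stocking rate is raised so that F = 1 and
    D stays continuous.
    """
    d_new = max(0.0, farm.d_opt + delta_d)
    s = farm.s_opt
    if s <= 0.0:
        # herd extinct or never established; density can only stay at zero
        return replace(farm, d_opt=0.0, f_opt=0.0)
    f_new = d_new / s
    if f_new > 1.0:
        out = replace(farm, s_opt=d_new, f_opt=1.0, d_opt=d_new)
    else:
        out = replace(farm, f_opt=f_new, d_opt=d_new)
    out.validate()
    return out


def adapt_year(farm: FarmOptimum, y_cut: float, t_farm: float, year: int,
               mparams: ManagementParams,
               alpha: float = DEFAULT_ALPHA) -> tuple[FarmOptimum, AdaptiveStep]:
    """One full year-end adaptation: balance, step, update."""
    x_prod, x_demand, delta_m = forage_balance(y_cut, farm, mparams, t_farm)
    delta_d = density_step(delta_m, mparams, alpha)
    new_farm = update_farm(farm, delta_d)
    step = AdaptiveStep(year=year, x_prod=x_prod, x_demand=x_demand,
                        delta_m=delta_m, delta_d=new_farm.d_opt - farm.d_opt,
                        d_before=farm.d_opt, d_after=new_farm.d_opt)
    return new_farm, step
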