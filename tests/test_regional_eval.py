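"""Regional aggregation, livestock-number equations, agreement metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graspasim.regional_eval import (
    RegionRecord,
    agreement,
    aggregate_density,
    coefficient_of_variation,
    density_productivity_ratio,
    detrend,
    evaluate_regions,
    grass_fed_observed,
    grass_fed_simulated,
    lsu_convert,
)


def _region(**kw):
    base = dict(region_id=1, area_temp_ha=10000.0, area_perm_ha=100000.0,
                area_rough_ha=50000.0, n_beef=1000.0, n_dairy=2000.0,
                n_sheep=500.0, n_goats=100.0, f_beef=0.8, f_dairy=0.7,
                f_sheep=0.9, f_goats=0.9, d_reg=1.0)
    base.update(kw)
    return RegionRecord(**base)


class TestLsuConvert:
    def test_sheep_coefficient(self):
        assert lsu_convert({"sheep": 100}) == pytest.approx(10.0)

    def test_no_animals(self):
        assert lsu_convert({"dairy_cows": 0, "goats": 0}) == 0.0

    def test_mixed_herd(self):
        assert lsu_convert({"dairy_cows": 10, "heifers": 10}) == \
            pytest.approx(18.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            lsu_convert({"sheep": -5})

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            lsu_convert({"llamas": 5})


class TestGrassFedObserved:
    def test_full_grass_diet_counts_everything(self):
        r = _region(f_beef=1.0, f_dairy=1.0, f_sheep=1.0, f_goats=1.0)
        assert grass_fed_observed(r) == pytest.approx(3600.0)

    def test_single_species_term(self):
        r = _region(n_beef=1000.0, f_beef=0.6, n_dairy=0, n_sheep=0,
                    n_goats=0)
        assert grass_fed_observed(r) == pytest.approx(600.0)

    def test_zero_fractions_zero_herd(self):
        r = _region(f_beef=0.0, f_dairy=0.0, f_sheep=0.0, f_goats=0.0)
        assert grass_fed_observed(r) == 0.0


class TestGrassFedSimulated:
    def test_default_support_fractions(self):
        r = _region(d_reg=1.0)
        # 1.0*10000 + 0.8*100000 + 0.1*50000
        assert grass_fed_simulated(r) == pytest.approx(95000.0)

    def test_zero_density_zero_herd(self):
        assert grass_fed_simulated(_region(d_reg=0.0)) == 0.0

    def test_rough_grazing_supports_ten_percent(self):
        r = _region(d_reg=1.0, area_temp_ha=0.0, area_perm_ha=0.0,
                    area_rough_ha=10000.0)
        assert grass_fed_simulated(r) == pytest.approx(1000.0)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_all_inputs(self, k):
        r = _region()
        scaled = _region(d_reg=r.d_reg * k)
        assert grass_fed_simulated(scaled) == \
            pytest.approx(k * grass_fed_simulated(r))
        obs = _region(n_beef=1000.0 * k, n_dairy=2000.0 * k,
                      n_sheep=500.0 * k, n_goats=100.0 * k)
        assert grass_fed_observed(obs) == \
            pytest.approx(k * grass_fed_observed(_region()))


class TestAggregateDensity:
    def test_uniform_density(self):
        out = aggregate_density(np.full(4, 0.8), np.ones(4), np.zeros(4))
        assert out.loc[0] == pytest.approx(0.8)

    def test_weighted_mean(self):
        out = aggregate_density(np.array([1.0, 0.0]), np.array([1.0, 3.0]),
                                np.array([7, 7]))
        assert out.loc[7] == pytest.approx(0.25)

    def test_zero_weight_region_flagged(self):
        with pytest.raises(ValueError, match="zero grassland weight"):
            aggregate_density(np.array([1.0, 1.0]), np.array([1.0, 0.0]),
                              np.array([1, 2]))


class TestDensityProductivityRatio:
    def test_ratio_units(self):
        assert density_productivity_ratio(0.75, 5.0) == pytest.approx(1.5)

    def test_zero_density(self):
        assert density_productivity_ratio(0.0, 5.0) == 0.0

    def test_mediterranean_magnitude(self):
        assert density_productivity_ratio(0.79, 4.52) == \
            pytest.approx(1.75, abs=0.01)

    def test_zero_productivity_rejected(self):
        with pytest.raises(ValueError):
            density_productivity_ratio(1.0, 0.0)


class TestAgreement:
    def test_identical_series_perfect_agreement(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        ag = agreement(y, y)
        assert ag.r == pytest.approx(1.0, abs=1e-12)
        assert ag.origin_slope == pytest.approx(1.0, abs=1e-12)
        assert ag.origin_r2 == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_series(self):
        y = np.array([1.0, -2.0, 3.0, -2.0])
        ag = agreement(-y + 10.0, y)
        assert ag.r == pytest.approx(-1.0, abs=1e-12)

    def test_pearson_hand_example(self):
        # r for (1,2,3) vs (2,4,7): 5 / sqrt(2 * 38/3)
        ag = agreement(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 7.0]))
        expected = 5.0 / np.sqrt(2.0 * 38.0 / 3.0)
        assert ag.r == pytest.approx(expected, abs=1e-12)
        assert ag.r == pytest.approx(0.99340, abs=5e-6)

    def test_detrending_removes_linear_component(self):
        rng = np.random.default_rng(3)
        y = 5.0 + 0.3 * np.arange(30) + rng.normal(0, 0.5, 30)
        res = detrend(y)
        slope = np.polyfit(np.arange(30), res, 1)[0]
        assert abs(slope) < 1e-10
        assert res.mean() == pytest.approx(y.mean())

    def test_cv_definition(self):
        y = np.array([4.0, 6.0])
        assert coefficient_of_variation(y) == \
            pytest.approx(100.0 * np.std(y, ddof=1) / 5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement(np.ones(3), np.ones(4))


class TestRegionalClosure:
    def test_constructed_regions_recover_unit_slope(self):
        """Regions whose observed herd is built exactly as the support-
        fraction-weighted density times areas give a through-origin slope of
        1.00 with R^2 = 1."""
        rng = np.random.default_rng(9)
        records = []
        for rid in range(12):
            d = float(rng.uniform(0.2, 1.5))
            areas = rng.uniform(1e4, 2e5, size=3)
            n_total = d * (1.0 * areas[0] + 0.8 * areas[1] + 0.1 * areas[2])
            records.append(RegionRecord(
                region_id=rid, area_temp_ha=areas[0], area_perm_ha=areas[1],
                area_rough_ha=areas[2], n_beef=n_total, n_dairy=0.0,
                n_sheep=0.0, n_goats=0.0, f_beef=1.0, f_dairy=0.0,
                f_sheep=0.0, f_goats=0.0, d_reg=d))
        table = evaluate_regions(records)
        ag = agreement(table["n_sim"].to_numpy(), table["n_obs"].to_numpy())
        assert ag.origin_slope == pytest.approx(1.0, abs=1e-12)
        assert ag.origin_r2 == pytest.approx(1.0, abs=1e-12)
        assert ag.r == pytest.approx(1.0, abs=1e-12)
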