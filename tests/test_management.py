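"""Mowing/grazing rules: thresholds, bookkeeping, mass conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graspasim.grass_growth import GrassState, GrowthParams, PhotosynthesisParams
from graspasim.management import (
    ManagementParams,
    YearForcing,
    indoor_period,
    simulate_cut_year,
    simulate_grazed_year,
    vegetation_window,
)


def _dead_forcing(n_cells: int) -> YearForcing:
    """Deep-frost, dark year: no growth anywhere."""
    shape = (365, n_cells)
    return YearForcing(np.full(shape, -15.0), np.zeros(shape),
                       np.zeros(shape), np.full(shape, 0.7), 380.0, 55.0,
                       110.0)


class TestSimulateCutYear:
    def test_zero_growth_no_harvest(self, pparams, gparams, mparams):
        state = GrassState.initial(2, shoot=100.0)
        harvest, _, _ = simulate_cut_year(state, _dead_forcing(2), pparams,
                                          gparams, mparams)
        assert np.all(harvest.y_cut == 0.0)
        assert np.all(harvest.mow_events == 0.0)

    def test_event_bookkeeping_identity(self, temperate_year, pparams,
                                        gparams, mparams):
        """Y_cut equals the summed biomass-above-residual at each cut."""
        _, forcing = temperate_year
        state = GrassState.initial(4, shoot=800.0)
        harvest, ledger, _ = simulate_cut_year(state, forcing, pparams,
                                               gparams, mparams)
        assert np.all(harvest.mow_events >= 2)
        # conservation closes, so harvested mass is exactly the ledger's
        np.testing.assert_allclose(harvest.y_cut, ledger.harvested)
        assert np.all(harvest.y_cut > 0)

    def test_infinite_trigger_single_salvage_cut(self, temperate_year,
                                                 pparams, gparams):
        _, forcing = temperate_year
        mp = ManagementParams(mow_trigger=1e12, mow_residual=500.0)
        state = GrassState.initial(4, shoot=800.0)
        harvest, _, _ = simulate_cut_year(state, forcing, pparams, gparams, mp)
        assert np.all(harvest.mow_events <= 1)

    def test_raising_trigger_never_increases_events(self, temperate_year,
                                                    pparams, gparams):
        _, forcing = temperate_year
        events = []
        for trigger in (1500.0, 2500.0, 4000.0):
            mp = ManagementParams(mow_trigger=trigger)
            state = GrassState.initial(4, shoot=800.0)
            h, _, _ = simulate_cut_year(state, forcing, pparams, gparams, mp)
            events.append(h.mow_events.copy())
        assert np.all(events[0] >= events[1])
        assert np.all(events[1] >= events[2])

    def test_mass_ledger_closes(self, temperate_year, pparams, gparams,
                                mparams):
        _, forcing = temperate_year
        state = GrassState.initial(4, shoot=800.0)
        _, ledger, _ = simulate_cut_year(state, forcing, pparams, gparams,
                                         mparams)
        scale = np.maximum(ledger.initial + ledger.grown, 1.0)
        assert np.all(np.abs(ledger.residual()) / scale < 1e-6)


class TestSimulateGrazedYear:
    def test_zero_stocking_no_intake_full_season_grazable(
            self, temperate_year, pparams, gparams, mparams):
        _, forcing = temperate_year
        state = GrassState.initial(4, shoot=800.0)
        harvest, _, _ = simulate_grazed_year(state, forcing, 0.0, pparams,
                                             gparams, mparams)
        assert np.all(harvest.y_graze == 0.0)
        assert np.all(harvest.grazing_days > 100)

    def test_biomass_below_threshold_never_grazed(self, pparams, gparams,
                                                  mparams):
        state = GrassState.initial(2, shoot=200.0)  # below 300 all year
        harvest, _, _ = simulate_grazed_year(state, _dead_forcing(2), 2.0,
                                             pparams, gparams, mparams)
        assert np.all(harvest.y_graze == 0.0)

    def test_intake_capacity_bound_exact(self, temperate_year, pparams,
                                         gparams, mparams):
        _, forcing = temperate_year
        state = GrassState.initial(4, shoot=800.0)
        s = 1.5
        harvest, _, _ = simulate_grazed_year(state, forcing, s, pparams,
                                             gparams, mparams)
        bound = harvest.grazing_days * mparams.intake_capacity * s
        assert np.all(harvest.y_graze <= bound + 1e-9)

    def test_overstocking_limited_by_production(self, temperate_year,
                                                pparams, gparams, mparams):
        """A huge herd cannot ingest more than the sward produces; grazing
        is repeatedly suspended and the ledger stays closed."""
        _, forcing = temperate_year
        mild = GrassState.initial(4, shoot=800.0)
        h_mild, _, _ = simulate_grazed_year(mild, forcing, 1.0, pparams,
                                            gparams, mparams)
        heavy = GrassState.initial(4, shoot=800.0)
        h_heavy, ledger, _ = simulate_grazed_year(heavy, forcing, 50.0,
                                                  pparams, gparams, mparams)
        assert np.all(h_heavy.grazing_days < h_mild.grazing_days)
        # ingested is the use-efficiency share of removed biomass
        np.testing.assert_allclose(h_heavy.y_graze,
                                   ledger.removed * mparams.use_efficiency)
        scale = np.maximum(ledger.initial + np.abs(ledger.grown), 1.0)
        assert np.all(np.abs(ledger.residual()) / scale < 1e-6)

    def test_negative_stocking_rejected(self, temperate_year, pparams,
                                        gparams, mparams):
        _, forcing = temperate_year
        with pytest.raises(ValueError):
            simulate_grazed_year(GrassState.initial(4), forcing, -1.0,
                                 pparams, gparams, mparams)


class TestIndoorPeriod:
    def test_growth_every_day(self):
        assert indoor_period(np.ones((365, 1)))[0] == 0

    def test_window_100_to_250(self):
        trace = -np.ones((365, 1))
        trace[100:251] = 1.0   # 151-day vegetation period
        assert indoor_period(trace)[0] == 365 - 151

    def test_no_growth(self):
        assert indoor_period(np.zeros((365, 2)))[0] == 365

    def test_vegetation_window_matches_period(self):
        trace = -np.ones((365, 1))
        trace[100:251] = 1.0
        win = vegetation_window(trace)
        assert win[:, 0].sum() == 151
        assert win[100, 0] and win[250, 0] and not win[99, 0]


class TestMassConservationProperty:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=5, deadline=None)
    def test_random_schedules_conserve_mass_and_positivity(self, seed):
        """Random mow/graze schedules never create or lose biomass and never
        drive pools negative."""
        from graspasim.synthetic_forcing import generate_grid, generate_meteo

        rng = np.random.default_rng(seed)
        grid = generate_grid(1, 2, seed=seed % 1000)
        meteo = generate_meteo(grid, 1, seed=(seed + 1) % 1000)
        forcing = YearForcing.from_meteo(meteo, 0, 380.0, 55.0, 110.0)
        mp = ManagementParams(
            mow_trigger=float(rng.uniform(1000, 3000)),
            mow_residual=float(rng.uniform(100, 900)),
            intake_capacity=float(rng.uniform(10, 16)),
        )
        state = GrassState.initial(2, shoot=float(rng.uniform(100, 2000)))
        pp, gp = PhotosynthesisParams(), GrowthParams()
        if rng.random() < 0.5:
            _, ledger, _ = simulate_cut_year(state, forcing, pp, gp, mp)
        else:
            s = float(rng.uniform(0, 6))
            _, ledger, _ = simulate_grazed_year(state, forcing, s, pp, gp, mp)
        scale = np.maximum(ledger.initial + np.abs(ledger.grown), 1.0)
        assert np.all(np.abs(ledger.residual()) / scale < 1e-6)
        assert np.all(state.shoot >= 0.0) and np.all(state.root >= 0.0)
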