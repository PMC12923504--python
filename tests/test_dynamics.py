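"""Annual-step simulator: rate formulas, the elevation bookkeeping
identity, conversion rules, and equivalence with a naive reference."""

import dataclasses

import numpy as np
import pytest

from marshline.dynamics import (NEVER_WETLAND, PERSISTENT, SimParams,
                                Surfaces, accretion_rate, calibrate_accretion,
                                erosion_rate, hydroperiod, initial_state,
                                run, step)
from marshline.grid import WATER, WETLAND, Grid, GridMeta
from marshline.scenarios import make_trajectory
from tests._oracles import reference_run, reference_step


def make_state(elev, landcover=None, year=2023, cell_size=2.0):
    elev = np.asarray(elev, dtype=float)
    meta = GridMeta(elev.shape[0], elev.shape[1], cell_size)
    if landcover is None:
        landcover = np.full(elev.shape, WETLAND)
    return initial_state(Grid(elev, meta),
                         Grid(np.asarray(landcover), meta), year)


class TestHydroperiod:
    def test_boundaries_and_midpoint(self, default_params):
        p = default_params
        assert hydroperiod(p.mhw, p) == 0.0
        assert hydroperiod(p.mlw, p) == 1.0
        assert hydroperiod(0.5 * (p.mlw + p.mhw), p) == pytest.approx(0.5)

    def test_monotone_non_increasing(self, default_params):
        z = np.linspace(-0.5, 0.5, 101)
        h = hydroperiod(z, default_params)
        assert (np.diff(h) <= 0).all()
        assert ((h >= 0) & (h <= 1)).all()


class TestAccretionRate:
    def test_no_sources_no_accretion(self, default_params):
        assert accretion_rate(0.0, 500.0, 0.0, 0.0, default_params) == 0.0

    def test_dry_cell_organic_only(self, default_params):
        p = default_params
        rate = accretion_rate(30.0, 500.0, 0.0, p.mhw + 0.1, p)
        assert rate == 0.0  # zero hydroperiod and zero belowground biomass

    def test_hand_computed_value(self):
        p = SimParams(k_settle=50.0, k_trap=1.0, b_ag_ref=1000.0,
                      bulk_density=0.289, k_org=0.0)
        rate = accretion_rate(30.0, 1000.0, 0.0, 0.0, p)
        # 50 * 30 * 0.5 * 2 / 289000
        assert rate == pytest.approx(5.19e-3, rel=1e-2)
        assert rate == pytest.approx(50 * 30 * 0.5 * 2 / 289000.0, rel=1e-12)

    def test_linear_in_tss_and_bg(self, default_params):
        base = accretion_rate(20.0, 400.0, 1000.0, 0.0, default_params)
        double_tss = accretion_rate(40.0, 400.0, 1000.0, 0.0, default_params)
        inorganic = double_tss - base  # the TSS-linear part
        assert accretion_rate(60.0, 400.0, 1000.0, 0.0, default_params) \
            == pytest.approx(base + 2 * inorganic, rel=1e-12)

    def test_non_increasing_in_elevation(self, default_params):
        z = np.linspace(-0.3, 0.3, 50)
        acc = accretion_rate(30.0, 500.0, 1500.0, z, default_params)
        assert (np.diff(acc) <= 1e-15).all()

    def test_trapping_saturates(self, default_params):
        at_ref = accretion_rate(30.0, default_params.b_ag_ref, 0.0, 0.0,
                                default_params)
        above_ref = accretion_rate(30.0, 5 * default_params.b_ag_ref, 0.0,
                                   0.0, default_params)
        assert at_ref == above_ref

    def test_water_cells_zero(self, default_params):
        assert accretion_rate(30.0, 500.0, 1000.0, -0.5, default_params,
                              water=True) == 0.0

    def test_negative_inputs_rejected(self, default_params):
        with pytest.raises(ValueError):
            accretion_rate(-1.0, 0.0, 0.0, 0.0, default_params)


class TestErosionRate:
    def test_exposure_scaling(self):
        p = SimParams(e_base=0.004)
        lc = np.array([[WETLAND, WETLAND, WETLAND],
                       [WATER, WETLAND, WATER],
                       [WETLAND, WETLAND, WETLAND]])
        ero = erosion_rate(lc, p)
        assert ero[1, 1] == pytest.approx(0.002)   # 2 of 4 neighbors water
        assert ero[0, 0] == pytest.approx(0.001)   # 1 water neighbor
        assert ero[0, 1] == 0.0                    # interior wetland
        assert ero[1, 0] == 0.0                    # water cells do not erode

    def test_domain_edge_counts_as_land(self):
        p = SimParams(e_base=0.004)
        lc = np.full((2, 2), WETLAND)
        assert (erosion_rate(lc, p) == 0.0).all()


class TestStep:
    def test_identity_forcing(self, flat_surfaces, default_params):
        state = make_state(np.full((4, 4), 0.3))
        new = step(state, dataclasses.replace(default_params, e_base=0.0),
                   0.0, flat_surfaces((4, 4)))
        assert new.year == state.year + 1
        assert np.array_equal(new.elevation, state.elevation)
        assert np.array_equal(new.landcover, state.landcover)

    def test_elevation_identity_arithmetic(self, flat_surfaces):
        """z' = z - RSLR + Acc - Ero for a single interior wetland cell."""
        p = SimParams(k_settle=0.0, k_org=0.005 / 1000.0, e_base=0.0)
        state = make_state(np.full((3, 3), 0.500))
        surf = flat_surfaces((3, 3), bg=1000.0)   # Acc = 0.005 exactly
        new = step(state, p, 0.009, surf)
        assert new.elevation[1, 1] == pytest.approx(0.500 - 0.009 + 0.005,
                                                    abs=1e-15)

    def test_conversion_below_mlw(self, flat_surfaces, default_params):
        state = make_state(np.array([[0.5, -0.14]]))
        new = step(state, dataclasses.replace(default_params, e_base=0.0),
                   0.02, flat_surfaces((1, 2)))
        assert new.landcover[0, 1] == WATER          # ended at -0.16 < MLW
        assert new.loss_year[0, 1] == state.year + 1
        assert new.landcover[0, 0] == WETLAND
        assert new.loss_year[0, 0] == PERSISTENT

    def test_water_cells_receive_only_rslr(self, flat_surfaces,
                                           default_params):
        state = make_state(np.array([[0.5, -0.5]]),
                           landcover=[[WETLAND, WATER]])
        surf = flat_surfaces((1, 2), tss=30.0, ab=500.0, bg=1000.0)
        new = step(state, default_params, 0.01, surf)
        assert new.elevation[0, 1] == pytest.approx(-0.51, abs=1e-15)

    def test_negative_rate_rejected(self, flat_surfaces, default_params):
        state = make_state(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            step(state, default_params, -0.001, flat_surfaces((2, 2)))

    def test_misaligned_surfaces_rejected(self, flat_surfaces,
                                          default_params):
        state = make_state(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            step(state, default_params, 0.001, flat_surfaces((3, 3)))


class TestRun:
    def test_zero_forcing_constant_area(self, flat_surfaces):
        state = make_state(np.full((5, 5), 0.4))
        p = SimParams(e_base=0.0)
        traj = make_trajectory("constant", 0.0, 2023, 2060)
        result = run(state, traj, p, flat_surfaces((5, 5)))
        assert len(result.wetland_ha) == 38
        assert (result.wetland_ha == result.wetland_ha[0]).all()

    def test_three_cell_toy_loss_years(self, flat_surfaces):
        """Loss year solves z - r*n < MLW by hand: n = 17, 26, 46.

        The third cell sits a hair above the exact boundary (z = 0.30 would
        reach MLW exactly at n = 45, where accumulated float rounding, not
        the model, would pick the year).
        """
        state = make_state(np.array([[0.01, 0.10, 0.30000001]]), year=2023)
        p = SimParams(mlw=-0.15, e_base=0.0)
        traj = make_trajectory("constant", 0.01, 2023, 2100)
        result = run(state, traj, p, flat_surfaces((1, 3)))
        assert result.loss_year.tolist() == [[2023 + 17, 2023 + 26,
                                              2023 + 46]]

    def test_area_non_increasing_without_accretion(self, small_bundle,
                                                   default_params):
        state = initial_state(small_bundle.dem, small_bundle.landcover, 2023)
        surf = Surfaces(tss=np.zeros(state.elevation.shape),
                        ab_biomass=(0.0, 0.0), bg_biomass=(0.0, 0.0))
        traj = make_trajectory("constant", 0.012, 2023, 2060)
        result = run(state, traj, default_params, surf)
        assert (np.diff(result.wetland_ha) <= 0).all()

    def test_monotone_forcing(self, small_bundle, default_params):
        """Stronger constant RSLR never leaves more wetland."""
        state = initial_state(small_bundle.dem, small_bundle.landcover, 2023)
        shape = state.elevation.shape
        surf = Surfaces(tss=np.full(shape, 30.0), ab_biomass=(500.0, 1000.0),
                        bg_biomass=(1250.0, 2500.0))
        areas = []
        for rate in (0.006, 0.012, 0.018):
            traj = make_trajectory("constant", rate, 2023, 2080)
            areas.append(run(state, traj, default_params, surf).wetland_ha[-1])
        assert areas[0] >= areas[1] >= areas[2]

    def test_irreversibility(self, small_bundle, default_params):
        state = initial_state(small_bundle.dem, small_bundle.landcover, 2023)
        surf = Surfaces(tss=np.full(state.elevation.shape, 30.0),
                        ab_biomass=(500.0, 1000.0), bg_biomass=(1250.0, 2500.0))
        current = state
        seen_loss = current.loss_year.copy()
        for year in range(2024, 2061):
            current = step(current, default_params, 0.018,
                           surf)
            newly = current.loss_year != seen_loss
            # only previously-persistent wetland cells may acquire a loss year
            assert (seen_loss[newly] == PERSISTENT).all()
            assert (current.loss_year[newly] == year).all()
            seen_loss = current.loss_year.copy()
        assert (current.loss_year[state.landcover != WETLAND]
                == NEVER_WETLAND).all()

    def test_trajectory_gap_rejected(self, flat_surfaces, default_params):
        state = make_state(np.zeros((2, 2)), year=2023)
        traj = make_trajectory("constant", 0.01, 2030, 2050)
        with pytest.raises(ValueError):
            run(state, traj, default_params, flat_surfaces((2, 2)))


class TestReferenceEquivalence:
    """The vectorized engine must match the naive cell loop bit-for-bit."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("dynamic_biomass", [False, True])
    def test_bit_identical_on_random_landscapes(self, seed, dynamic_biomass):
        rng = np.random.default_rng(seed)
        shape = (20, 20)
        elev = rng.uniform(-0.6, 0.8, shape)
        lc = np.where(elev >= -0.15, WETLAND, WATER)
        tss = rng.uniform(0.0, 60.0, shape)
        if dynamic_biomass:
            ab_spec = (500.0, 1000.0)
            bg_spec = (1250.0, 2500.0)
        else:
            ab_spec = rng.uniform(0.0, 1500.0, shape)
            bg_spec = rng.uniform(0.0, 3000.0, shape)
        params = SimParams()
        surf = Surfaces(tss=tss, ab_biomass=ab_spec, bg_biomass=bg_spec)
        state = make_state(elev, landcover=lc, year=2023)
        traj = make_trajectory("constant", 0.012, 2023, 2053)
        result = run(state, traj, params, surf)
        ref_elev, ref_lc, ref_ly = reference_run(
            state.elevation, state.landcover, state.loss_year, 2023, 30,
            params, 0.012, tss, ab_spec, bg_spec)
        assert np.array_equal(result.final_state.elevation, ref_elev)
        assert np.array_equal(result.final_state.landcover, ref_lc)
        assert np.array_equal(result.final_state.loss_year, ref_ly)

    def test_single_step_identity_holds(self, default_params):
        """Eq.-style bookkeeping: production step equals the reference's
        independent recomputation of Acc and Ero on every cell."""
        rng = np.random.default_rng(9)
        elev = rng.uniform(-0.4, 0.6, (15, 15))
        lc = np.where(elev >= default_params.mlw, WETLAND, WATER)
        tss = rng.uniform(0, 50, (15, 15))
        surf = Surfaces(tss=tss, ab_biomass=(500.0, 1000.0),
                        bg_biomass=(1250.0, 2500.0))
        state = make_state(elev, landcover=lc)
        new = step(state, default_params, 0.009, surf)
        ref_elev, _, _ = reference_step(
            state.elevation, state.landcover, state.loss_year, state.year,
            default_params, 0.009, tss, (500.0, 1000.0), (1250.0, 2500.0))
        assert np.array_equal(new.elevation, ref_elev)


class TestCalibrateAccretion:
    def _setup(self):
        shape = (10, 10)
        elev = np.full(shape, 0.0)
        lc = np.full(shape, WETLAND)
        surf = Surfaces(tss=np.full(shape, 30.0),
                        ab_biomass=np.full(shape, 500.0),
                        bg_biomass=np.full(shape, 1000.0))
        return elev, lc, surf

    def test_fixed_point(self, default_params):
        elev, lc, surf = self._setup()
        cells = [(2, 2), (5, 5)]
        acc = accretion_rate(30.0, 500.0, 1000.0, 0.0, default_params)
        out = calibrate_accretion(default_params, surf, elev, lc, cells,
                                  float(acc))
        assert out.k_settle == pytest.approx(default_params.k_settle,
                                             rel=1e-12)

    def test_common_factor_scaling(self, default_params):
        elev, lc, surf = self._setup()
        cells = [(1, 1)]
        acc = float(accretion_rate(30.0, 500.0, 1000.0, 0.0, default_params))
        out = calibrate_accretion(default_params, surf, elev, lc, cells,
                                  2.0 * acc)
        assert out.k_settle == pytest.approx(2 * default_params.k_settle,
                                             rel=1e-9)
        assert out.k_org == pytest.approx(2 * default_params.k_org, rel=1e-9)
        new_acc = accretion_rate(30.0, 500.0, 1000.0, 0.0, out)
        assert float(new_acc) == pytest.approx(2.0 * acc, rel=1e-9)

    def test_zero_accretion_uncalibratable(self, default_params):
        elev, lc, surf = self._setup()
        surf = Surfaces(tss=np.zeros((10, 10)),
                        ab_biomass=np.zeros((10, 10)),
                        bg_biomass=np.zeros((10, 10)))
        with pytest.raises(ValueError):
            calibrate_accretion(default_params, surf, elev, lc, [(0, 0)],
                                0.008)
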