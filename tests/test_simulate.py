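"""Forward simulator: round trips, lysate artefacts, oracle, campaigns."""

import numpy as np
import pytest

from fidascreen import fitting, physics, simulate
from fidascreen.simulate import BinderTruth, CampaignTruth, LysateModel, SpeciesState


class TestSimulateTaylorgram:
    @pytest.mark.parametrize("rh", [0.5, 1.15, 2.96, 5.0, 10.0])
    def test_noiseless_round_trip_across_radii(self, method, rh):
        tg = simulate.simulate_taylorgram(
            method, [SpeciesState(rh=rh)], None, 1.0, 50e-9, 0.0, 0)
        fit = fitting.fit_single_species(tg, method)
        assert fit.rh == pytest.approx(rh, rel=1e-3)

    def test_same_seed_bit_identical(self, method):
        a = simulate.simulate_taylorgram(
            method, [SpeciesState(rh=2.0)], LysateModel.heat(), 10.0,
            200e-9, 15.0, 123)
        b = simulate.simulate_taylorgram(
            method, [SpeciesState(rh=2.0)], LysateModel.heat(), 10.0,
            200e-9, 15.0, 123)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.time, b.time)

    def test_empty_species_rejected(self, method):
        with pytest.raises(ValueError, match="at least one species"):
            simulate.simulate_taylorgram(method, [], None, 1.0, 50e-9, 0.0, 0)

    def test_viscous_lysate_shifts_retention_by_interpolated_factor(self, method):
        lys = LysateModel(lysis_mode="heat", autofluorescence_level=0.0,
                          viscosity_factor_at_stock=1.5,
                          nonspecific_rh_shift=0.0,
                          baseline_mismatch_amplitude=0.0)
        tg = simulate.simulate_taylorgram(
            method, [SpeciesState(rh=1.15)], lys, 2.0, 50e-9, 0.0, 0)
        fit = fitting.fit_single_species(tg, method)
        tr_buffer = physics.transit_time(method, 400.0, 0.84)
        # 1 + (1.5 - 1)/2 = 1.25
        assert fit.retention_time == pytest.approx(1.25 * tr_buffer, rel=1e-3)

    def test_gross_baseline_mismatch_is_flagged_downstream(self, method):
        lys = LysateModel(lysis_mode="chemical", autofluorescence_level=0.0,
                          viscosity_factor_at_stock=1.0,
                          nonspecific_rh_shift=0.0,
                          baseline_mismatch_amplitude=10000.0)
        tg = simulate.simulate_taylorgram(
            method, [SpeciesState(rh=1.15)], lys, 2.0, 50e-9, 0.0, 0)
        _, score = fitting.estimate_baseline(tg)
        assert score > fitting.MISMATCH_THRESHOLD
        fit = fitting.fit_single_species(tg, method)
        assert physics.BASELINE_MISMATCH in fit.flags

    def test_mixture_mole_fractions_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate.check_mixture([SpeciesState(rh=1.0, mole_fraction=0.5),
                                    SpeciesState(rh=2.0, mole_fraction=0.6)])


class TestPdeOracle:
    def test_mass_conserved_under_grid_refinement(self, method):
        # integrated detector signal ~ injected amount / velocity: the
        # normalized area must be stable across refinement
        areas = []
        for nx in (1501, 3001):
            tg = simulate.pde_oracle(method, 1.15, nx=nx)
            area = np.trapezoid(tg.signal, tg.time) / tg.signal.max()
            areas.append(area)
        assert abs(areas[1] - areas[0]) / areas[0] < 0.005

    def test_fitted_rh_stable_when_halving_spatial_step(self, method):
        opts = fitting.FitOptions(taylorgram_fraction=1.0)
        fits = [fitting.fit_single_species(
            simulate.pde_oracle(method, 1.15, nx=nx), method, opts).rh
            for nx in (1501, 3001)]
        assert abs(fits[1] - fits[0]) / fits[0] < 0.005

    def test_unstable_grid_refused(self, method):
        with pytest.raises(ValueError, match="nx >= 100"):
            simulate.pde_oracle(method, 1.15, nx=50)
        with pytest.raises(ValueError, match="Peclet|plug"):
            simulate.pde_oracle(method, 0.2, nx=120)  # coarse grid, small K


class TestSimulateTitration:
    def test_zero_analyte_reads_free_radius_exactly(self):
        df = simulate.simulate_titration(
            {"kd": 2.76e-6, "rh_free": 1.15, "rh_complex": 2.4},
            50e-9, [0.0, 1e-6], replicates=1, seed=0)
        assert df.loc[df.analyte_conc_M == 0.0, "rh_apparent_nm"].iloc[0] == 1.15

    def test_fast_kinetics_limit_reproduces_equilibrium(self):
        ladder = [1e-7, 1e-6, 1e-5]
        eq = simulate.simulate_titration(
            {"kd": 1e-6, "rh_free": 1.15, "rh_complex": 2.4}, 50e-9,
            ladder, replicates=1, seed=0)
        fast = simulate.simulate_titration(
            {"kd": 1e-6, "rh_free": 1.15, "rh_complex": 2.4}, 50e-9,
            ladder, replicates=1, seed=0,
            kinetics={"k_on": 1e12, "k_off": 1e6})
        np.testing.assert_allclose(fast.rh_apparent_nm, eq.rh_apparent_nm,
                                   rtol=1e-9)

    def test_slow_association_reads_low(self):
        """Capmix caveat: slow binders under-read within the transit time."""
        ladder = [1e-6]
        slow = simulate.simulate_titration(
            {"kd": 1e-6, "rh_free": 1.15, "rh_complex": 2.4}, 50e-9,
            ladder, replicates=1, seed=0,
            kinetics={"k_on": 1e2, "k_off": 1e-4})
        eq = simulate.simulate_titration(
            {"kd": 1e-6, "rh_free": 1.15, "rh_complex": 2.4}, 50e-9,
            ladder, replicates=1, seed=0)
        assert slow.rh_apparent_nm.iloc[0] < eq.rh_apparent_nm.iloc[0]

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_titration(
                {"kd": 1e-6, "rh_free": 1.15, "rh_complex": 2.4},
                50e-9, [-1e-6], replicates=1, seed=0)


class TestSimulateCampaign:
    def test_preculture_reads_free_indicator_when_noiseless(self, method):
        truth = simulate.alfa_campaign(seed=0)
        sheet, traces, _ = simulate.simulate_campaign(
            truth, LysateModel.heat(), method, seed=0, noise_sd_signal=0.0)
        row = sheet[(sheet.role == "preculture")
                    & (sheet.dilution_factor == 30.0)].iloc[0]
        fit = fitting.fit_single_species(traces[row.trace_path], method)
        corrected = fitting.viscosity_normalize(
            fit, physics.transit_time(method, 400.0, 0.84))
        assert corrected.rh == pytest.approx(truth.indicator_rh_free, rel=2e-3)

    def test_sheet_and_truth_mutually_consistent(self):
        truth = simulate.alfa_campaign(seed=3)
        sheet, traces, record = simulate.simulate_campaign(
            truth, LysateModel.heat(), seed=3)
        binder_rows = sheet[sheet.role == "binder"]
        assert set(binder_rows.binder_id) == set(record.binder_id)
        assert set(sheet.loc[sheet.trace_path.notna(), "trace_path"]) == set(traces)
        expected = (len(truth.binders) * len(truth.dilution_ladder)
                    * truth.replicates)
        assert len(binder_rows) == expected

    def test_campaign_deterministic_given_seed(self):
        truth = simulate.gk_campaign(seed=7)
        s1, _, _ = simulate.simulate_campaign(truth, LysateModel.heat(),
                                              seed=7, output="rh")
        s2, _, _ = simulate.simulate_campaign(truth, LysateModel.heat(),
                                              seed=7, output="rh")
        assert s1.equals(s2)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            CampaignTruth(binders=(BinderTruth("x", None, 1e-6, 2.0),),
                          indicator_rh_free=1.15, indicator_conc=2e-7,
                          replicates=0)
        with pytest.raises(ValueError, match="unique"):
            CampaignTruth(binders=(BinderTruth("x", None, 1e-6, 2.0),
                                   BinderTruth("x", None, 1e-6, 2.0)),
                          indicator_rh_free=1.15, indicator_conc=2e-7)


class TestLysateModel:
    def test_chemical_default_shifts_larger_than_heat(self):
        assert (LysateModel.chemical().nonspecific_rh_shift
                > LysateModel.heat().nonspecific_rh_shift)

    def test_viscosity_interpolation_limits(self):
        lys = LysateModel.heat()
        assert lys.viscosity_factor(1.0) == lys.viscosity_factor_at_stock
        assert lys.viscosity_factor(1e9) == pytest.approx(1.0, abs=1e-6)
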