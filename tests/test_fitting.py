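"""Dispersion fitting: baseline QC, single/two-species fits, normalization."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fidascreen import fitting, physics, simulate
from fidascreen.fitting import FitError, FitOptions
from fidascreen.physics import SpeciesFit, Taylorgram
from fidascreen.simulate import SpeciesState


def _step_trace(method, step_fraction=0.2):
    """Gaussian peak of height 100 plus a flank step of known size."""
    t = np.linspace(0.0, 180.0, 1801)
    sig = physics.gaussian_model(t, 100.0, 106.0, 5.4, 0.0)
    sig += (100.0 * step_fraction) * (t > 106.0)
    return Taylorgram(time=t, signal=sig, method=method)


class TestEstimateBaseline:
    def test_flat_baseline_scores_zero(self, flat_trace):
        baseline, score = fitting.estimate_baseline(flat_trace)
        assert baseline == 0.0
        assert score == 0.0

    def test_constructed_step_mismatch_recovers_fraction(self, method):
        tg = _step_trace(method, step_fraction=0.2)
        _, score = fitting.estimate_baseline(tg)
        assert score == pytest.approx(0.2, abs=0.02)

    def test_mismatch_above_threshold_sets_flag(self, method):
        tg = _step_trace(method, step_fraction=0.2)
        fit = fitting.fit_single_species(tg, method)
        assert physics.BASELINE_MISMATCH in fit.flags
        tg_ok = _step_trace(method, step_fraction=0.01)
        fit_ok = fitting.fit_single_species(tg_ok, method)
        assert physics.BASELINE_MISMATCH not in fit_ok.flags


class TestFitSingleSpecies:
    def test_noiseless_round_trip(self, clean_trace, method):
        fit = fitting.fit_single_species(clean_trace, method)
        assert fit.rh == pytest.approx(1.15, rel=1e-3)
        assert not fit.flags

    def test_scale_invariance(self, clean_trace, method):
        fit1 = fitting.fit_single_species(clean_trace, method)
        scaled = Taylorgram(time=clean_trace.time,
                            signal=clean_trace.signal * 37.0, method=method)
        fit2 = fitting.fit_single_species(scaled, method)
        assert fit2.amplitude == pytest.approx(37.0 * fit1.amplitude, rel=1e-6)
        assert fit2.rh == pytest.approx(fit1.rh, rel=1e-6)

    def test_time_origin_shift_changes_nothing_but_tr(self, clean_trace, method):
        fit1 = fitting.fit_single_species(clean_trace, method)
        shifted = Taylorgram(time=clean_trace.time + 7.0,
                             signal=clean_trace.signal, method=method)
        fit2 = fitting.fit_single_species(shifted, method)
        assert fit2.retention_time == pytest.approx(fit1.retention_time + 7.0,
                                                    abs=1e-6)
        assert fit2.sigma_t == pytest.approx(fit1.sigma_t, rel=1e-6)

    def test_low_snr_flagged(self, method):
        tg = simulate.simulate_taylorgram(
            method, [SpeciesState(rh=1.15)], None, 1.0, 50e-9,
            noise_sd=50.0, seed=0)  # amplitude 1000 -> S/N ~ 20
        fit = fitting.fit_single_species(tg, method)
        assert physics.LOW_SNR in fit.flags

    def test_peak_narrower_than_plug_errors(self, method):
        s0 = physics.plug_sigma0(method)
        t = np.linspace(0.0, 180.0, 3601)
        sig = physics.gaussian_model(t, 100.0, 106.0, 0.5 * s0, 0.0)
        tg = Taylorgram(time=t, signal=sig, method=method)
        with pytest.raises(FitError, match="narrower than"):
            fitting.fit_single_species(tg, method)

    def test_stochastic_recovery_median_error(self, method):
        """200 seeded noisy traces over rh 0.6-5 nm, S/N 50-500:
        median |relative error| < 2%."""
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(200):
            rh = rng.uniform(0.6, 5.0)
            snr = rng.uniform(50.0, 500.0)
            tg = simulate.simulate_taylorgram(
                method, [SpeciesState(rh=rh)], None, 1.0, 50e-9,
                1000.0 / snr, rng)
            fit = fitting.fit_single_species(tg, method)
            errs.append(abs(fit.rh - rh) / rh)
        assert np.median(errs) < 0.02


class TestFitTwoSpeciesLocked:
    @pytest.fixture()
    def mixture_trace(self, method):
        species = [SpeciesState(rh=2.96, mole_fraction=0.8),
                   SpeciesState(rh=0.6, mole_fraction=0.2)]
        return simulate.simulate_taylorgram(
            method, species, None, 1.0, 80e-9, 0.0, 0)

    def test_mixture_round_trip(self, mixture_trace, method):
        opts = FitOptions(locked_rh_second_species=0.6)
        main, locked, frac = fitting.fit_two_species_locked(
            mixture_trace, method, opts)
        assert main.rh == pytest.approx(2.96, rel=0.01)
        assert frac == pytest.approx(0.8, abs=0.02)
        assert locked.rh == 0.6

    def test_zero_locked_amplitude_reduces_to_single_species(self, clean_trace,
                                                             method):
        opts = FitOptions(locked_rh_second_species=0.6)
        main, locked, _ = fitting.fit_two_species_locked(clean_trace, method,
                                                         opts)
        single = fitting.fit_single_species(clean_trace, method)
        assert main.rh == pytest.approx(single.rh, rel=1e-6)
        assert locked.amplitude == pytest.approx(0.0, abs=1e-6 * main.amplitude)

    def test_single_species_fit_on_mixture_lands_between(self, mixture_trace,
                                                         method):
        fit = fitting.fit_single_species(mixture_trace, method)
        assert 0.6 < fit.rh < 2.96

    def test_requires_locked_radius(self, clean_trace, method):
        with pytest.raises(ValueError, match="locked_rh"):
            fitting.fit_two_species_locked(clean_trace, method, FitOptions())


class TestViscosityNormalize:
    def _fit(self, rh=1.725, tr=159.5):
        return SpeciesFit(retention_time=tr, sigma_t=6.0, amplitude=100.0,
                          baseline=0.0, diffusivity=1e-10, rh=rh)

    def test_identity_when_factor_one(self):
        fit = self._fit(tr=100.0)
        out = fitting.viscosity_normalize(fit, reference_tr=100.0)
        assert out.rh == fit.rh
        assert physics.VISCOSITY_CORRECTED in out.flags

    @given(f=st.floats(0.9, 3.0))
    def test_correction_exactly_linear(self, f):
        fit = self._fit(rh=2.0, tr=100.0 * f)
        out = fitting.viscosity_normalize(fit, reference_tr=100.0)
        assert out.rh * out.viscosity_factor == pytest.approx(fit.rh, rel=1e-12)

    def test_end_to_end_correction_recovers_truth(self, method):
        lys = simulate.LysateModel(
            lysis_mode="heat", autofluorescence_level=0.0,
            viscosity_factor_at_stock=1.5, nonspecific_rh_shift=0.0,
            baseline_mismatch_amplitude=0.0)
        tg = simulate.simulate_taylorgram(
            method, [SpeciesState(rh=1.15)], lys, 1.0, 50e-9, 0.0, 0)
        fit = fitting.fit_single_species(tg, method)
        assert fit.rh == pytest.approx(1.5 * 1.15, rel=0.02)  # inflated
        out = fitting.viscosity_normalize(
            fit, physics.transit_time(method, 400.0, 0.84))
        assert out.rh == pytest.approx(1.15, rel=0.02)

    def test_suspiciously_fast_sample_warns(self):
        with pytest.warns(UserWarning, match="faster than buffer"):
            fitting.viscosity_normalize(self._fit(tr=50.0), reference_tr=100.0)


class TestReplicateSummary:
    def test_identical_fits_have_zero_sd(self):
        fits = [self._fit(1.5)] * 3
        mean, sd, n = fitting.replicate_summary(fits)
        assert (mean, sd, n) == (1.5, 0.0, 3)

    def test_hand_arithmetic(self):
        fits = [self._fit(r) for r in (1.0, 1.1, 1.2)]
        mean, sd, n = fitting.replicate_summary(fits)
        assert mean == pytest.approx(1.1)
        assert sd == pytest.approx(0.1)
        assert n == 3

    def test_single_replicate_sd_is_nan_not_zero(self):
        mean, sd, n = fitting.replicate_summary([self._fit(1.5)])
        assert math.isnan(sd) and n == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fitting.replicate_summary([])

    def test_flags_propagate_as_union(self):
        a = replace(self._fit(1.0), flags=frozenset({physics.LOW_SNR}))
        b = replace(self._fit(1.1), flags=frozenset({physics.TAYLOR_INVALID}))
        assert fitting.replicate_flags([a, b]) == frozenset(
            {physics.LOW_SNR, physics.TAYLOR_INVALID})

    @staticmethod
    def _fit(rh):
        return SpeciesFit(retention_time=100.0, sigma_t=5.0, amplitude=10.0,
                          baseline=0.0, diffusivity=1e-10, rh=rh)


class TestFitOptions:
    @pytest.mark.parametrize("kwargs", [
        {"taylorgram_fraction": 0.0},
        {"taylorgram_fraction": 1.5},
        {"locked_rh_second_species": -0.6},
        {"convergence_tol": 0.0},
    ])
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FitOptions(**kwargs)
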