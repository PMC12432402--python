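"""Extraction of hydrodynamic radii from Taylorgrams.

The fitting pipeline is: robust baseline from the trace flanks, nonlinear
Gaussian least squares restricted to the top fraction of the peak (the
"Taylorgram fraction", default 75%), optional subtraction of the injection-
plug variance, inversion of the Taylor-Aris relation to a diffusion
coefficient, and Stokes-Einstein conversion to R_h in nm.  Quality control
(signal-to-noise, baseline mismatch between the flanks, Taylor-regime
validity) is carried on the result as flags, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from . import physics
from .physics import (
    BASELINE_MISMATCH,
    LOW_SNR,
    TAYLOR_INVALID,
    VISCOSITY_CORRECTED,
    InstrumentMethod,
    SpeciesFit,
    Taylorgram,
    gaussian_model,
)

FitOptionsError = ValueError  # keeps the error taxonomy small

__all__ = [
    "FitOptions",
    "FitError",
    "estimate_baseline",
    "fit_single_species",
    "fit_two_species_locked",
    "viscosity_normalize",
    "replicate_summary",
]

FLANK_FRACTION = 0.10  # first/last 10% of samples define the flanks
MISMATCH_THRESHOLD = 0.05  # |pre - post| / peak height above this flags QC
SNR_FLOOR = 50.0  # paper-grade robust-signal floor
MAD_TO_SD = 1.4826  # normal-consistency factor for the median abs deviation


class FitError(RuntimeError):
    """Raised when a dispersion fit cannot produce a trustworthy number.

    Carries a ``diagnostics`` dict (initial guesses, data ranges, solver
    message) so batch pipelines can log the failure usefully.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the dispersion fit.

    taylorgram_fraction
        Fit only points whose baseline-corrected signal exceeds
        (1 - fraction) of the peak height, i.e. 0.75 keeps the top 75% of
        the peak.  This de-weights tailing and baseline artefacts.
    locked_rh_second_species
        When set (nm), a second Gaussian with its width pinned to this
        radius is co-fitted to absorb free-label signal (0.6 nm for the
        AF488 workflow).
    subtract_plug_sigma
        Subtract the injection-plug variance sigma0^2 (from the method's
        indicator step) in quadrature before inverting to D.  Off mimics an
        idealized point-injection analysis.
    """

    taylorgram_fraction: float = 0.75
    locked_rh_second_species: float | None = None
    subtract_plug_sigma: bool = True
    max_iterations: int = 10000
    convergence_tol: float = 1e-10

    def __post_init__(self) -> None:
        if not 0.0 < self.taylorgram_fraction <= 1.0:
            raise FitOptionsError(
                f"taylorgram_fraction must be in (0, 1], got {self.taylorgram_fraction}"
            )
        if self.locked_rh_second_species is not None and self.locked_rh_second_species <= 0:
            raise FitOptionsError("locked_rh_second_species must be > 0 nm")
        if self.convergence_tol <= 0 or self.max_iterations <= 0:
            raise FitOptionsError("tolerances and iteration caps must be > 0")


def _flanks(trace: Taylorgram) -> tuple[np.ndarray, np.ndarray]:
    n = len(trace)
    k = max(int(round(FLANK_FRACTION * n)), 3)
    if 2 * k >= n:
        raise FitError(
            f"trace of {n} points is shorter than two {k}-point flank windows",
            {"n_points": n, "flank": k},
        )
    return trace.signal[:k], trace.signal[-k:]


def estimate_baseline(trace: Taylorgram) -> tuple[float, float]:
    """Robust baseline level and flank-mismatch score.

    The baseline is the median of the pooled pre- and post-peak flanks
    (first and last 10% of samples).  The mismatch score is the absolute
    difference between the two flank medians divided by the peak height;
    lysate/buffer composition mismatch shows up as a step between the
    flanks (score > 0.05 is flagged downstream).
    """
    pre, post = _flanks(trace)
    pre_level = float(np.median(pre))
    post_level = float(np.median(post))
    baseline = float(np.median(np.concatenate([pre, post])))
    peak_height = float(trace.signal.max() - baseline)
    if peak_height <= 0:
        return baseline, 0.0
    score = abs(pre_level - post_level) / peak_height
    return baseline, score


def _noise_sd(trace: Taylorgram) -> float:
    """Robust noise SD: MAD of each flank about its own median, x 1.4826."""
    pre, post = _flanks(trace)
    devs = np.concatenate([pre - np.median(pre), post - np.median(post)])
    return float(np.median(np.abs(devs)) * MAD_TO_SD)


def _initial_guess(trace: Taylorgram, baseline: float):
    sig = trace.signal - baseline
    i_max = int(np.argmax(sig))
    amp = float(sig[i_max])
    tr = float(trace.time[i_max])
    above = sig >= 0.5 * amp
    if above.any():
        fwhm = float(trace.time[above][-1] - trace.time[above][0])
    else:
        fwhm = float(trace.time[-1] - trace.time[0]) / 10.0
    sigma = max(fwhm / 2.355, np.median(np.diff(trace.time)))
    return amp, tr, sigma


def _fraction_window(time: np.ndarray, tr: float, sigma: float,
                     fraction: float) -> np.ndarray:
    """Points within the Taylorgram fraction: model signal above
    (1 - fraction) of peak height, i.e. |t - t_R| <= sigma sqrt(-2 ln(1-f)).

    The window is computed from fitted (pass-1) parameters, never from the
    noisy samples themselves: thresholding raw samples couples the
    selection to the noise and biases the refitted width low.
    """
    if fraction >= 1.0:
        return np.ones_like(time, dtype=bool)
    half_width = sigma * math.sqrt(-2.0 * math.log(1.0 - fraction))
    return np.abs(time - tr) <= half_width


def _rh_from_sigma(sigma_t: float, tr: float, method: InstrumentMethod,
                   options: FitOptions) -> tuple[float, float, float]:
    """(sigma_eff, diffusivity, rh_nm) after optional plug subtraction."""
    if options.subtract_plug_sigma:
        s0 = physics.plug_sigma0(method)
        var = sigma_t**2 - s0**2
        if var <= 0:
            raise FitError(
                f"fitted peak (sigma={sigma_t:.3g} s) is narrower than the "
                f"injection plug (sigma0={s0:.3g} s); dispersion is unresolvable",
                {"sigma_t": sigma_t, "sigma0": s0, "retention_time": tr},
            )
        sigma_eff = math.sqrt(var)
    else:
        sigma_eff = sigma_t
    d, rh_m = physics.rh_from_peak(sigma_eff, tr, method)
    return sigma_eff, d, rh_m * 1e9


def _qc_flags(rh_nm: float, tr: float, snr: float, mismatch: float,
              method: InstrumentMethod) -> set[str]:
    flags: set[str] = set()
    if snr < SNR_FLOOR:
        flags.add(LOW_SNR)
    if mismatch > MISMATCH_THRESHOLD:
        flags.add(BASELINE_MISMATCH)
    _, valid = physics.taylor_validity(rh_nm * 1e-9, tr, method)
    if not valid:
        flags.add(TAYLOR_INVALID)
    return flags


def fit_single_species(trace: Taylorgram, method: InstrumentMethod,
                       options: FitOptions = FitOptions()) -> SpeciesFit:
    """Fit one Gaussian species and convert its width to a hydrodynamic radius.

    Least squares runs on the points above (1 - fraction) of the
    baseline-corrected peak height; D = r^2 t_R / (24 (sigma^2 - sigma0^2))
    and R_h via Stokes-Einstein.  Raises :class:`FitError` (with
    diagnostics) on non-convergence or a peak narrower than the plug.
    """
    baseline0, mismatch = estimate_baseline(trace)
    amp0, tr0, sig0 = _initial_guess(trace, baseline0)
    if amp0 <= 0:
        raise FitError("no peak above the baseline", {"baseline": baseline0})

    def run(t, y, p0):
        try:
            popt, _ = curve_fit(
                gaussian_model, t, y, p0=p0,
                bounds=([0.0, t[0] - 10 * sig0, 1e-6, -np.inf],
                        [np.inf, t[-1] + 10 * sig0, np.inf, np.inf]),
                maxfev=options.max_iterations,
                xtol=options.convergence_tol, ftol=options.convergence_tol,
            )
        except RuntimeError as exc:
            raise FitError(f"Gaussian fit did not converge: {exc}",
                           {"p0": p0, "n_points": len(t)}) from exc
        return list(map(float, popt))

    # pass 1: whole trace, all four parameters free; pass 2: refit
    # (amplitude, t_R, sigma) inside the Taylorgram fraction window derived
    # from the pass-1 peak, with the baseline fixed at its pass-1 value --
    # a free baseline is unidentifiable from top-of-peak points alone and
    # would inflate the width variance several-fold.
    popt = run(trace.time, trace.signal, [amp0, tr0, sig0, baseline0])
    baseline = popt[3]
    if options.taylorgram_fraction < 1.0:
        mask = _fraction_window(trace.time, popt[1], popt[2],
                                options.taylorgram_fraction)
        if mask.sum() < 6:
            raise FitError(
                f"only {int(mask.sum())} points fall inside the Taylorgram "
                f"fraction window; trace too sparse for a 4-parameter fit",
                {"n_selected": int(mask.sum()),
                 "fraction": options.taylorgram_fraction},
            )
        t2, y2 = trace.time[mask], trace.signal[mask]

        def peak_only(t, amp, tr, sigma):
            return gaussian_model(t, amp, tr, sigma, baseline)

        try:
            popt2, _ = curve_fit(
                peak_only, t2, y2, p0=popt[:3],
                bounds=([0.0, t2[0] - 10 * sig0, 1e-6],
                        [np.inf, t2[-1] + 10 * sig0, np.inf]),
                maxfev=options.max_iterations,
                xtol=options.convergence_tol, ftol=options.convergence_tol,
            )
        except RuntimeError as exc:
            raise FitError(f"windowed refit did not converge: {exc}",
                           {"p0": popt[:3], "n_points": int(mask.sum())}) from exc
        popt = list(map(float, popt2)) + [baseline]
    amp, tr, sigma_t, baseline = popt
    _, d, rh_nm = _rh_from_sigma(sigma_t, tr, method, options)
    noise = _noise_sd(trace)
    snr = amp / noise if noise > 0 else float("inf")
    flags = _qc_flags(rh_nm, tr, snr, mismatch, method)
    return SpeciesFit(
        retention_time=tr, sigma_t=sigma_t, amplitude=amp, baseline=baseline,
        diffusivity=d, rh=rh_nm, snr=snr, flags=frozenset(flags),
    )


def fit_two_species_locked(trace: Taylorgram, method: InstrumentMethod,
                           options: FitOptions,
                           ) -> tuple[SpeciesFit, SpeciesFit, float]:
    """Two-Gaussian fit with the second species' radius locked.

    Both species share the retention time (they co-elute in the same plug);
    the locked species' width is computed from its fixed radius at the
    shared t_R rather than fitted, so only (t_R, two amplitudes, main sigma,
    baseline) are free.  Used to absorb free-label fluorescence (0.6 nm for
    hydrolysed AF488) under the main protein peak.

    Returns (main-species fit, locked-species fit, main amplitude fraction).
    """
    if options.locked_rh_second_species is None:
        raise FitOptionsError("fit_two_species_locked requires locked_rh_second_species")
    locked_rh_m = options.locked_rh_second_species * 1e-9
    s0 = physics.plug_sigma0(method) if options.subtract_plug_sigma else 0.0

    def locked_sigma(tr: float) -> float:
        base = physics.taylor_sigma(locked_rh_m, tr, method)
        return math.sqrt(base**2 + s0**2)

    def model(t, amp_main, tr, sigma_main, amp_locked, baseline):
        out = gaussian_model(t, amp_main, tr, sigma_main, baseline)
        out += gaussian_model(t, amp_locked, tr, locked_sigma(tr), 0.0)
        return out

    baseline0, mismatch = estimate_baseline(trace)
    amp0, tr0, sig0 = _initial_guess(trace, baseline0)
    if amp0 <= 0:
        raise FitError("no peak above the baseline", {"baseline": baseline0})

    def run(t, y, p0):
        try:
            popt, _ = curve_fit(
                model, t, y, p0=p0,
                bounds=([0.0, t[0] - 10 * sig0, 1e-6, 0.0, -np.inf],
                        [np.inf, t[-1] + 10 * sig0, np.inf, np.inf, np.inf]),
                maxfev=options.max_iterations,
                xtol=options.convergence_tol, ftol=options.convergence_tol,
            )
        except RuntimeError as exc:
            raise FitError(f"two-species fit did not converge: {exc}",
                           {"p0": p0, "n_points": len(t)}) from exc
        return list(map(float, popt))

    popt = run(trace.time, trace.signal,
               [0.8 * amp0, tr0, sig0, 0.2 * amp0, baseline0])
    baseline = popt[4]
    if options.taylorgram_fraction < 1.0:
        mask = _fraction_window(trace.time, popt[1], popt[2],
                                options.taylorgram_fraction)
        if mask.sum() < 7:
            raise FitError(
                "too few points in the fraction window for a 5-parameter fit",
                {"n_selected": int(mask.sum())})
        t2, y2 = trace.time[mask], trace.signal[mask]

        def peak_only(t, amp_main, tr, sigma_main, amp_locked):
            return model(t, amp_main, tr, sigma_main, amp_locked, baseline)

        try:
            popt2, _ = curve_fit(
                peak_only, t2, y2, p0=popt[:4],
                bounds=([0.0, t2[0] - 10 * sig0, 1e-6, 0.0],
                        [np.inf, t2[-1] + 10 * sig0, np.inf, np.inf]),
                maxfev=options.max_iterations,
                xtol=options.convergence_tol, ftol=options.convergence_tol,
            )
        except RuntimeError as exc:
            raise FitError(f"windowed refit did not converge: {exc}",
                           {"p0": popt[:4], "n_points": int(mask.sum())}) from exc
        popt = list(map(float, popt2)) + [baseline]
    amp_main, tr, sigma_main, amp_locked, baseline = popt
    _, d_main, rh_main = _rh_from_sigma(sigma_main, tr, method, options)
    noise = _noise_sd(trace)
    snr = amp_main / noise if noise > 0 else float("inf")
    flags = _qc_flags(rh_main, tr, snr, mismatch, method)
    if abs(rh_main - options.locked_rh_second_species) < 0.1 * options.locked_rh_second_species:
        flags.add("DEGENERATE_SPECIES")
    main = SpeciesFit(
        retention_time=tr, sigma_t=sigma_main, amplitude=amp_main,
        baseline=baseline, diffusivity=d_main, rh=rh_main, snr=snr,
        flags=frozenset(flags),
    )
    d_locked = physics.diffusivity_from_rh(locked_rh_m, method.temperature,
                                           method.buffer_viscosity)
    locked = SpeciesFit(
        retention_time=tr, sigma_t=locked_sigma(tr), amplitude=amp_locked,
        baseline=baseline, diffusivity=d_locked,
        rh=options.locked_rh_second_species, snr=snr, flags=frozenset(),
    )
    total = amp_main + amp_locked
    main_fraction = amp_main / total if total > 0 else float("nan")
    return main, locked, main_fraction


def viscosity_normalize(fit: SpeciesFit, reference_tr: float) -> SpeciesFit:
    """Correct an apparent radius for elevated sample viscosity.

    Viscous samples slow the flow and shrink diffusion by the same factor,
    inflating the apparent R_h linearly.  The factor is estimated from the
    retention time relative to the same indicator in clean buffer:
    f = t_R / t_R(buffer); corrected R_h = apparent R_h / f.
    """
    if reference_tr <= 0:
        raise ValueError(f"reference_tr must be > 0 s, got {reference_tr}")
    f = fit.retention_time / reference_tr
    if f < 0.8:
        import warnings
        warnings.warn(
            f"sample eluted {1 / f:.2f}x faster than buffer (factor {f:.3f}); "
            "a sample less viscous than buffer is physically suspicious",
            stacklevel=2,
        )
    return replace(
        fit,
        rh=fit.rh / f,
        diffusivity=fit.diffusivity * f,
        viscosity_factor=f,
        flags=fit.flags | {VISCOSITY_CORRECTED},
    )


def replicate_summary(fits: list[SpeciesFit]) -> tuple[float, float, int]:
    """Mean and sample SD (ddof=1) of R_h over replicate fits.

    Returns (mean_rh_nm, sd_rh_nm, n); sd is NaN for n = 1 (a single
    measurement carries no spread information), never reported as 0.
    """
    if not fits:
        raise ValueError("replicate_summary requires at least one fit")
    rhs = np.array([f.rh for f in fits], dtype=float)
    mean = float(rhs.mean())
    sd = float(rhs.std(ddof=1)) if len(rhs) > 1 else float("nan")
    return mean, sd, len(rhs)


def replicate_flags(fits: list[SpeciesFit]) -> frozenset[str]:
    """Union of QC flags across replicates."""
    out: set[str] = set()
    for f in fits:
        out |= f.flags
    return frozenset(out)
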