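"""Equilibrium 1:1 binding model and KD estimation from titration data.

In a FIDA titration the labelled indicator I (at fixed, low concentration)
is mixed with increasing amounts of unlabelled binder B.  Under fast
exchange the measured apparent hydrodynamic radius is a population-weighted
average of the free and complexed indicator, so the titration curve

    Rh_app([B]) = Rh_free + f_b([B]) * (Rh_complex - Rh_free)

traces the bound fraction f_b.  Because indicator concentrations (50-200 nM)
are not always negligible against the KD (down to ~44 nM here), f_b uses the
exact depletion-corrected quadratic solution of the 1:1 mass-action law,
not the hyperbolic approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TitrationPoint",
    "TitrationResult",
    "fraction_bound",
    "apparent_rh",
    "fit_kd",
    "predict_binding_curve",
]

KD_LO, KD_HI = 1e-12, 1e-2  # M; log-scale search bounds for the KD


@dataclass(frozen=True)
class TitrationPoint:
    """One point of a titration: total analyte concentration vs apparent Rh."""

    analyte_conc: float  # M, total binder concentration [B]_tot
    rh_apparent: float  # nm
    rh_sd: float = float("nan")  # nm
    n: int = 1

    def __post_init__(self) -> None:
        if self.analyte_conc < 0:
            raise ValueError(f"analyte_conc must be >= 0, got {self.analyte_conc}")


@dataclass
class TitrationResult:
    """Fitted 1:1 binding isotherm."""

    kd: float  # M
    kd_se: float  # M
    rh_free: float  # nm
    rh_free_se: float  # nm (nan when rh_free was fixed)
    rh_complex: float  # nm
    rh_complex_se: float  # nm
    indicator_conc: float  # M
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    flags: frozenset[str] = frozenset()
    message: str = ""

    @property
    def ss_res(self) -> float:
        return float(np.sum(np.square(self.residuals)))


def fraction_bound(kd: float, indicator_conc: float, analyte_conc: float) -> float:
    """Equilibrium fraction of indicator bound in a 1:1 complex.

    Exact solution of I + B <-> IB with totals I, B and dissociation
    constant KD:

        f_b = (S - sqrt(S^2 - 4 I B)) / (2 I),   S = I + B + KD.

    Includes ligand depletion; in the trace limit I -> 0 it reduces to the
    hyperbola B / (B + KD), which is used directly when I underflows.
    """
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if indicator_conc < 0 or analyte_conc < 0:
        raise ValueError("concentrations must be >= 0")
    b = analyte_conc
    i = indicator_conc
    if b == 0.0:
        return 0.0
    if i == 0.0:
        return b / (b + kd)
    s = i + b + kd
    disc = s * s - 4.0 * i * b
    # disc >= kd^2 > 0 analytically; clip against roundoff.  The textbook
    # form (S - sqrt(disc)) / (2I) cancels catastrophically when 4IB << S^2,
    # so compute the small root as 2B / (S + sqrt(disc)) instead.
    root = math.sqrt(max(disc, 0.0))
    fb = 2.0 * b / (s + root)
    return min(max(fb, 0.0), 1.0)


def apparent_rh(frac_bound: float, rh_free: float, rh_complex: float,
                average: str = "rh") -> float:
    """Apparent hydrodynamic radius of a fast-exchanging free/bound mixture.

    Default (``average="rh"``): mole-fraction-weighted arithmetic mean of
    Rh, matching the vendor software's reporting convention.  The
    alternative ``average="diffusivity"`` weights diffusion coefficients
    instead (harmonic mean in Rh); the two differ by at most a few percent
    at intermediate saturation and coincide at the endpoints.
    """
    if not 0.0 <= frac_bound <= 1.0:
        raise ValueError(f"fraction bound must lie in [0, 1], got {frac_bound}")
    if rh_complex < rh_free:
        raise ValueError("rh_complex must be >= rh_free")
    if average == "rh":
        return rh_free + frac_bound * (rh_complex - rh_free)
    if average == "diffusivity":
        # D ~ 1/Rh: weighted mean diffusivity, then back to Rh.
        inv = (1.0 - frac_bound) / rh_free + frac_bound / rh_complex
        return 1.0 / inv
    raise ValueError(f"unknown averaging mode {average!r}")


def _model_rh(b: np.ndarray, log10_kd: float, rh_free: float, rh_complex: float,
              indicator_conc: float, average: str) -> np.ndarray:
    kd = 10.0**log10_kd
    fb = np.array([fraction_bound(kd, indicator_conc, float(x)) for x in b])
    if average == "rh":
        return rh_free + fb * (rh_complex - rh_free)
    inv = (1.0 - fb) / rh_free + fb / rh_complex
    return 1.0 / inv


def fit_kd(points: list[TitrationPoint], indicator_conc: float,
           fix_rh_free: float | None = None, average: str = "rh") -> TitrationResult:
    """Weighted nonlinear least-squares fit of the 1:1 binding isotherm.

    The KD is searched on a log10 scale within [1e-12, 1e-2] M.  Weights are
    1/sd^2 when per-point SDs are available (all finite and positive),
    unweighted otherwise.  ``fix_rh_free`` pins the free-indicator radius to
    a separately measured value (the usual practice); pass None to fit it.

    Non-identifiable data (flat response) or a KD pinned at the search
    bounds yield ``converged=False`` with an explanatory flag rather than a
    silent estimate.
    """
    if indicator_conc < 0:
        raise ValueError("indicator_conc must be >= 0")
    if len(points) < 3:
        raise ValueError(f"need at least 3 titration points, got {len(points)}")
    b = np.array([p.analyte_conc for p in points], dtype=float)
    y = np.array([p.rh_apparent for p in points], dtype=float)
    sd = np.array([p.rh_sd for p in points], dtype=float)

    distinct = np.unique(b[b > 0])
    if len(distinct) < 4 or distinct.max() / distinct.min() < 10.0:
        warnings.warn(
            "titration ladder is thin (<4 distinct concentrations or <1 decade); "
            "KD may be poorly constrained",
            stacklevel=2,
        )

    span = float(y.max() - y.min())
    noise = float(np.nanmedian(sd)) if np.any(np.isfinite(sd)) else 0.0
    if span <= 0 or (noise > 0 and span < 2.0 * noise):
        return TitrationResult(
            kd=float("nan"), kd_se=float("nan"),
            rh_free=float(y.min()), rh_free_se=float("nan"),
            rh_complex=float(y.max()), rh_complex_se=float("nan"),
            indicator_conc=indicator_conc, residuals=y - y.mean(),
            converged=False, flags=frozenset({"NO_SIGNAL"}),
            message="apparent Rh does not vary with analyte concentration; "
                    "KD is unidentifiable",
        )

    use_weights = bool(np.all(np.isfinite(sd)) and np.all(sd > 0))
    sigma = sd if use_weights else None

    rh_free0 = float(y[np.argmin(b)])
    rh_cplx0 = float(y.max()) + 0.05 * span
    # Midpoint concentration as the KD starting guess.
    half = rh_free0 + 0.5 * span
    kd0 = float(np.interp(half, np.sort(y), b[np.argsort(y)])) if span > 0 else 1e-6
    kd0 = min(max(kd0, 10 * KD_LO), KD_HI / 10)

    if fix_rh_free is not None:
        def f(bb, log_kd, rh_c):
            return _model_rh(bb, log_kd, fix_rh_free, rh_c, indicator_conc, average)
        p0 = [math.log10(kd0), rh_cplx0]
        lo = [math.log10(KD_LO), rh_free0]
        hi = [math.log10(KD_HI), 50.0]
    else:
        def f(bb, log_kd, rh_f, rh_c):
            return _model_rh(bb, log_kd, rh_f, rh_c, indicator_conc, average)
        p0 = [math.log10(kd0), rh_free0, rh_cplx0]
        lo = [math.log10(KD_LO), 0.05, 0.05]
        hi = [math.log10(KD_HI), 50.0, 50.0]

    try:
        popt, pcov = curve_fit(f, b, y, p0=p0, sigma=sigma,
                               absolute_sigma=use_weights,
                               bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        return TitrationResult(
            kd=float("nan"), kd_se=float("nan"),
            rh_free=rh_free0, rh_free_se=float("nan"),
            rh_complex=rh_cplx0, rh_complex_se=float("nan"),
            indicator_conc=indicator_conc, residuals=np.full_like(y, np.nan),
            converged=False, flags=frozenset({"NO_CONVERGENCE"}),
            message=f"least-squares did not converge: {exc}",
        )

    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    kd = 10.0**popt[0]
    # delta method: se(kd) = kd * ln(10) * se(log10 kd)
    kd_se = kd * math.log(10.0) * perr[0]
    flags: set[str] = set()
    converged = True
    margin = 0.01  # log10 units from the search bounds
    if popt[0] <= math.log10(KD_LO) + margin or popt[0] >= math.log10(KD_HI) - margin:
        flags.add("KD_AT_BOUND")
        converged = False

    if fix_rh_free is not None:
        rh_free, rh_free_se = fix_rh_free, float("nan")
        rh_complex, rh_complex_se = float(popt[1]), float(perr[1])
    else:
        rh_free, rh_free_se = float(popt[1]), float(perr[1])
        rh_complex, rh_complex_se = float(popt[2]), float(perr[2])

    residuals = y - f(b, *popt)
    return TitrationResult(
        kd=float(kd), kd_se=float(kd_se),
        rh_free=rh_free, rh_free_se=rh_free_se,
        rh_complex=rh_complex, rh_complex_se=rh_complex_se,
        indicator_conc=indicator_conc, residuals=residuals,
        converged=converged, flags=frozenset(flags),
    )


def predict_binding_curve(result: TitrationResult, indicator_conc: float,
                          analyte_grid: np.ndarray,
                          average: str = "rh") -> np.ndarray:
    """Model curve Rh_app(B) on a concentration grid, for plots and reports."""
    if not result.converged or not np.isfinite(result.kd):
        raise ValueError("cannot predict from a non-converged titration result")
    grid = np.asarray(analyte_grid, dtype=float)
    fb = np.array([fraction_bound(result.kd, indicator_conc, float(x)) for x in grid])
    return np.array([
        apparent_rh(float(f), result.rh_free, result.rh_complex, average=average)
        for f in fb
    ])
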