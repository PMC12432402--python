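"""Physical model of the FIDA capillary experiment.

Flow-induced dispersion analysis (FIDA) pushes a fluorescent indicator plug
through a narrow capillary under pressure-driven (Poiseuille) flow.  Radial
diffusion averages the indicator over the parabolic velocity profile, so the
plug arrives at the detection window as a near-Gaussian peak (a "Taylorgram")
whose width encodes the molecular diffusion coefficient D and hence, through
the Stokes-Einstein relation, the hydrodynamic radius R_h.

This module owns the physical symbols and unit conventions used everywhere
else: lengths in metres, pressures in mbar at the interface (Pa internally),
times in seconds, viscosities in Pa·s, temperatures in kelvin, and R_h in
metres at the physics layer (nanometres only in user-facing tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BOLTZMANN",
    "TAU_MIN",
    "InstrumentMethod",
    "Taylorgram",
    "SpeciesFit",
    "transit_time",
    "mean_velocity",
    "stokes_einstein",
    "diffusivity_from_rh",
    "taylor_sigma",
    "rh_from_peak",
    "taylor_validity",
    "gaussian_model",
    "plug_sigma0",
]

BOLTZMANN = 1.380649e-23  # J/K (exact, SI 2019)

#: Minimum dimensionless residence time tau = D * t_R / r**2 for the
#: Taylor-Aris dispersion limit to hold.  Standard TDA practice places the
#: regime boundary near 1.4; below it the peak is not a simple Gaussian and
#: the fitted R_h is unreliable.
TAU_MIN = 1.4

MBAR_TO_PA = 100.0

# QC flags carried on fits.
LOW_SNR = "LOW_SNR"
BASELINE_MISMATCH = "BASELINE_MISMATCH"
TAYLOR_INVALID = "TAYLOR_INVALID"
VISCOSITY_CORRECTED = "VISCOSITY_CORRECTED"


def _default_steps() -> tuple[tuple[str, float, float], ...]:
    # (label, pressure mbar, duration s): the standard coated-capillary
    # four-step program; data are recorded during the final mobilization.
    return (
        ("equilibrate", 3500.0, 75.0),
        ("analyte_load", 3500.0, 20.0),
        ("indicator_inject", 50.0, 10.0),
        ("mobilize", 400.0, 180.0),
    )


@dataclass(frozen=True)
class InstrumentMethod:
    """Capillary geometry, conditions, and the pressure program.

    Defaults describe a 75 um inner-diameter, 1 m capillary with the
    detection window 84 cm downstream, run at room temperature in a
    water-like buffer.
    """

    capillary_radius: float = 37.5e-6  # m
    total_length: float = 1.0  # m
    detect_length: float = 0.84  # m
    temperature: float = 298.15  # K
    buffer_viscosity: float = 8.9e-4  # Pa s
    steps: tuple[tuple[str, float, float], ...] = field(default_factory=_default_steps)

    def __post_init__(self) -> None:
        for name in ("capillary_radius", "total_length", "detect_length",
                     "temperature", "buffer_viscosity"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.detect_length >= self.total_length:
            raise ValueError(
                f"detect_length ({self.detect_length}) must be smaller than "
                f"total_length ({self.total_length})"
            )
        if not self.steps:
            raise ValueError("pressure program must contain at least one step")
        for label, p, d in self.steps:
            if p <= 0 or d <= 0:
                raise ValueError(f"step {label!r}: pressure and duration must be > 0")
        if self.steps[-1][0] != "mobilize":
            raise ValueError("last program step must be the mobilization step")

    @property
    def mobilize_pressure(self) -> float:
        """Pressure (mbar) of the final mobilization step."""
        return self.steps[-1][1]

    @property
    def mobilize_duration(self) -> float:
        return self.steps[-1][2]

    def step(self, label: str) -> tuple[str, float, float]:
        for s in self.steps:
            if s[0] == label:
                return s
        raise KeyError(f"no program step labelled {label!r}")

    def with_(self, **kwargs) -> "InstrumentMethod":
        return replace(self, **kwargs)


@dataclass
class Taylorgram:
    """A time-ordered fluorescence trace plus acquisition metadata.

    The atomic observable of the pipeline: ``signal[i]`` is the detector
    reading (arbitrary fluorescence units) at ``time[i]`` seconds after the
    start of the mobilization step.
    """

    time: np.ndarray
    signal: np.ndarray
    indicator_id: str = "indicator"
    indicator_conc: float = float("nan")  # M
    analyte_id: str = ""
    analyte_conc: float = 0.0  # M
    dilution_factor: float = 1.0
    replicate_index: int = 0
    method: InstrumentMethod | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays")
        if len(self.time) != len(self.signal):
            raise ValueError(
                f"time ({len(self.time)}) and signal ({len(self.signal)}) "
                "must have equal length"
            )
        if len(self.time) < 50:
            raise ValueError(f"trace too short: {len(self.time)} points (< 50)")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(
                f"time must be strictly increasing; violation at row {i + 1} "
                f"(t[{i}]={self.time[i]!r} >= t[{i + 1}]={self.time[i + 1]!r})"
            )
        if self.dilution_factor < 1:
            raise ValueError(f"dilution_factor must be >= 1, got {self.dilution_factor}")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def meta(self) -> dict:
        return {
            "indicator_id": self.indicator_id,
            "indicator_conc": self.indicator_conc,
            "analyte_id": self.analyte_id,
            "analyte_conc": self.analyte_conc,
            "dilution_factor": self.dilution_factor,
            "replicate_index": self.replicate_index,
        }


@dataclass
class SpeciesFit:
    """Result of dispersion fitting one species from a Taylorgram."""

    retention_time: float  # s
    sigma_t: float  # s
    amplitude: float  # fluorescence units
    baseline: float  # fluorescence units
    diffusivity: float  # m^2/s
    rh: float  # nm
    rh_sd: float = float("nan")  # nm
    snr: float = float("nan")
    viscosity_factor: float = 1.0
    flags: frozenset[str] = frozenset()
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.sigma_t <= 0:
            raise ValueError(f"sigma_t must be > 0, got {self.sigma_t}")
        if self.rh <= 0 or self.diffusivity <= 0:
            raise ValueError("rh and diffusivity must be > 0")
        if not math.isnan(self.snr) and self.snr < 0:
            raise ValueError("snr must be >= 0")
        self.flags = frozenset(self.flags)

    def with_flags(self, *new: str) -> "SpeciesFit":
        out = replace(self, flags=self.flags | frozenset(new))
        return out


def mean_velocity(method: InstrumentMethod, pressure_mbar: float,
                  viscosity_factor: float = 1.0) -> float:
    """Cross-section-averaged Poiseuille velocity (m/s) at a given pressure.

    v = dP * r^2 / (8 * eta * L) with dP across the full capillary length.
    ``viscosity_factor`` scales the buffer viscosity to model viscous samples.
    """
    if pressure_mbar <= 0:
        raise ValueError(f"pressure must be > 0 mbar, got {pressure_mbar}")
    if viscosity_factor <= 0:
        raise ValueError("viscosity_factor must be > 0")
    dp = pressure_mbar * MBAR_TO_PA
    eta = method.buffer_viscosity * viscosity_factor
    return dp * method.capillary_radius**2 / (8.0 * eta * method.total_length)


def transit_time(method: InstrumentMethod, pressure_mbar: float,
                 length: float, viscosity_factor: float = 1.0) -> float:
    """Time (s) for the plug to travel ``length`` metres under laminar flow.

    With the default method at the 400 mbar mobilization pressure the
    84 cm transit takes ~106 s, i.e. under 1.8 min -- the available
    in-capillary reaction time for capmix experiments.
    """
    if length <= 0:
        raise ValueError(f"length must be > 0 m, got {length}")
    if length > method.total_length:
        raise ValueError(
            f"length ({length} m) exceeds capillary total_length "
            f"({method.total_length} m)"
        )
    return length / mean_velocity(method, pressure_mbar, viscosity_factor)


def stokes_einstein(diffusivity: float, temperature: float, viscosity: float) -> float:
    """Hydrodynamic radius (m) from the Stokes-Einstein relation.

    R_h = k_B T / (6 pi eta D).  The same closed form converts R_h back to D
    (the relation is its own inverse with D and R_h exchanged), which
    :func:`diffusivity_from_rh` exposes for readability.
    """
    for name, v in (("diffusivity", diffusivity), ("temperature", temperature),
                    ("viscosity", viscosity)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be strictly positive, got {v!r}")
    return BOLTZMANN * temperature / (6.0 * math.pi * viscosity * diffusivity)


def diffusivity_from_rh(rh: float, temperature: float, viscosity: float) -> float:
    """Diffusion coefficient (m^2/s) of a Stokes sphere of radius ``rh`` (m)."""
    return stokes_einstein(rh, temperature, viscosity)


def taylor_sigma(rh: float, retention_time: float, method: InstrumentMethod) -> float:
    """Temporal Gaussian SD (s) of the Taylorgram peak for a species of
    hydrodynamic radius ``rh`` (m) eluting at ``retention_time`` (s).

    Taylor-Aris dispersion gives sigma_t^2 = r^2 t_R / (24 D) for
    cross-section-averaged detection, with D from Stokes-Einstein at the
    method's temperature and buffer viscosity.
    """
    if rh <= 0 or retention_time <= 0:
        raise ValueError("rh and retention_time must be > 0")
    d = diffusivity_from_rh(rh, method.temperature, method.buffer_viscosity)
    return math.sqrt(method.capillary_radius**2 * retention_time / (24.0 * d))


def rh_from_peak(sigma_t: float, retention_time: float,
                 method: InstrumentMethod) -> tuple[float, float]:
    """Invert Taylor-Aris: (diffusivity m^2/s, rh m) from peak shape.

    D = r^2 t_R / (24 sigma_t^2); exact algebraic inverse of
    :func:`taylor_sigma`.
    """
    if sigma_t <= 0 or retention_time <= 0:
        raise ValueError("sigma_t and retention_time must be > 0")
    d = method.capillary_radius**2 * retention_time / (24.0 * sigma_t**2)
    rh = stokes_einstein(d, method.temperature, method.buffer_viscosity)
    return d, rh


def taylor_validity(rh: float, retention_time: float,
                    method: InstrumentMethod) -> tuple[float, bool]:
    """Dimensionless residence time tau = D t_R / r^2 and the regime check.

    Taylor-Aris dispersion requires radial diffusion to sample the full
    cross-section during transit; tau >= TAU_MIN (1.4) is the heuristic
    regime bound.  Large, slow species at short retention times fail it.
    """
    if rh <= 0 or retention_time <= 0:
        raise ValueError("rh and retention_time must be > 0")
    d = diffusivity_from_rh(rh, method.temperature, method.buffer_viscosity)
    tau = d * retention_time / method.capillary_radius**2
    return tau, tau >= TAU_MIN


def gaussian_model(time: np.ndarray, amplitude: float, retention_time: float,
                   sigma_t: float, baseline: float) -> np.ndarray:
    """Gaussian Taylorgram model s(t) = baseline + A exp(-(t-t_R)^2/(2 sigma^2))."""
    if sigma_t <= 0:
        raise ValueError(f"sigma_t must be > 0, got {sigma_t}")
    t = np.asarray(time, dtype=float)
    z = (t - retention_time) / sigma_t
    return baseline + amplitude * np.exp(-0.5 * z * z)


def plug_sigma0(method: InstrumentMethod) -> float:
    """Temporal SD (s) contributed by the finite injection plug.

    The indicator step (duration t_i at pressure p_i) lays down a plug of
    length v(p_i) * t_i; crossing the detector at the mobilization velocity
    it spans w = plug_length / v_mobilize seconds.  A top-hat of width w has
    SD w / sqrt(12); this is added to the Taylor broadening in quadrature by
    the simulator and (optionally) subtracted by the fitter.
    """
    _, p_inj, t_inj = method.step("indicator_inject")
    plug_len = mean_velocity(method, p_inj) * t_inj
    width_s = plug_len / mean_velocity(method, method.mobilize_pressure)
    return width_s / math.sqrt(12.0)
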