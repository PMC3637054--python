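"""Uricase reaction kinetics and synthetic absorbance traces.

Uricase oxidizes uric acid (UA) to 5-hydroxyisourate (HIU), which
spontaneously decomposes to allantoin (no UV absorbance above 280 nm):

    UA --(Michaelis-Menten, Km, Vmax)--> HIU --(first order, k_d)--> allantoin

    dS/dt = -v(S),   dH/dt = v(S) - k_d H,   dAll/dt = k_d H,
    v(S)  = Vmax S / (Km + S)

Both UA and HIU absorb in the 290-310 nm window, so a spectrophotometric
trace A(t) = l (eps_UA S + eps_HIU H) can *rise* early in the reaction when
the HIU extinction at the monitoring wavelength exceeds that of uric acid
(the case at 308 nm), biasing initial-rate assays.  The HIU decomposition
rate depends on buffer and pH — fast in alkaline borate, slow in Tris-HCl
near pH 7.4 — which is what makes alkaline borate the reliable assay buffer.

k_d is parameterized as

    k_d(buffer, pH) = k_ref * 10**(PH_SLOPE * (pH - 7.4)) * m_buffer * m_Mg

with k_ref anchored by :func:`calibrate_interference_model` to the observed
absorbance peak at ~100 s (Tris pH 7.4, 103 U/L, 0.30 mM UA, 308 nm).
No published rate constants exist for this system; the parameterization is
the minimal mechanism consistent with the qualitative interference
phenomenology, and amplitudes are conventions, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    CalibrationError,
    ConfigurationError,
    DomainError,
    InvalidGridError,
    InvalidModelError,
)

__all__ = [
    "AssayCondition",
    "KineticModel",
    "ConcentrationSeries",
    "AbsorbanceTrace",
    "simulate_reaction",
    "render_absorbance",
    "activity_to_vmax",
    "vmax_to_activity",
    "k_d_value",
    "calibrate_interference_model",
    "default_k_ref",
    "default_kinetic_model",
    "DEFAULT_EPS_UA",
    "DEFAULT_EPS_HIU",
    "PH_SLOPE",
    "BUFFER_FACTOR",
]

BUFFERS = ("tris", "borate")

#: Uric acid extinction coefficients, mM^-1 cm^-1.  293 nm is the published
#: assay value; 308 nm is a model convention bounded by the requirement that
#: 0.4 mM uric acid reads below 1.200 AU (so eps_ua(308) < 3.0).
DEFAULT_EPS_UA: Mapping[float, float] = {293.0: 11.5, 308.0: 2.9}

#: HIU extinction coefficients, mM^-1 cm^-1 (model conventions; HIU peaks
#: near 302 nm so its coefficient at 308 nm exceeds the uric acid one there,
#: while at 293 nm it is small relative to uric acid's 11.5).
DEFAULT_EPS_HIU: Mapping[float, float] = {293.0: 1.4, 308.0: 4.2}

#: Decades of k_d per pH unit (HIU decay accelerates with pH).
PH_SLOPE = 0.6

#: Buffer multipliers on k_d; borate strongly accelerates HIU decay.
BUFFER_FACTOR = {"tris": 1.0, "borate": 10.0}


def _lookup_eps(eps_map: Mapping[float, float], wavelength_nm: float, what: str) -> float:
    for wl, eps in eps_map.items():
        if abs(float(wl) - float(wavelength_nm)) <= 0.5:
            return float(eps)
    raise ConfigurationError(
        f"no {what} extinction coefficient for wavelength {wavelength_nm} nm "
        f"(available: {sorted(float(w) for w in eps_map)})"
    )


@dataclass(frozen=True)
class AssayCondition:
    """Cuvette-level assay conditions.

    Volumes follow the published protocol: 50 uL enzyme solution into a
    0.80 mL reaction, i.e. a 16x dilution of the enzyme sample.
    """

    buffer: str = "borate"
    pH: float = 9.2
    wavelength_nm: float = 293.0
    temperature_C: float = 25.0
    path_length_cm: float = 1.0
    reaction_volume_mL: float = 0.80
    enzyme_volume_uL: float = 50.0

    def __post_init__(self):
        if self.buffer not in BUFFERS:
            raise ConfigurationError(f"unknown buffer {self.buffer!r}; expected one of {BUFFERS}")
        if not 6.0 <= self.pH <= 11.0:
            raise ConfigurationError(f"pH {self.pH} outside supported range [6, 11]")
        if not 280.0 <= self.wavelength_nm <= 320.0:
            raise ConfigurationError(
                f"wavelength {self.wavelength_nm} nm outside supported range [280, 320]"
            )
        if self.path_length_cm <= 0 or self.reaction_volume_mL <= 0 or self.enzyme_volume_uL <= 0:
            raise ConfigurationError("path length and volumes must be positive")
        if self.enzyme_volume_uL >= 1000.0 * self.reaction_volume_mL:
            raise ConfigurationError("enzyme volume must be smaller than the reaction volume")

    @property
    def dilution_factor(self) -> float:
        """Sample dilution into the cuvette (800/50 = 16 by default)."""
        return 1000.0 * self.reaction_volume_mL / self.enzyme_volume_uL


@dataclass(frozen=True)
class KineticModel:
    """Kinetic and spectral parameters driving the simulator.

    Km_mM, Vmax_mM_per_min: Michaelis-Menten parameters in the cuvette.
    k_d_per_s: first-order HIU decomposition rate.
    eps_ua, eps_hiu: wavelength (nm) -> extinction coefficient (mM^-1 cm^-1).
    """

    Km_mM: float
    Vmax_mM_per_min: float
    k_d_per_s: float
    eps_ua: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_EPS_UA))
    eps_hiu: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_EPS_HIU))

    def __post_init__(self):
        for name, value in (
            ("Km_mM", self.Km_mM),
            ("Vmax_mM_per_min", self.Vmax_mM_per_min),
            ("k_d_per_s", self.k_d_per_s),
        ):
            if not math.isfinite(value):
                raise InvalidModelError(f"{name} must be finite, got {value}")
            if value < 0:
                raise InvalidModelError(f"{name} must be nonnegative, got {value}")
        if self.Km_mM == 0:
            raise InvalidModelError("Km_mM must be positive")
        for what, eps_map in (("eps_ua", self.eps_ua), ("eps_hiu", self.eps_hiu)):
            for wl, eps in eps_map.items():
                if not (math.isfinite(eps) and eps >= 0):
                    raise InvalidModelError(f"{what}[{wl}] must be finite and nonnegative")

    def eps_ua_at(self, wavelength_nm: float) -> float:
        return _lookup_eps(self.eps_ua, wavelength_nm, "uric acid")

    def eps_hiu_at(self, wavelength_nm: float) -> float:
        return _lookup_eps(self.eps_hiu, wavelength_nm, "HIU")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Species concentrations on a shared time grid (mM vs seconds)."""

    times_s: np.ndarray
    ua_mM: np.ndarray
    hiu_mM: np.ndarray
    allantoin_mM: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        if t.ndim != 1 or t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise InvalidGridError("times_s must be strictly increasing from 0")

    @property
    def ua0_mM(self) -> float:
        return float(self.ua_mM[0])


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A timestamped absorbance series from one simulated reaction."""

    times_s: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float
    condition: AssayCondition | None = None
    noise_sd: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ConfigurationError("times_s and absorbance must be 1-d arrays of equal length")
        if np.any(t < 0):
            raise ConfigurationError("times_s must be nonnegative")
        if not np.all(np.isfinite(a)):
            raise ConfigurationError("absorbance must be finite")


def activity_to_vmax(activity_U_per_L: float) -> float:
    """Convert a cuvette activity (U/L) to Vmax in mM/min.

    One unit oxidizes 1 umol uric acid per minute, so
    1 U/L = 1 umol min^-1 L^-1 = 1e-3 mM min^-1.
    """
    if activity_U_per_L < 0:
        raise DomainError(f"activity must be nonnegative, got {activity_U_per_L}")
    return activity_U_per_L * 1e-3


def vmax_to_activity(vmax_mM_per_min: float) -> float:
    """Inverse of :func:`activity_to_vmax`."""
    if vmax_mM_per_min < 0:
        raise DomainError(f"Vmax must be nonnegative, got {vmax_mM_per_min}")
    return vmax_mM_per_min * 1e3


def simulate_reaction(
    model: KineticModel,
    ua0_mM: float,
    duration_s: float,
    step_s: float,
    rtol: float = 1e-8,
    clamp_substrate: bool = False,
) -> ConcentrationSeries:
    """Integrate the two-species ODE and return mass-conserving series.

    ``clamp_substrate`` holds the substrate at ``ua0_mM`` (constant
    production rate), a test mode exposing the HIU steady state v/k_d.
    Allantoin is computed by difference, so UA + HIU + allantoin == ua0
    to solver round-off at every grid point.
    """
    if not (math.isfinite(ua0_mM) and ua0_mM > 0):
        raise DomainError(f"ua0_mM must be positive and finite, got {ua0_mM}")
    if duration_s <= 0 or step_s <= 0:
        raise InvalidGridError("duration_s and step_s must be positive")
    if step_s > duration_s:
        raise InvalidGridError(f"step_s ({step_s}) exceeds duration_s ({duration_s})")

    vmax_per_s = model.Vmax_mM_per_min / 60.0
    km = model.Km_mM
    kd = model.k_d_per_s

    def rhs(_t, y):
        s, h = y
        s = max(s, 0.0)
        src = ua0_mM if clamp_substrate else s
        v = vmax_per_s * src / (km + src)
        ds = 0.0 if clamp_substrate else -v
        return (ds, v - kd * h)

    t_eval = np.arange(0.0, duration_s + 0.5 * step_s, step_s)
    if t_eval[-1] < duration_s - 1e-9:
        t_eval = np.append(t_eval, duration_s)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        (ua0_mM, 0.0),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=1e-13,
    )
    if not sol.success:  # pragma: no cover - LSODA handles this system easily
        raise CalibrationError(f"ODE integration failed: {sol.message}")
    ua = np.clip(sol.y[0], 0.0, ua0_mM)
    hiu = np.maximum(sol.y[1], 0.0)
    allantoin = np.maximum(ua0_mM - ua - hiu, 0.0)
    return ConcentrationSeries(t_eval, ua, hiu, allantoin)


def render_absorbance(
    series: ConcentrationSeries,
    model: KineticModel,
    condition: AssayCondition,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> AbsorbanceTrace:
    """Beer-Lambert composition of the two absorbers plus Gaussian noise.

    A(t) = l * (eps_UA(lambda) * UA(t) + eps_HIU(lambda) * HIU(t)) + N(0, noise_sd)
    """
    wl = condition.wavelength_nm
    eps_ua = model.eps_ua_at(wl)
    eps_hiu = model.eps_hiu_at(wl)
    absorbance = condition.path_length_cm * (eps_ua * series.ua_mM + eps_hiu * series.hiu_mM)
    if noise_sd < 0:
        raise DomainError("noise_sd must be nonnegative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=absorbance.shape)
    return AbsorbanceTrace(
        times_s=np.asarray(series.times_s, dtype=float),
        absorbance=absorbance,
        wavelength_nm=wl,
        condition=condition,
        noise_sd=noise_sd,
    )


def k_d_value(
    buffer: str,
    pH: float,
    k_ref_per_s: float,
    ph_slope: float = PH_SLOPE,
    buffer_factor: Mapping[str, float] | None = None,
    mg_factor: float = 1.0,
) -> float:
    """HIU decomposition rate for a buffer/pH, anchored at Tris pH 7.4.

    ``mg_factor`` is an optional multiplier for magnesium-accelerated decay
    (default 1.0, off); no quantitative magnesium claim is modeled.
    """
    factors = dict(BUFFER_FACTOR if buffer_factor is None else buffer_factor)
    if buffer not in factors:
        raise ConfigurationError(f"unknown buffer {buffer!r}")
    if mg_factor <= 0:
        raise DomainError("mg_factor must be positive")
    return k_ref_per_s * 10.0 ** (ph_slope * (pH - 7.4)) * factors[buffer] * mg_factor


def _peak_time(model: KineticModel, condition: AssayCondition, ua0_mM: float,
               duration_s: float = 300.0, step_s: float = 1.0) -> float:
    series = simulate_reaction(model, ua0_mM, duration_s, step_s)
    trace = render_absorbance(series, model, condition)
    return float(trace.times_s[int(np.argmax(trace.absorbance))])


_CALIBRATION_CACHE: dict = {}


def calibrate_interference_model(
    condition: AssayCondition,
    activity_U_per_L: float = 103.0,
    ua0_mM: float = 0.30,
    target_peak_time_s: float = 100.0,
    Km_mM: float = 0.25,
    bracket: tuple[float, float] = (1e-4, 1.0),
    eps_ua: Mapping[float, float] | None = None,
    eps_hiu: Mapping[float, float] | None = None,
) -> KineticModel:
    """Find k_d such that the simulated absorbance peaks at the target time.

    The observed anchor is the A308 maximum at ~100 s in Tris pH 7.4 with
    0.30 mM uric acid at 103 U/L.  Peak time decreases monotonically with
    k_d, so a bisection on the bracket suffices.  Results are cached on the
    full argument set.
    """
    if target_peak_time_s <= 0:
        raise DomainError("target_peak_time_s must be positive")
    eps_ua = dict(DEFAULT_EPS_UA if eps_ua is None else eps_ua)
    eps_hiu = dict(DEFAULT_EPS_HIU if eps_hiu is None else eps_hiu)
    key = (
        condition.buffer, round(condition.pH, 4), round(condition.wavelength_nm, 1),
        round(activity_U_per_L, 6), round(ua0_mM, 6), round(target_peak_time_s, 3),
        round(Km_mM, 6), tuple(sorted(eps_ua.items())), tuple(sorted(eps_hiu.items())),
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    vmax = activity_to_vmax(activity_U_per_L)

    def make(kd):
        return KineticModel(Km_mM, vmax, kd, eps_ua, eps_hiu)

    lo, hi = bracket
    f_lo = _peak_time(make(lo), condition, ua0_mM) - target_peak_time_s
    f_hi = _peak_time(make(hi), condition, ua0_mM) - target_peak_time_s
    if not (f_lo > 0 > f_hi):
        raise CalibrationError(
            f"no k_d in bracket {bracket} gives a peak at {target_peak_time_s} s "
            f"(peak times {f_lo + target_peak_time_s:.1f} s and "
            f"{f_hi + target_peak_time_s:.1f} s at the bracket ends)"
        )
    for _ in range(60):
        mid = math.sqrt(lo * hi)  # bisect on log scale
        if _peak_time(make(mid), condition, ua0_mM) > target_peak_time_s:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0 + 1e-6:
            break
    model = make(math.sqrt(lo * hi))
    _CALIBRATION_CACHE[key] = model
    return model


_K_REF: dict = {}


def default_k_ref() -> float:
    """Package-default k_ref (s^-1): k_d at Tris pH 7.4, calibrated once
    against the ~100 s A308 peak anchor and cached."""
    if "k_ref" not in _K_REF:
        condition = AssayCondition(buffer="tris", pH=7.4, wavelength_nm=308.0)
        _K_REF["k_ref"] = calibrate_interference_model(condition).k_d_per_s
    return _K_REF["k_ref"]


def default_kinetic_model(
    condition: AssayCondition,
    activity_U_per_L: float,
    Km_mM: float = 0.25,
    mg_factor: float = 1.0,
) -> KineticModel:
    """Build the package-default model for a condition and activity."""
    kd = k_d_value(condition.buffer, condition.pH, default_k_ref(), mg_factor=mg_factor)
    return KineticModel(Km_mM, activity_to_vmax(activity_U_per_L), kd)


def with_activity(model: KineticModel, activity_U_per_L: float) -> KineticModel:
    """Same kinetic/spectral parameters at a different enzyme activity."""
    return replace(model, Vmax_mM_per_min=activity_to_vmax(activity_U_per_L))
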