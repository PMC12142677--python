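"""Drift-time to collision-cross-section calibration for traveling-wave
cyclic ion mobility.

Two calibration routes are implemented:

* **instrument default** (single pass): ADC drift bins are converted to
  milliseconds, corrected for the m/z-dependent transfer time (EDC term),
  mapped linearly to charge/reduced-mass-corrected CCS, and finally converted
  to CCS:

  .. math::

      t_d(\\mathrm{ms}) = t_d(\\mathrm{bins}) \\cdot V_{ADC} / 1000, \\qquad
      t_c^* = t_d(\\mathrm{ms}) - C\\sqrt{m/z}, \\qquad
      \\Omega_c = m\\, t_c^* + b, \\qquad
      \\Omega = \\Omega_c \\, z \\sqrt{1/\\mu}

* **multipass**: arrival-time distributions recorded at several pass
  counts/separation times are reduced to apexes by Gaussian fitting, the
  periodic drift time :math:`t_{pp}` is extracted by the linear regression

  .. math::

      (t_{nd} - t_s)/n = t_{pp} - (v_u/v_p)\\,(t_s/n)

  (intercept :math:`t_{pp}`, slope :math:`-v_u/v_p`), and corrected CCS is
  calibrated against :math:`t_{pp}` by a power law
  :math:`\\Omega_c = A\\, t_{pp}^B` fitted in log--log space.

The regression arrangement for the multipass model is isolated in
:func:`fit_tpp` so an alternate arrangement is a one-function change.  The
power law calibrates *corrected* CCS (reference CCS divided by
:math:`z\\sqrt{1/\\mu}`) and is back-transformed per ion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .masscalc import N2, DriftGas, reduced_mass

__all__ = [
    "DriftMeasurement",
    "LinearCalModel",
    "GaussianPeak",
    "MultipassObservation",
    "MultipassFit",
    "PowerLawModel",
    "CCSValue",
    "bins_to_ms",
    "edc_correct",
    "fit_linear_calibration",
    "corrected_to_ccs",
    "ccs_to_corrected",
    "fit_gaussian_peak",
    "fit_tpp",
    "fit_powerlaw",
    "fit_multipass_calibration",
    "ccs_percent_error",
    "default_ccs",
    "invert_default_ccs",
    "estimate_tpp",
    "multipass_ccs",
]


# --------------------------------------------------------------------------
# elementary conversions
# --------------------------------------------------------------------------

def bins_to_ms(t_d_bins: float, pusher_period_us: float) -> float:
    """Convert drift time in ADC bins to milliseconds.

    One bin corresponds to one ADC pusher period (microseconds).
    """
    if t_d_bins < 0 or pusher_period_us < 0:
        raise ValueError("drift bins and pusher period must be non-negative")
    return t_d_bins * pusher_period_us / 1000.0


def edc_correct(
    t_d_ms: float, edc_coefficient: float, mz: float, *, unit_factor: float = 1.0
) -> float:
    """Remove the m/z-dependent transfer-time term: t_c* = t_d - C*sqrt(m/z).

    ``unit_factor`` rescales the instrument's EDC coefficient if the metadata
    field is recorded on a different scale than milliseconds per sqrt(Th).
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    t_c = t_d_ms - edc_coefficient * unit_factor * math.sqrt(mz)
    if t_c <= 0:
        raise ValueError(
            f"corrected drift time {t_c:.6g} ms is non-physical "
            f"(t_d={t_d_ms} ms, C={edc_coefficient}, m/z={mz})"
        )
    return t_c


def corrected_to_ccs(ccs_corrected: float, z: int, mu: float) -> float:
    """CCS from corrected CCS: Omega = Omega_c * z * sqrt(1/mu)."""
    if ccs_corrected <= 0:
        raise ValueError("corrected CCS must be positive")
    if z < 1:
        raise ValueError("charge must be >= 1")
    if mu <= 0:
        raise ValueError("reduced mass must be positive")
    return ccs_corrected * z * math.sqrt(1.0 / mu)


def ccs_to_corrected(ccs: float, z: int, mu: float) -> float:
    """Inverse of :func:`corrected_to_ccs` (used when calibrating and by the
    simulator)."""
    if ccs <= 0:
        raise ValueError("CCS must be positive")
    if z < 1:
        raise ValueError("charge must be >= 1")
    if mu <= 0:
        raise ValueError("reduced mass must be positive")
    return ccs / (z * math.sqrt(1.0 / mu))


def ccs_percent_error(
    experimental: float, reference: float, *, signed: bool = False
) -> float:
    """Percent CCS error between an experimental and a reference value."""
    if reference <= 0:
        raise ValueError("reference CCS must be positive")
    err = (experimental - reference) / reference * 100.0
    return err if signed else abs(err)


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftMeasurement:
    """A drift-time reading in ADC bins with its acquisition context."""

    t_d_bins: float
    pusher_period_us: float
    pass_count: int = 1
    separation_time_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.t_d_bins < 0:
            raise ValueError("drift bins must be non-negative")
        if self.pass_count < 1:
            raise ValueError("pass count must be >= 1")

    @property
    def t_d_ms(self) -> float:
        return bins_to_ms(self.t_d_bins, self.pusher_period_us)


@dataclass(frozen=True)
class CCSValue:
    """A CCS result with the quantities it was derived from."""

    ccs: float  # Angstrom^2
    ccs_corrected: float
    z: int
    mu: float  # Da
    method: str = "default"  # "default" | "multipass"

    def __post_init__(self) -> None:
        if self.ccs <= 0:
            raise ValueError("CCS must be positive")


@dataclass
class LinearCalModel:
    """Linear map from EDC-corrected drift time to corrected CCS."""

    slope: float
    intercept: float
    edc_coefficient: float = 0.0
    pusher_period_us: float = 0.0
    drift_gas: DriftGas = N2
    r_squared: float = float("nan")
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def ccs_corrected(self, t_corrected_ms: float) -> float:
        return self.slope * t_corrected_ms + self.intercept

    def corrected_drift(self, ccs_corrected: float) -> float:
        """Inverse map, used when simulating drift times from known CCS."""
        return (ccs_corrected - self.intercept) / self.slope


@dataclass(frozen=True)
class GaussianPeak:
    apex: float  # ms
    sigma: float  # ms
    amplitude: float


@dataclass(frozen=True)
class MultipassObservation:
    """One (pass count, separation time, total drift time) triple."""

    n: int
    t_s: float  # ms
    t_nd: float  # ms

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("pass count must be >= 1")


@dataclass
class MultipassFit:
    """Result of the per-ion periodic-drift-time regression."""

    t_pp: float  # ms
    velocity_ratio: float  # v_u / v_p
    r_squared: float = float("nan")
    t_pp_stderr: float = float("nan")
    slope_stderr: float = float("nan")
    n_obs: int = 0


@dataclass
class PowerLawModel:
    """Corrected CCS vs t_pp: Omega_c = A * t_pp**B, fitted in log-log space."""

    A: float
    B: float
    r_squared: float = float("nan")
    log_residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def ccs_corrected(self, t_pp: float) -> float:
        if t_pp <= 0:
            raise ValueError("t_pp must be positive")
        return self.A * t_pp**self.B

    def t_pp(self, ccs_corrected: float) -> float:
        if ccs_corrected <= 0:
            raise ValueError("corrected CCS must be positive")
        return (ccs_corrected / self.A) ** (1.0 / self.B)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def fit_linear_calibration(
    pairs: Sequence[Tuple[float, float]],
    *,
    edc_coefficient: float = 0.0,
    pusher_period_us: float = 0.0,
    drift_gas: DriftGas = N2,
) -> LinearCalModel:
    """Ordinary least-squares fit of corrected CCS against corrected drift.

    ``pairs`` are (t_c*, Omega_c) calibrant points, e.g. the content of an
    instrument "mob_cal"-style calibration table.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (t_c*, Omega_c) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all corrected drift times identical; fit undefined")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    return LinearCalModel(
        slope=res.slope,
        intercept=res.intercept,
        edc_coefficient=edc_coefficient,
        pusher_period_us=pusher_period_us,
        drift_gas=drift_gas,
        r_squared=res.rvalue**2,
        slope_stderr=res.stderr,
        intercept_stderr=res.intercept_stderr,
        residuals=y - fitted,
    )


def _gauss(t: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def fit_gaussian_peak(
    times: Sequence[float], intensities: Sequence[float]
) -> GaussianPeak:
    """Nonlinear least-squares Gaussian fit of an arrival-time distribution.

    Initialisation: mean at the max-intensity point, sigma from an FWHM
    estimate, amplitude from the max intensity; the fit window is limited to
    +-3 initial sigma around the apex.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and intensities must be equal-length 1-D arrays")
    if t.size < 5:
        raise ValueError("need at least 5 points for a Gaussian fit")
    if np.ptp(y) == 0:
        raise ValueError("flat (constant) signal; no peak to fit")

    i0 = int(np.argmax(y))
    mu0 = t[i0]
    amp0 = y[i0]
    half = (y.max() + y.min()) / 2.0
    above = t[y >= half]
    fwhm = np.ptp(above) if above.size > 1 else 0.0
    sigma0 = fwhm / 2.3548 if fwhm > 0 else np.ptp(t) / 6.0
    if sigma0 <= 0:
        sigma0 = max(abs(mu0) * 1e-3, 1e-3)

    window = np.abs(t - mu0) <= 3.0 * sigma0
    if window.sum() < 5:
        window = np.ones_like(t, dtype=bool)
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            t[window],
            y[window],
            p0=[amp0, mu0, sigma0],
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"Gaussian peak fit did not converge: {exc}") from exc
    return GaussianPeak(apex=float(popt[1]), sigma=abs(float(popt[2])), amplitude=float(popt[0]))


def fit_tpp(observations: Sequence[MultipassObservation]) -> MultipassFit:
    """Extract the periodic drift time from multipass observations.

    Regresses y = (t_nd - t_s)/n on x = t_s/n; the intercept is t_pp and the
    slope is -(v_u/v_p).  Requires >= 2 observations with distinct x.
    """
    obs = [
        o if isinstance(o, MultipassObservation) else MultipassObservation(*o)
        for o in observations
    ]
    if len(obs) < 2:
        raise ValueError("need at least 2 multipass observations")
    x = np.array([o.t_s / o.n for o in obs], dtype=float)
    y = np.array([(o.t_nd - o.t_s) / o.n for o in obs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(
            "all t_s/n identical; periodic drift regression is underdetermined"
        )
    res = stats.linregress(x, y)
    return MultipassFit(
        t_pp=res.intercept,
        velocity_ratio=-res.slope,
        r_squared=res.rvalue**2,
        t_pp_stderr=res.intercept_stderr,
        slope_stderr=res.stderr,
        n_obs=len(obs),
    )


def fit_powerlaw(
    t_pp: Sequence[float], ccs_corrected: Sequence[float]
) -> PowerLawModel:
    """Fit Omega_c = A * t_pp**B by OLS in log-log space.

    Log-log linearisation is deterministic and needs no initialisation;
    residuals are reported in both spaces.
    """
    t = np.asarray(t_pp, dtype=float)
    w = np.asarray(ccs_corrected, dtype=float)
    if t.size != w.size or t.size < 2:
        raise ValueError("need at least 2 calibrant (t_pp, Omega_c) pairs")
    if np.any(t <= 0) or np.any(w <= 0):
        raise ValueError("t_pp and corrected CCS must all be positive")
    if np.ptp(t) == 0:
        raise ValueError("all t_pp identical; power-law fit undefined")
    res = stats.linregress(np.log(t), np.log(w))
    A = math.exp(res.intercept)
    B = res.slope
    fitted = A * t**B
    return PowerLawModel(
        A=A,
        B=B,
        r_squared=res.rvalue**2,
        log_residuals=np.log(w) - np.log(fitted),
        residuals=w - fitted,
    )


def fit_multipass_calibration(
    t_pp: Sequence[float],
    reference_ccs: Sequence[float],
    z: Sequence[int],
    mu: Sequence[float],
) -> PowerLawModel:
    """Power-law calibration from calibrant t_pp values and reference CCS.

    Reference (drift-tube) CCS values are first reduced to corrected CCS by
    removing the charge and reduced-mass dependence, so that a single curve
    serves all charge states; predictions are back-transformed per ion.
    """
    omega_c = [
        ccs_to_corrected(c, zi, mi) for c, zi, mi in zip(reference_ccs, z, mu)
    ]
    return fit_powerlaw(t_pp, omega_c)


# --------------------------------------------------------------------------
# pipelines
# --------------------------------------------------------------------------

def default_ccs(
    t_d_bins: float,
    mz: float,
    z: int,
    ion_mass: float,
    model: LinearCalModel,
    *,
    drift_gas: Optional[DriftGas] = None,
    edc_unit_factor: float = 1.0,
) -> CCSValue:
    """Single-pass CCS via the instrument-default chain (bins -> ms -> EDC
    correction -> linear map -> CCS)."""
    gas = drift_gas or model.drift_gas
    t_ms = bins_to_ms(t_d_bins, model.pusher_period_us)
    t_c = edc_correct(t_ms, model.edc_coefficient, mz, unit_factor=edc_unit_factor)
    omega_c = model.ccs_corrected(t_c)
    mu = reduced_mass(ion_mass, gas.mass)
    return CCSValue(
        ccs=corrected_to_ccs(omega_c, z, mu),
        ccs_corrected=omega_c,
        z=z,
        mu=mu,
        method="default",
    )


def invert_default_ccs(
    ccs: float,
    mz: float,
    z: int,
    ion_mass: float,
    model: LinearCalModel,
    *,
    drift_gas: Optional[DriftGas] = None,
    edc_unit_factor: float = 1.0,
) -> float:
    """Drift bins that the default chain would map to ``ccs`` (simulator
    support; exact inverse of :func:`default_ccs`)."""
    gas = drift_gas or model.drift_gas
    mu = reduced_mass(ion_mass, gas.mass)
    omega_c = ccs_to_corrected(ccs, z, mu)
    t_c = model.corrected_drift(omega_c)
    t_ms = t_c + model.edc_coefficient * edc_unit_factor * math.sqrt(mz)
    return t_ms * 1000.0 / model.pusher_period_us


def estimate_tpp(
    histograms: Mapping[Tuple[int, float], Tuple[Sequence[float], Sequence[float]]],
) -> MultipassFit:
    """Gaussian-fit every arrival histogram of one ion, then regress the
    apexes to the periodic drift time.

    ``histograms`` maps (pass count, separation time ms) to an
    (arrival times, intensities) pair.
    """
    obs = []
    for (n, t_s), (times, intens) in histograms.items():
        peak = fit_gaussian_peak(times, intens)
        obs.append(MultipassObservation(n=n, t_s=t_s, t_nd=peak.apex))
    return fit_tpp(obs)


def multipass_ccs(
    t_pp: float, z: int, ion_mass: float, model: PowerLawModel, *, drift_gas: DriftGas = N2
) -> CCSValue:
    """CCS of one ion from its periodic drift time and a power-law calibration."""
    mu = reduced_mass(ion_mass, drift_gas.mass)
    omega_c = model.ccs_corrected(t_pp)
    return CCSValue(
        ccs=corrected_to_ccs(omega_c, z, mu),
        ccs_corrected=omega_c,
        z=z,
        mu=mu,
        method="multipass",
    )
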