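"""Compression-device signal analysis.

The device drives a piezoelectric actuator with a sinusoidal voltage; the
actuator displaces an agarose gel layer resting on the cells, so the
compressive stress the cells feel is the gel's Young's modulus times the
imposed engineering strain.  This module estimates the gel modulus from an
unconfined-compression stress--strain curve, converts a voltage trace into a
stress trace through the actuator gain and gel thickness, and fits a
four-parameter sinusoid  y = A sin(w t + phi) + C  to stress traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic import VoltageSignal


class NonPhysicalFitError(ValueError):
    """Fitted modulus is not positive."""


class ConvergenceError(RuntimeError):
    """Nonlinear least squares failed to converge."""

    def __init__(self, msg: str, residual: float | None = None):
        super().__init__(msg)
        self.residual = residual


class SmallStrainWarning(UserWarning):
    """Implied gel strain is large enough to strain the linear assumption."""


@dataclass
class GelCharacterization:
    """Young's modulus of the gel from the linear portion of the curve."""

    youngs_modulus: float  # Pa
    fit_range: tuple[float, float]  # strain interval used
    r_squared: float

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("modulus must be positive")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class SinusoidParams:
    """Coefficients of y = amplitude * sin(omega * t + phase) + offset.

    Amplitude is reported non-negative, with the phase adjusted accordingly
    and stored modulo 2*pi.  ``phase_defined`` is False for flat traces.
    """

    amplitude: float
    angular_frequency: float
    phase: float
    offset: float
    phase_defined: bool = True

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        self.phase = float(self.phase) % (2.0 * math.pi)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.sin(self.angular_frequency * np.asarray(t)
                                       + self.phase) + self.offset


@dataclass
class StressTrace:
    times: np.ndarray  # s, strictly ascending
    stress: np.ndarray  # Pa

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.times.shape != self.stress.shape:
            raise ValueError("times and stress must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly ascending")


def estimate_youngs_modulus(curve: np.ndarray,
                            linear_fraction: float = 0.5) -> GelCharacterization:
    """Ordinary least-squares slope over the initial linear portion.

    ``curve`` is an ``(n, 2)`` array of (strain, stress) with strains
    ascending.  Only points within the first ``linear_fraction`` of the
    strain range are fitted; the slope is the engineering Young's modulus.
    """
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need an (n>=3, 2) array of (strain, stress)")
    strain, stress = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(strain) >= 0):
        raise ValueError("strains must be ascending")
    cutoff = strain[0] + linear_fraction * (strain[-1] - strain[0])
    sel = strain <= cutoff
    if sel.sum() < 2:
        sel = np.zeros_like(sel)
        sel[:2] = True
    res = stats.linregress(strain[sel], stress[sel])
    if res.slope <= 0:
        raise NonPhysicalFitError(f"non-physical fitted slope {res.slope:.3g} Pa")
    return GelCharacterization(
        youngs_modulus=float(res.slope),
        fit_range=(float(strain[sel][0]), float(strain[sel][-1])),
        r_squared=float(res.rvalue**2),
    )


def voltage_to_stress(signal: VoltageSignal, actuator_gain: float,
                      gel_thickness: float, E: float) -> StressTrace:
    """Convert drive voltage to compressive stress on the cells.

    The actuator is modelled as a linear gain (displacement = gain * V, in
    micrometres per volt; the characteristic is 10 um at 30 V); dividing by
    the gel thickness (um) gives the engineering strain of the gel, and
    multiplying by the gel Young's modulus ``E`` (Pa) gives the transmitted
    stress under the small-strain uniaxial assumption.  A warning is issued
    if the implied strain reaches 20%.
    """
    if actuator_gain <= 0 or gel_thickness <= 0 or E <= 0:
        raise ValueError("gain, thickness and modulus must be positive")
    strain = actuator_gain * np.asarray(signal.volts, dtype=float) / gel_thickness
    if np.max(np.abs(strain)) >= 0.20:
        warnings.warn(
            f"implied gel strain reaches {np.max(np.abs(strain)):.1%}; "
            "small-strain assumption is violated", SmallStrainWarning,
        )
    return StressTrace(times=np.asarray(signal.times, float), stress=E * strain)


def fit_sinusoid(trace: StressTrace, flat_tol: float = 1e-12) -> SinusoidParams:
    """Nonlinear least-squares fit of y = A sin(w t + phi) + C.

    Initial guesses: w from the dominant peak of the discrete spectrum, A
    from half the trace range, C from the mean.  The returned amplitude is
    non-negative with the phase normalised accordingly (an (A, phi) and
    (-A, phi+pi) pair describe the same curve).  A flat trace returns zero
    amplitude with ``phase_defined=False``.
    """
    t = trace.times
    y = trace.stress
    if t.size < 8:
        raise ValueError("too few samples to fit a sinusoid")
    rng_y = float(np.ptp(y))
    c0 = float(np.mean(y))
    if rng_y <= flat_tol * max(1.0, abs(c0)):
        return SinusoidParams(amplitude=0.0, angular_frequency=1.0, phase=0.0,
                              offset=c0, phase_defined=False)
    # dominant-frequency initial guess from the rFFT of the detrended trace
    dt = float(np.median(np.diff(t)))
    spec = np.abs(np.fft.rfft(y - c0))
    freqs = np.fft.rfftfreq(t.size, dt)
    k = int(np.argmax(spec[1:]) + 1)
    w0 = 2.0 * math.pi * freqs[k]
    if w0 <= 0:
        w0 = 2.0 * math.pi / (t[-1] - t[0])
    a0 = rng_y / 2.0
    # linear phase guess at fixed w0: y - c0 = P sin(w t) + Q cos(w t)
    S, C = np.sin(w0 * t), np.cos(w0 * t)
    M = np.column_stack([S, C])
    pq, *_ = np.linalg.lstsq(M, y - c0, rcond=None)
    phi0 = math.atan2(pq[1], pq[0])

    def model(tt, A, w, phi, C_):
        return A * np.sin(w * tt + phi) + C_

    try:
        with warnings.catch_warnings():
            # exact noiseless data makes the parameter covariance singular
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, t, y, p0=[a0, w0, phi0, c0], maxfev=20000,
            )
    except RuntimeError as e:
        resid = float(np.sqrt(np.mean((model(t, a0, w0, phi0, c0) - y) ** 2)))
        raise ConvergenceError(f"sinusoid fit did not converge: {e}",
                               residual=resid) from e
    A, w, phi, C_ = (float(v) for v in popt)
    if A < 0:
        A, phi = -A, phi + math.pi
    if w < 0:
        w, phi = -w, math.pi - phi
    return SinusoidParams(amplitude=A, angular_frequency=w, phase=phi, offset=C_)
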