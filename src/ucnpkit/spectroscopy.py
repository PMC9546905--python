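"""Ensemble spectroscopy: emission-band integration and decay-lifetime fits.

Er³⁺ upconversion emission concentrates in two green bands (around 521 and
541 nm) and one red band (around 654 nm).  The red-to-green ratio divides
the integrated red band (635–683 nm) by the summed green bands (510–534 and
535–577 nm).  Luminescence decays are fit with a double exponential
A1·exp(−t/τ1) + A2·exp(−t/τ2) + baseline, and the reported lifetime is the
1/e time of the fitted, baseline-subtracted curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "Spectrum",
    "BandSet",
    "DecayFit",
    "integrate_band",
    "red_green_ratio",
    "fit_decay",
    "ZeroGreenError",
    "DecayFitError",
]


class ZeroGreenError(ZeroDivisionError):
    """Combined green band area is zero; ratio undefined."""


class DecayFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class Spectrum:
    """Wavelength–intensity arrays, optionally tagged with excitation power."""

    wavelength: np.ndarray  # nm, strictly increasing
    intensity: np.ndarray  # arbitrary units
    power_density: float | None = None  # W/cm²

    def __post_init__(self):
        wl = np.asarray(self.wavelength, float)
        inten = np.asarray(self.intensity, float)
        if wl.ndim != 1 or wl.shape != inten.shape:
            raise ValueError("wavelength and intensity must be equal-length 1D arrays")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength must be strictly increasing")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class BandSet:
    """Integration windows (nm): red 635–683, green 510–534 and 535–577."""

    red: tuple[float, float] = (635.0, 683.0)
    green1: tuple[float, float] = (510.0, 534.0)
    green2: tuple[float, float] = (535.0, 577.0)


def integrate_band(spectrum: Spectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of intensity over the closed band window.

    Integrates on the native wavelength grid (no interpolation); the window
    must lie within the spectral range.
    """
    lo, hi = band
    wl = spectrum.wavelength
    if lo >= hi:
        raise ValueError(f"empty band ({lo}, {hi})")
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"band ({lo}, {hi}) outside spectral range ({wl[0]}, {wl[-1]})"
        )
    mask = (wl >= lo) & (wl <= hi)
    return float(np.trapezoid(spectrum.intensity[mask], wl[mask]))


def red_green_ratio(spectrum: Spectrum, bands: BandSet = BandSet()) -> float:
    """Integrated red band over the summed green bands."""
    red = integrate_band(spectrum, bands.red)
    green = integrate_band(spectrum, bands.green1) + integrate_band(
        spectrum, bands.green2
    )
    if green == 0.0:
        raise ZeroGreenError("combined green band area is zero")
    return red / green


@dataclass(frozen=True)
class DecayFit:
    """Double-exponential decay parameters with the 1/e lifetime.

    τ are in the units of the input time axis (µs in practice); ``tau_1e``
    solves I(t) − baseline = (I(0) − baseline)/e on the fitted curve and
    always lies between τ1 and τ2.
    """

    A1: float
    tau1: float
    A2: float
    tau2: float
    baseline: float
    tau_1e: float
    residual_rms: float
    flags: tuple[str, ...] = ()

    def evaluate(self, t):
        t = np.asarray(t, float)
        return (
            self.A1 * np.exp(-t / self.tau1)
            + self.A2 * np.exp(-t / self.tau2)
            + self.baseline
        )


def _tau_1e_of(A1, tau1, A2, tau2):
    """1/e time of A1·e^(−t/τ1) + A2·e^(−t/τ2) by bracketed root finding."""
    i0 = A1 + A2
    target = i0 / np.e

    def f(t):
        return A1 * np.exp(-t / tau1) + A2 * np.exp(-t / tau2) - target

    hi = max(tau1, tau2)
    while f(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12 * max(tau1, tau2),
                                 rtol=8.9e-16))


def fit_decay(time: np.ndarray, intensity: np.ndarray) -> DecayFit:
    """Nonlinear least-squares double-exponential fit of a decay curve.

    Requires ≥20 samples spanning more than ~3× the slower lifetime (checked
    loosely via the observed decay).  t = 0 is the first sample.  Flags
    (rather than errors) mark negative fitted amplitudes; non-convergence
    raises :class:`DecayFitError`.  Components are ordered τ1 ≤ τ2.
    """
    t = np.asarray(time, float)
    y = np.asarray(intensity, float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("time and intensity must be equal-length 1D arrays")
    if t.size < 20:
        raise ValueError("need at least 20 samples")
    t = t - t[0]

    # initialization: baseline from the tail, 1/e crossing for the fast τ
    b0 = float(np.mean(y[-max(3, t.size // 20):]))
    amp = float(y[0] - b0)
    if amp <= 0:
        amp = max(float(np.ptp(y)), 1e-12)
    dec = y - b0
    below = np.flatnonzero(dec < amp / np.e)
    tau_guess = float(t[below[0]]) if below.size else float(t[-1] / 3.0)
    tau_guess = max(tau_guess, float(t[1] - t[0]))

    def model(t_, A1, tau1, A2, tau2, b):
        return A1 * np.exp(-t_ / tau1) + A2 * np.exp(-t_ / tau2) + b

    p0 = [0.6 * amp, 0.5 * tau_guess, 0.4 * amp, 3.0 * tau_guess, b0]
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, 1e-12, -np.inf, 1e-12, -np.inf],
                    [np.inf, np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise DecayFitError(f"decay fit did not converge: {exc}") from exc
    A1, tau1, A2, tau2, b = (float(v) for v in popt)
    if tau1 > tau2:
        A1, tau1, A2, tau2 = A2, tau2, A1, tau1
    flags = []
    if A1 < 0 or A2 < 0:
        flags.append("negative_amplitude")
    if t[-1] < 3.0 * tau2:
        flags.append("short_time_span")
    tau_1e = _tau_1e_of(A1, tau1, A2, tau2)
    resid = model(t, A1, tau1, A2, tau2, b) - y
    return DecayFit(
        A1=A1, tau1=tau1, A2=A2, tau2=tau2, baseline=b, tau_1e=tau_1e,
        residual_rms=float(np.sqrt(np.mean(resid**2))), flags=tuple(flags),
    )
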