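"""Single-particle localization and brightness analysis.

Isolated upconversion nanoparticles imaged on an EMCCD appear as
diffraction-limited spots.  Each spot is fit with a normalized-amplitude 2D
Gaussian

    I(x, y) = I0 / (2πσ²) · exp(−((x−x0)² + (y−y0)²) / (2σ²)) + C

on photon-converted pixels, so that the fitted ``I0`` is the total spot flux
in photons/s (the single-particle brightness) and ``C`` the background in
photons/s/px.  Brightness-vs-irradiance saturation curves and the log-log
power-law slope n (≈2 for a two-photon process at low power) are built on
top of the per-spot fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from skimage.feature import peak_local_max

__all__ = [
    "CameraModel",
    "GaussianSpotFit",
    "SaturationCurve",
    "PowerLawFit",
    "SpotFitError",
    "gaussian_spot_model",
    "fit_gaussian_spot",
    "detect_spots",
    "brightness_statistics",
    "power_law_slope",
]


class SpotFitError(RuntimeError):
    """Fit did not converge or sat pinned at a bound."""


@dataclass(frozen=True)
class CameraModel:
    """EMCCD calibration used to convert camera counts to photon rates.

    ``photons_per_count`` is the sensitivity (photoelectrons per output
    count) before EM amplification; photons = counts·photons_per_count /
    em_gain, and rates divide by ``exposure``.
    """

    pixel_size: float  # nm / px
    photons_per_count: float
    em_gain: float = 1.0
    read_noise: float = 0.0  # counts RMS
    exposure: float = 1.0  # s

    def __post_init__(self):
        for name in ("pixel_size", "photons_per_count", "em_gain", "exposure"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.read_noise < 0:
            raise ValueError("read_noise must be >= 0")

    def counts_to_photons(self, counts):
        return np.asarray(counts, float) * self.photons_per_count / self.em_gain

    def photons_to_counts(self, photons):
        return np.asarray(photons, float) * self.em_gain / self.photons_per_count

    def counts_to_rate(self, counts):
        """counts → photons/s."""
        return self.counts_to_photons(counts) / self.exposure


@dataclass(frozen=True)
class GaussianSpotFit:
    """Fitted spot parameters in physical units.

    ``I0`` photons/s (total flux), ``x0``/``y0``/``sigma`` nm, ``C``
    photons/s/px; 1σ uncertainties from the scaled least-squares covariance.
    """

    I0: float
    x0: float
    y0: float
    sigma: float
    C: float
    I0_err: float
    x0_err: float
    y0_err: float
    sigma_err: float
    C_err: float
    residual_rms: float
    converged: bool
    peak_rate: float  # photons/s/px at the fitted peak pixel, "pps px⁻¹"


def gaussian_spot_model(xx, yy, I0, x0, y0, sigma, C):
    """Evaluate the normalized 2D Gaussian spot at pixel centers."""
    return (
        I0
        / (2.0 * np.pi * sigma**2)
        * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))
        + C
    )


def fit_gaussian_spot(
    region: np.ndarray,
    camera: CameraModel,
    init: tuple | None = None,
) -> GaussianSpotFit:
    """Least-squares Gaussian fit of one spot region.

    ``region`` is a counts image of at least 7×7 px containing a single
    candidate spot.  Pixels are photon-rate converted before the unweighted
    least-squares fit; pixel centers sit at integer coordinates with the
    origin at the top-left pixel center (x rightward, y downward).  Returns
    parameters in nm and photons/s.  Non-convergence or a σ pinned at its
    bound raises :class:`SpotFitError`.
    """
    region = np.asarray(region, float)
    if region.ndim != 2 or min(region.shape) < 7:
        raise ValueError("region must be a 2D array of at least 7x7 pixels")
    rate = camera.counts_to_rate(region)
    h, w = rate.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    if init is None:
        c0 = float(rate.min())
        excess = np.clip(rate - c0, 0, None)
        tot = excess.sum()
        if tot <= 0:
            x0g, y0g, sg = (w - 1) / 2.0, (h - 1) / 2.0, 1.5
        else:
            x0g = float((xx * excess).sum() / tot)
            y0g = float((yy * excess).sum() / tot)
            var = ((xx - x0g) ** 2 + (yy - y0g) ** 2) * excess
            sg = max(0.8, float(np.sqrt(var.sum() / tot / 2.0)))
        p0 = np.array([max(tot, 1e-9), x0g, y0g, sg, c0])
    else:
        p0 = np.asarray(init, float)

    sig_lo, sig_hi = 0.3, max(h, w)
    lb = [0.0, -1.0, -1.0, sig_lo, -np.inf]
    ub = [np.inf, w, h, sig_hi, np.inf]
    p0 = np.clip(p0, lb, ub)

    def resid(p):
        return (gaussian_spot_model(xx, yy, *p) - rate).ravel()

    sol = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise SpotFitError(f"spot fit did not converge: {sol.message}")
    I0, x0, y0, sigma, C = sol.x
    if sigma <= sig_lo * 1.001 or sigma >= sig_hi * 0.999:
        raise SpotFitError(f"sigma pinned at bound ({sigma:.3g} px)")

    # scaled covariance from the Jacobian
    m, npar = sol.jac.shape
    dof = max(m - npar, 1)
    resvar = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * resvar
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        perr = np.full(npar, np.nan)

    px = camera.pixel_size
    peak = float(I0 / (2.0 * np.pi * sigma**2) + C)
    return GaussianSpotFit(
        I0=float(I0),
        x0=float(x0 * px),
        y0=float(y0 * px),
        sigma=float(sigma * px),
        C=float(C),
        I0_err=float(perr[0]),
        x0_err=float(perr[1] * px),
        y0_err=float(perr[2] * px),
        sigma_err=float(perr[3] * px),
        C_err=float(perr[4]),
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
        converged=True,
        peak_rate=peak,
    )


def detect_spots(
    frame: np.ndarray,
    k: float = 6.0,
    min_separation: int = 5,
) -> np.ndarray:
    """Candidate spot centers as (row, col) pixel indices.

    Local maxima above ``median + k·MAD`` with a minimum mutual separation.
    An empty array is a valid result.
    """
    frame = np.asarray(frame, float)
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    thr = med + k * mad
    return peak_local_max(frame, min_distance=min_separation, threshold_abs=thr,
                          exclude_border=False)


@dataclass(frozen=True)
class SaturationCurve:
    """Mean ± std single-particle brightness vs excitation power density."""

    power_densities: np.ndarray  # W/cm², strictly increasing
    mean_brightness: np.ndarray  # photons/s
    std_brightness: np.ndarray
    n_particles: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.power_densities, float)
        if p.ndim != 1 or not np.all(np.diff(p) > 0):
            raise ValueError("power densities must be strictly increasing")
        for name in ("mean_brightness", "std_brightness", "n_particles"):
            if len(getattr(self, name)) != len(p):
                raise ValueError("saturation-curve arrays must have equal length")


def brightness_statistics(fits_per_power: dict) -> SaturationCurve:
    """Aggregate per-spot brightnesses into a saturation curve.

    ``fits_per_power`` maps power density (W/cm²) to a sequence of
    :class:`GaussianSpotFit` (or raw I0 values).  Empty levels are dropped
    with a warning.
    """
    powers, means, stds, ns = [], [], [], []
    for p in sorted(fits_per_power):
        vals = [
            f.I0 if isinstance(f, GaussianSpotFit) else float(f)
            for f in fits_per_power[p]
        ]
        if not vals:
            warnings.warn(f"power level {p} W/cm² has no fits; dropped", stacklevel=2)
            continue
        arr = np.asarray(vals, float)
        powers.append(float(p))
        means.append(float(arr.mean()))
        stds.append(float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
        ns.append(arr.size)
    if not powers:
        raise ValueError("no non-empty power levels")
    return SaturationCurve(
        power_densities=np.array(powers),
        mean_brightness=np.array(means),
        std_brightness=np.array(stds),
        n_particles=np.array(ns),
    )


@dataclass(frozen=True)
class PowerLawFit:
    """log10(brightness) = n·log10(power) + intercept over the fit range."""

    n: float
    intercept: float
    n_stderr: float
    power_range: tuple[float, float]
    n_points: int


def power_law_slope(
    curve: SaturationCurve,
    power_range: tuple[float, float] | None = None,
) -> PowerLawFit:
    """OLS slope of log10 brightness vs log10 power density.

    Restricting ``power_range`` to the unsaturated low-power regime recovers
    the multiphoton order n.
    """
    p = curve.power_densities
    b = curve.mean_brightness
    if power_range is not None:
        lo, hi = power_range
        mask = (p >= lo) & (p <= hi)
    else:
        mask = np.ones_like(p, bool)
    p, b = p[mask], b[mask]
    if p.size < 3:
        raise ValueError("need at least 3 points in the fit range")
    if np.any(p <= 0) or np.any(b <= 0):
        raise ValueError("power-law fit requires positive powers and brightnesses")
    res = stats.linregress(np.log10(p), np.log10(b))
    return PowerLawFit(
        n=float(res.slope),
        intercept=float(res.intercept),
        n_stderr=float(res.stderr),
        power_range=(float(p.min()), float(p.max())),
        n_points=int(p.size),
    )
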