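"""Synthetic data with known ground truth for every analysis stage.

Generators emulate the measured inputs of the pipeline — EMCCD movies of
isolated diffraction-limited emitters, power-law brightness with
saturation, multi-band emission spectra (521/541/654 nm), double-exponential
decays, and 2D trajectories (Brownian, directed with transverse scatter,
confined, or two-state stop-and-go) with localization noise.  Every
generator is deterministic under a seed and returns the truth alongside the
data.

Default imaging parameters mimic a 100×/NA 1.49 EMCCD setup: 10 fps,
160 nm pixels, PSF σ ≈ 76 nm at 541 nm emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .photometry import CameraModel, gaussian_spot_model
from .tracking import Trajectory

__all__ = [
    "SceneTruth",
    "MotionTruth",
    "DEFAULT_CAMERA",
    "emitter_brightness",
    "generate_movie",
    "generate_trajectory",
    "generate_spectrum",
    "generate_decay",
]

#: Typical EMCCD calibration for the emulated wide-field setup.
DEFAULT_CAMERA = CameraModel(
    pixel_size=160.0,  # nm/px (100× objective)
    photons_per_count=10.0,  # e-/count sensitivity
    em_gain=100.0,
    read_noise=1.0,  # counts RMS after gain
    exposure=0.1,  # s (10 fps)
)

#: Default PSF width, nm (diffraction limit near 541 nm emission).
DEFAULT_PSF_SIGMA = 76.0


def emitter_brightness(k: float, n: float, power: float, p_sat: float = np.inf):
    """Brightness (photons/s) = k·(P/(1+P/P_sat))^n.

    Below saturation this is the pure power law k·P^n with multiphoton
    order n; approaching ``p_sat`` the effective log-log slope falls.
    """
    p = np.asarray(power, float)
    return k * (p / (1.0 + p / p_sat)) ** n


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for a wide-field movie of isolated emitters."""

    positions: np.ndarray  # (k, 2) nm, (x, y)
    brightness: np.ndarray  # (k,) photons/s
    psf_sigma: float = DEFAULT_PSF_SIGMA  # nm
    background: float = 0.0  # photons/s/px
    power_density: float | None = None  # W/cm²

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.positions, float))
        b = np.atleast_1d(np.asarray(self.brightness, float))
        if p.shape[1] != 2 or p.shape[0] != b.shape[0]:
            raise ValueError("positions (k,2) and brightness (k,) must match")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "brightness", b)


@dataclass(frozen=True)
class MotionTruth:
    """Parameters of one 2D motion model.

    ``model`` ∈ {brownian, directed, confined, switching}.  ``D`` µm²/s,
    ``v`` nm/s, ``sigma_t`` nm transverse scatter of directed motion,
    ``confinement_radius`` nm, ``switch_rates`` (go→stop, stop→go) s⁻¹.
    """

    model: str
    D: float = 0.0
    v: float = 0.0
    direction: float = 0.0  # radians
    sigma_t: float = 0.0
    confinement_radius: float = 0.0
    switch_rates: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.model not in ("brownian", "directed", "confined", "switching"):
            raise ValueError(f"unknown motion model {self.model!r}")


def generate_movie(
    scene: SceneTruth,
    camera: CameraModel = DEFAULT_CAMERA,
    n_frames: int = 1,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    noise: bool = True,
    path: str | Path | None = None,
):
    """Render an EMCCD movie of the scene.

    Per frame and pixel the expected photon count is exposure·(spot model +
    background); shot noise is Poisson, EM amplification gamma-distributed
    with the camera's mean gain, and read noise Gaussian in counts.  With
    ``noise=False`` frames are the exact expected counts.  Returns
    ``(stack, truth)`` with the truth table of emitter positions (nm, and
    px) and brightness; optionally writes a TIFF + truth CSV.
    """
    h, w = shape
    px = camera.pixel_size
    xs = scene.positions[:, 0] / px
    ys = scene.positions[:, 1] / px
    if np.any((xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1)):
        raise ValueError("emitter outside the field of view")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rate = np.full((h, w), float(scene.background))
    for (x0, y0), i0 in zip(zip(xs, ys), scene.brightness):
        rate += gaussian_spot_model(xx, yy, i0, x0, y0, scene.psf_sigma / px, 0.0)
    mu_photons = rate * camera.exposure

    rng = np.random.default_rng(seed)
    stack = np.empty((n_frames, h, w))
    if noise:
        for f in range(n_frames):
            n_ph = rng.poisson(mu_photons)
            electrons = np.where(
                n_ph > 0, rng.gamma(np.maximum(n_ph, 1e-12), camera.em_gain), 0.0
            )
            counts = electrons / camera.photons_per_count
            counts += rng.normal(0.0, camera.read_noise, size=(h, w))
            stack[f] = counts
    else:
        stack[:] = camera.photons_to_counts(mu_photons)

    truth = pd.DataFrame(
        {
            "emitter": np.arange(len(scene.brightness)),
            "x_nm": scene.positions[:, 0],
            "y_nm": scene.positions[:, 1],
            "x_px": xs,
            "y_px": ys,
            "brightness_pps": scene.brightness,
            "psf_sigma_nm": scene.psf_sigma,
            "background_pps_px": scene.background,
        }
    )
    if path is not None:
        path = Path(path)
        tifffile.imwrite(path, stack.astype(np.float32))
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    return stack, truth


def generate_trajectory(
    motion: MotionTruth,
    dt: float = 0.1,
    n: int = 600,
    loc_noise: float = 0.0,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Simulate one 2D trajectory and return (noisy trajectory, true path).

    Brownian: Gaussian steps with per-axis variance 2D·dt.  Directed: v·t
    along ``direction`` plus independent transverse Gaussian scatter σ_t.
    Confined: Brownian reflected at a disk of the confinement radius.
    Switching: two-state Markov (go = directed, stop = paused) with the
    given rates.  Localization noise is i.i.d. Gaussian per axis (nm).
    """
    if dt <= 0 or n < 2:
        raise ValueError("need dt > 0 and n >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    D_nm = motion.D * 1e6  # µm²/s → nm²/s
    if motion.model == "brownian":
        steps = rng.normal(0.0, np.sqrt(2.0 * D_nm * dt), size=(n - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    elif motion.model == "directed":
        u = np.array([np.cos(motion.direction), np.sin(motion.direction)])
        nvec = np.array([-u[1], u[0]])
        along = motion.v * t
        across = rng.normal(0.0, motion.sigma_t, size=n) if motion.sigma_t > 0 else np.zeros(n)
        pos = np.outer(along, u) + np.outer(across, nvec)
    elif motion.model == "confined":
        R = motion.confinement_radius
        if R <= 0:
            raise ValueError("confined motion needs a positive confinement radius")
        pos = np.zeros((n, 2))
        for i in range(1, n):
            step = rng.normal(0.0, np.sqrt(2.0 * D_nm * dt), size=2)
            cand = pos[i - 1] + step
            r = np.hypot(*cand)
            if r > R:  # radial reflection at the boundary
                cand *= (2.0 * R - r) / r
            pos[i] = cand
    else:  # switching stop-and-go
        u = np.array([np.cos(motion.direction), np.sin(motion.direction)])
        nvec = np.array([-u[1], u[0]])
        p_stop = 1.0 - np.exp(-motion.switch_rates[0] * dt)
        p_go = 1.0 - np.exp(-motion.switch_rates[1] * dt)
        pos = np.zeros((n, 2))
        going = True
        for i in range(1, n):
            if going:
                adv = motion.v * dt * u
                jig = rng.normal(0.0, motion.sigma_t) * nvec if motion.sigma_t > 0 else 0.0
                pos[i] = pos[i - 1] + adv + jig
                going = rng.random() >= p_stop
            else:
                pos[i] = pos[i - 1]
                going = rng.random() < p_go

    noisy = pos + (
        rng.normal(0.0, loc_noise, size=pos.shape) if loc_noise > 0 else 0.0
    )
    return Trajectory(times=t, positions=noisy), pos


#: Emission band centers (nm) and default widths for the emulated spectra.
DEFAULT_BANDS = (
    {"center": 521.0, "sigma": 5.0},
    {"center": 541.0, "sigma": 6.0},
    {"center": 654.0, "sigma": 8.0},
)


def generate_spectrum(
    power: float = 1.0,
    areas: tuple[float, float, float] | None = None,
    coefficients: tuple[float, float, float] = (1.0, 1.0, 1.0),
    exponents: tuple[float, float, float] = (2.0, 2.0, 2.0),
    bands: tuple[dict, ...] = DEFAULT_BANDS,
    wavelength: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
):
    """Sum-of-Gaussians emission spectrum at the given excitation power.

    Band areas are ``areas`` if given, else ``k_b · P^(n_b)`` per band.
    Returns ``(Spectrum, truth)`` where truth holds the configured band
    areas.  Optional additive Gaussian noise.
    """
    from .spectroscopy import Spectrum

    if power <= 0:
        raise ValueError("power must be positive")
    if wavelength is None:
        wavelength = np.arange(480.0, 720.0, 0.05)
    wl = np.asarray(wavelength, float)
    if areas is None:
        areas = tuple(k * power**n for k, n in zip(coefficients, exponents))
    inten = np.zeros_like(wl)
    for band, area in zip(bands, areas):
        s = band["sigma"]
        inten += area / (s * np.sqrt(2 * np.pi)) * np.exp(
            -((wl - band["center"]) ** 2) / (2 * s**2)
        )
    if noise > 0:
        inten = inten + np.random.default_rng(seed).normal(0.0, noise, wl.size)
    truth = {
        "areas": tuple(float(a) for a in areas),
        "centers": tuple(b["center"] for b in bands),
        "sigmas": tuple(b["sigma"] for b in bands),
        "power": float(power),
    }
    return Spectrum(wavelength=wl, intensity=inten, power_density=power), truth


def generate_decay(
    A1: float = 0.7,
    tau1: float = 100.0,
    A2: float = 0.3,
    tau2: float = 400.0,
    dt: float = 2.0,
    T: float | None = None,
    baseline: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sampled double-exponential decay (times in µs by convention).

    ``T`` defaults to 5× the slower lifetime and must exceed 3× it.
    Returns a DataFrame (time_us, intensity); optional Gaussian noise.
    """
    slow = max(tau1, tau2)
    if T is None:
        T = 5.0 * slow
    if T <= 3.0 * slow:
        raise ValueError("time span T must exceed 3× the slower lifetime")
    t = np.arange(0.0, T, dt)
    y = A1 * np.exp(-t / tau1) + A2 * np.exp(-t / tau2) + baseline
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise, t.size)
    return pd.DataFrame({"time_us": t, "intensity": y})
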