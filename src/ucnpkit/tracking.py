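"""Trajectory analysis and correlative-image registration.

Covers the single-particle tracking workflow: linking per-frame
localizations into trajectories, time-averaged mean-squared-displacement
(MSD) curves with MSD = 4Dτ diffusion estimates for 2D imaging, the FWHM of
transverse deviations from a fitted line for directed ("stop-and-go")
transport, and first-degree 2D polynomial (affine) mapping of luminescence
coordinates onto SEM coordinates with mutual-nearest-neighbor point
matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree

__all__ = [
    "Trajectory",
    "MSDCurve",
    "DiffusionEstimate",
    "AffineMap",
    "link_localizations",
    "compute_msd",
    "estimate_diffusion",
    "line_deviation_fwhm",
    "fit_affine_registration",
    "match_points",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 2D positions (nm); ``gaps`` flags bridged frames."""

    times: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # (n, 2) nm
    gaps: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, float)
        p = np.asarray(self.positions, float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] != t.shape[0]:
            raise ValueError("positions must be (n, 2) matching times")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD per lag; counts are the number of averaged pairs."""

    lags: np.ndarray  # s
    msd: np.ndarray  # nm²
    counts: np.ndarray


@dataclass(frozen=True)
class DiffusionEstimate:
    """MSD-line fit: D (µm²/s) from slope/4, intercept (nm²) absorbs the
    4σ² localization-noise offset."""

    D: float
    intercept: float
    stderr: float
    n_lags: int
    negative_slope: bool = False


@dataclass(frozen=True)
class AffineMap:
    """First-degree 2D polynomial map x' = a0 + a1·x + a2·y (same for y')."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]
    rms_residual: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        x, y = p[:, 0], p[:, 1]
        return np.column_stack([
            self.a[0] + self.a[1] * x + self.a[2] * y,
            self.b[0] + self.b[1] * x + self.b[2] * y,
        ])

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a[1], self.a[2]], [self.b[1], self.b[2]]])


def link_localizations(
    locs: pd.DataFrame,
    max_disp: float,
    max_gap: int = 0,
    dt: float = 1.0,
    min_length: int = 2,
) -> list[Trajectory]:
    """Greedy nearest-neighbor frame-to-frame linking.

    ``locs`` needs columns ``frame``, ``x``, ``y`` (positions in nm, sorted
    by frame).  Links are made in ascending distance order within
    ``max_disp`` nm; a track may skip up to ``max_gap`` frames.  Times are
    ``frame·dt`` seconds.
    """
    req = {"frame", "x", "y"}
    if not req.issubset(locs.columns):
        raise ValueError(f"localization table needs columns {sorted(req)}")
    tracks: list[dict] = []  # each: frames[], pts[], last_frame
    active: list[int] = []
    for frame, group in locs.sort_values("frame").groupby("frame", sort=True):
        frame = int(frame)
        pts = group[["x", "y"]].to_numpy(float)
        # retire stale tracks
        active = [ti for ti in active if frame - tracks[ti]["last_frame"] <= max_gap + 1]
        assigned = np.full(len(pts), False)
        if active and len(pts):
            ends = np.array([tracks[ti]["pts"][-1] for ti in active])
            d = np.linalg.norm(ends[:, None, :] - pts[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            used_tracks = set()
            for ti_idx, pj in order:
                if d[ti_idx, pj] > max_disp:
                    break
                if ti_idx in used_tracks or assigned[pj]:
                    continue
                ti = active[ti_idx]
                gap = frame - tracks[ti]["last_frame"] - 1
                tracks[ti]["frames"].append(frame)
                tracks[ti]["pts"].append(pts[pj])
                tracks[ti]["gapped"].append(gap > 0)
                tracks[ti]["last_frame"] = frame
                used_tracks.add(ti_idx)
                assigned[pj] = True
        for pj in np.flatnonzero(~assigned):
            tracks.append(
                {"frames": [frame], "pts": [pts[pj]], "gapped": [False],
                 "last_frame": frame}
            )
            active.append(len(tracks) - 1)

    out = []
    for tr in tracks:
        if len(tr["frames"]) < min_length:
            continue
        out.append(
            Trajectory(
                times=np.asarray(tr["frames"], float) * dt,
                positions=np.asarray(tr["pts"], float),
                gaps=np.asarray(tr["gapped"], bool),
            )
        )
    return out


def compute_msd(trajectory: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD over all ordered pairs at each lag.

    Assumes uniform sampling; lags run up to ``max_lag_fraction`` of the
    trajectory duration.  Needs ≥10 points.
    """
    n = len(trajectory)
    if n < 10:
        raise ValueError(f"trajectory too short for MSD ({n} < 10 points)")
    dts = np.diff(trajectory.times)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6):
        raise ValueError("MSD assumes uniformly sampled trajectories")
    kmax = max(1, int(np.floor((n - 1) * max_lag_fraction)))
    pos = trajectory.positions
    lags = np.arange(1, kmax + 1) * dt
    msd = np.empty(kmax)
    counts = np.empty(kmax, int)
    for k in range(1, kmax + 1):
        d = pos[k:] - pos[:-k]
        msd[k - 1] = float(np.mean(np.sum(d**2, axis=1)))
        counts[k - 1] = n - k
    return MSDCurve(lags=lags, msd=msd, counts=counts)


def estimate_diffusion(msd: MSDCurve, n_points: int = 4) -> DiffusionEstimate:
    """Weighted linear fit of the first ``n_points`` MSD lags; D = slope/4.

    Weights are the pair counts per lag.  Slope is nm²/s; D is returned in
    µm²/s.  A negative slope is reported with a flag rather than an error.
    """
    if n_points < 2:
        raise ValueError("need at least 2 lags")
    n_points = min(n_points, msd.lags.size)
    x = msd.lags[:n_points]
    y = msd.msd[:n_points]
    w = msd.counts[:n_points].astype(float)
    W = np.diag(w)
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * y, rcond=None)
    slope, intercept = float(beta[0]), float(beta[1])
    resid = y - X @ beta
    dof = max(n_points - 2, 1)
    s2 = float(np.sum(w * resid**2) / dof)
    cov = s2 * np.linalg.inv(X.T @ W @ X)
    return DiffusionEstimate(
        D=slope / 4.0 * 1e-6,  # nm²/s → µm²/s
        intercept=intercept,
        stderr=float(np.sqrt(cov[0, 0]) / 4.0 * 1e-6),
        n_lags=n_points,
        negative_slope=slope < 0,
    )


def line_deviation_fwhm(points: np.ndarray, method: str = "gaussian") -> float:
    """FWHM (nm) of perpendicular deviations from the best-fit line.

    A total-least-squares line (principal axis) is fit to the segment; the
    signed perpendicular distances are summarized either by a Gaussian fit
    to their histogram (``gaussian``; FWHM = 2√(2 ln 2)·σ) or by the sample
    standard deviation (``std``).  Needs ≥20 points; a degenerate segment
    returns 0.
    """
    p = np.asarray(points, float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if p.shape[0] < 20:
        raise ValueError("need at least 20 points")
    centered = p - p.mean(axis=0)
    if np.allclose(centered, 0):
        return 0.0
    # principal axis = TLS line direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[1]
    dev = centered @ normal
    sigma = float(dev.std(ddof=1))
    extent = float(np.abs(centered).max())
    if sigma <= 1e-12 * max(extent, 1.0):  # numerically collinear segment
        return 0.0
    if method == "std":
        return FWHM_FACTOR * sigma
    if method != "gaussian":
        raise ValueError(f"unknown method {method!r}")
    nbins = max(10, int(np.sqrt(dev.size)))
    counts, edges = np.histogram(dev, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, s):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * s**2))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                gauss, centers, counts,
                p0=[counts.max(), float(dev.mean()), sigma], maxfev=5000,
            )
        sigma_fit = abs(float(popt[2]))
    except RuntimeError:
        sigma_fit = sigma
    return FWHM_FACTOR * sigma_fit


def fit_affine_registration(
    src: np.ndarray, dst: np.ndarray, matches: np.ndarray | None = None
) -> AffineMap:
    """Least-squares affine (1st-degree 2D polynomial) map src → dst.

    ``matches`` is an optional (m, 2) index array pairing src rows with dst
    rows; by default rows correspond one-to-one.  Requires ≥3 non-collinear
    control pairs.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if matches is not None:
        matches = np.asarray(matches, int)
        src = src[matches[:, 0]]
        dst = dst[matches[:, 1]]
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matched (n, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 control pairs")
    X = np.column_stack([np.ones(n), src])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError("control points are collinear (rank-deficient)")
    coeffs, *_ = np.linalg.lstsq(X, dst, rcond=None)
    resid = dst - X @ coeffs
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineMap(
        a=tuple(float(v) for v in coeffs[:, 0]),
        b=tuple(float(v) for v in coeffs[:, 1]),
        rms_residual=rms,
    )


def match_points(
    src: np.ndarray,
    dst: np.ndarray,
    initial_map: AffineMap | None = None,
    max_dist: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mutual-nearest-neighbor matching after optional coarse alignment.

    Returns ``(matches, unmatched_src, unmatched_dst)`` where matches is an
    (m, 2) array of (src_index, dst_index).  When no ``max_dist`` is given, a
    scale-derived default (median nearest-neighbor spacing of dst) is used.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.size == 0 or dst.size == 0:
        raise ValueError("point sets must be nonempty")
    moved = initial_map.apply(src) if initial_map is not None else src
    tree_dst = cKDTree(dst)
    tree_src = cKDTree(moved)
    d_sd, nn_sd = tree_dst.query(moved)
    _, nn_ds = tree_src.query(dst)
    if max_dist is None:
        if len(dst) > 1:
            dd, _ = tree_dst.query(dst, k=2)
            max_dist = float(np.median(dd[:, 1])) / 2.0
        else:
            max_dist = np.inf
    pairs = [
        (i, int(nn_sd[i]))
        for i in range(len(moved))
        if nn_ds[nn_sd[i]] == i and d_sd[i] <= max_dist
    ]
    matches = np.asarray(pairs, int).reshape(-1, 2)
    unmatched_src = np.setdiff1d(np.arange(len(src)), matches[:, 0] if len(pairs) else [])
    unmatched_dst = np.setdiff1d(np.arange(len(dst)), matches[:, 1] if len(pairs) else [])
    return matches, unmatched_src, unmatched_dst
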