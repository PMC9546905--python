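"""Monte Carlo energy migration over Yb³⁺ sites to an absorbing interface.

An excitation quantum absorbed at a sensitizer site hops between neighboring
Yb³⁺ sites with Dexter-exchange probabilities ∝ exp(−2r/L), r the neighbor
distance in Å and L = 0.3 Å the exchange decay length.  A hop that lands in
the emitter compartment is absorbed (the walk terminates; that hop counts as
a step).  A site with no available target — possible under Yb dilution —
traps the walker; trapped walks are excluded from step statistics and
reported as a fraction.

The ensemble driver repeats the walk from every sensitizer site and returns
per-site mean step counts plus the aggregate views used to compare
architectures: a histogram of per-site means, radial and elevation profiles,
and an azimuthally averaged (cylindrical radius, z) heatmap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .lattice import (
    COMP_CORE,
    NanoparticleModel,
    NeighborTable,
    OCC_YB,
)

__all__ = [
    "HopKernel",
    "WalkResult",
    "WalkStatistics",
    "TrappedSiteError",
    "hop_probabilities",
    "simulate_walk",
    "run_ensemble",
    "cumulative_frequency",
    "CumulativeCurve",
]


class MigrationError(ValueError):
    pass


class TrappedSiteError(MigrationError):
    """Raised when a site has no available migration target."""


@dataclass(frozen=True)
class HopKernel:
    """Dexter-exchange hop weights, w(r) = exp(−2r/decay_length), r in Å."""

    decay_length: float = 0.3

    def weight(self, r):
        return np.exp(-2.0 * np.asarray(r, float) / self.decay_length)

    def relative_weight(self, r, r_ref: float):
        """exp(−2(r − r_ref)/L): numerically safe for small decay lengths."""
        return np.exp(-2.0 * (np.asarray(r, float) - r_ref) / self.decay_length)


@dataclass(frozen=True)
class WalkResult:
    start_site_id: int
    steps: int
    outcome: str  # "absorbed" | "trapped"
    end_site_id: int


def _availability(model: NanoparticleModel) -> np.ndarray:
    """Boolean mask of valid hop targets: sensitizer Yb sites or any
    emitter-compartment site (absorbing)."""
    geo = model.geometry
    sens_yb = (model.compartment == geo.sensitizer_compartment) & (
        model.occupant == OCC_YB
    )
    return sens_yb | (model.compartment == geo.emitter_compartment)


def hop_probabilities(
    model: NanoparticleModel,
    site_id: int,
    kernel: HopKernel = HopKernel(),
    table: NeighborTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized hop probabilities from one Yb site.

    Returns ``(target_ids, probabilities)`` over the currently available
    neighbors (Yb sensitizers and absorbing emitter-compartment sites, which
    keep their distance weight).  Raises :class:`TrappedSiteError` when no
    target exists.
    """
    if model.occupant[site_id] != OCC_YB:
        raise MigrationError(f"site {site_id} is not Yb-occupied")
    if table is None:
        table = model.neighbors("as_stated")
    ids, dist = table.neighbors_of(site_id)
    avail = _availability(model)
    keep = avail[ids] if ids.size else np.zeros(0, bool)
    ids, dist = ids[keep], dist[keep]
    if ids.size == 0:
        raise TrappedSiteError(f"site {site_id} has no available migration target")
    w = kernel.relative_weight(dist, float(dist.min()))
    return ids, w / w.sum()


def simulate_walk(
    model: NanoparticleModel,
    kernel: HopKernel,
    start_site: int,
    rng: np.random.Generator,
    table: NeighborTable | None = None,
    max_steps: int = 1_000_000,
) -> WalkResult:
    """Single migration walk until absorption at the interface (or trapping).

    The absorbing hop is counted in ``steps``.  Pure-Python reference path;
    :func:`run_ensemble` uses the compiled equivalent.
    """
    geo = model.geometry
    if not (
        model.compartment[start_site] == geo.sensitizer_compartment
        and model.occupant[start_site] == OCC_YB
    ):
        raise MigrationError(
            f"start site {start_site} is not a Yb site in the sensitizer compartment"
        )
    if table is None:
        table = model.neighbors("as_stated")
    emitter = geo.emitter_compartment
    site = start_site
    for step in range(1, max_steps + 1):
        try:
            ids, p = hop_probabilities(model, site, kernel, table)
        except TrappedSiteError:
            return WalkResult(start_site, step - 1, "trapped", site)
        site = int(rng.choice(ids, p=p))
        if model.compartment[site] == emitter:
            return WalkResult(start_site, step, "absorbed", site)
    return WalkResult(start_site, max_steps, "trapped", site)


@njit(cache=True)
def _walk_kernel(start_ids, nbr_ids, nbr_cum, nbr_deg, is_absorbing,
                 repeats, seeds, max_steps):  # pragma: no cover - compiled
    n = start_ids.size
    mean_steps = np.full(n, np.nan)
    m2 = np.full(n, np.nan)
    n_absorbed = np.zeros(n, np.int64)
    n_trapped = np.zeros(n, np.int64)
    for i in range(n):
        np.random.seed(seeds[i])
        s0 = start_ids[i]
        tot = 0.0
        totsq = 0.0
        for _ in range(repeats):
            site = s0
            steps = 0
            trapped = False
            while True:
                deg = nbr_deg[site]
                if deg == 0:
                    trapped = True
                    break
                u = np.random.random()
                j = 0
                while j < deg - 1 and u > nbr_cum[site, j]:
                    j += 1
                nxt = nbr_ids[site, j]
                steps += 1
                if is_absorbing[nxt]:
                    break
                site = nxt
                if steps >= max_steps:
                    trapped = True
                    break
            if trapped:
                n_trapped[i] += 1
            else:
                n_absorbed[i] += 1
                tot += steps
                totsq += steps * steps
        if n_absorbed[i] > 0:
            mean_steps[i] = tot / n_absorbed[i]
            m2[i] = totsq / n_absorbed[i] - mean_steps[i] ** 2
    return mean_steps, m2, n_absorbed, n_trapped


def _transition_arrays(model, kernel, table):
    """Static walk arrays given the frozen disorder: per-site available
    neighbor ids and cumulative hop probabilities."""
    avail = _availability(model)
    n = model.n_sites
    max_deg = table.ids.shape[1]
    ids = np.full((n, max_deg), -1, np.int32)
    cum = np.ones((n, max_deg))
    deg = np.zeros(n, np.int32)
    walkable = np.flatnonzero(
        (model.compartment == model.geometry.sensitizer_compartment)
        & (model.occupant == OCC_YB)
    )
    for i in walkable:
        nb, dist = table.neighbors_of(i)
        keep = avail[nb]
        nb, dist = nb[keep], dist[keep]
        if nb.size == 0:
            continue
        w = kernel.relative_weight(dist, float(dist.min()))
        c = np.cumsum(w / w.sum())
        ids[i, : nb.size] = nb
        cum[i, : nb.size] = c
        deg[i] = nb.size
    is_absorbing = (model.compartment == model.geometry.emitter_compartment)
    _prune_unreachable(ids, deg, is_absorbing)
    return ids, cum, deg, is_absorbing


def _prune_unreachable(ids, deg, is_absorbing):
    """Zero the degree of sites with no path to the absorbing set.

    A walker landing on such a site can never absorb (possible under Yb
    dilution when a cluster is disconnected from the interface); marking it
    degree-0 traps it immediately instead of walking to the step cap.
    Reachability is found by reverse BFS from the absorbing sites.
    """
    n = deg.size
    if not n:
        return
    src = np.repeat(np.arange(n), deg)
    dst = (
        np.concatenate([ids[i, : deg[i]] for i in range(n) if deg[i]])
        if src.size
        else np.zeros(0, np.int64)
    ).astype(np.int64)
    order = np.argsort(dst, kind="stable")
    dst_sorted, src_sorted = dst[order], src[order]
    starts = np.searchsorted(dst_sorted, np.arange(n + 1))
    reach = is_absorbing.copy()
    frontier = np.flatnonzero(is_absorbing)
    while frontier.size:
        nxt = []
        for j in frontier:
            preds = src_sorted[starts[j] : starts[j + 1]]
            new = preds[~reach[preds]]
            if new.size:
                reach[new] = True
                nxt.append(new)
        frontier = np.concatenate(nxt) if nxt else np.zeros(0, np.int64)
    deg[~reach] = 0


@dataclass
class CumulativeCurve:
    """Step curve: number of sites with per-site mean steps ≤ threshold."""

    thresholds: np.ndarray  # sorted per-site means
    counts: np.ndarray  # 1..n_sites
    label: str = ""

    def evaluate(self, s) -> np.ndarray:
        """Count of sites with mean steps ≤ s (vectorized)."""
        return np.searchsorted(self.thresholds, np.asarray(s, float), side="right")


@dataclass
class WalkStatistics:
    """Ensemble migration statistics for one model.

    ``per_site_mean_steps`` maps initiation site id → mean steps over
    absorbed repeats; trapped repeats are excluded from the means and
    reported via ``trapped_fraction``.
    """

    site_ids: np.ndarray
    mean_steps: np.ndarray  # per site, NaN if never absorbed
    std_steps: np.ndarray
    n_absorbed: np.ndarray
    n_trapped: np.ndarray
    repeats: int
    seed: int
    histogram: tuple[np.ndarray, np.ndarray]  # counts, bin edges
    radial_profile: pd.DataFrame  # bin_center, mean_steps, n_sites
    elevation_profile: pd.DataFrame
    heatmap: dict = field(repr=False, default_factory=dict)

    @property
    def per_site_mean_steps(self) -> dict[int, float]:
        return dict(zip(self.site_ids.tolist(), self.mean_steps.tolist()))

    @property
    def trapped_fraction(self) -> float:
        total = int(self.n_absorbed.sum() + self.n_trapped.sum())
        return float(self.n_trapped.sum() / total) if total else 0.0

    @property
    def ensemble_mean_steps(self) -> float:
        """Mean of per-site means over sites with ≥1 absorbed walk."""
        ok = np.isfinite(self.mean_steps)
        return float(np.mean(self.mean_steps[ok]))

    def cumulative(self, label: str = "") -> CumulativeCurve:
        ok = np.isfinite(self.mean_steps)
        t = np.sort(self.mean_steps[ok])
        return CumulativeCurve(t, np.arange(1, t.size + 1), label)


def _profiles(model, site_ids, means, n_elev_bins=18):
    ok = np.isfinite(means)
    sids, m = site_ids[ok], means[ok]
    r = model.radial_distance[sids]
    theta = model.polar_angle[sids]
    dr = model.cell.d_aa  # one lattice spacing
    r_edges = np.arange(0.0, model.geometry.Rs + 2 * dr, dr)
    t_edges = np.linspace(0.0, math.pi, n_elev_bins + 1)

    def binned(x, edges):
        idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
        n = np.bincount(idx, minlength=len(edges) - 1)
        s = np.bincount(idx, weights=m, minlength=len(edges) - 1)
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return pd.DataFrame({"bin_center": centers, "mean_steps": mean, "n_sites": n})

    radial = binned(r, r_edges)
    elev = binned(theta, t_edges)

    rho = np.hypot(model.positions[sids, 0], model.positions[sids, 1])
    z = model.positions[sids, 2]
    rho_edges = np.arange(0.0, model.geometry.Rs + 2 * dr, dr)
    z_edges = np.arange(-model.geometry.Rs - dr, model.geometry.Rs + 2 * dr, dr)
    ri = np.clip(np.digitize(rho, rho_edges) - 1, 0, len(rho_edges) - 2)
    zi = np.clip(np.digitize(z, z_edges) - 1, 0, len(z_edges) - 2)
    flat = ri * (len(z_edges) - 1) + zi
    size = (len(rho_edges) - 1) * (len(z_edges) - 1)
    cnt = np.bincount(flat, minlength=size).astype(float)
    tot = np.bincount(flat, weights=m, minlength=size)
    with np.errstate(invalid="ignore"):
        grid = np.where(cnt > 0, tot / np.maximum(cnt, 1.0), np.nan)
    heatmap = {
        "rho_edges": rho_edges,
        "z_edges": z_edges,
        "mean_steps": grid.reshape(len(rho_edges) - 1, len(z_edges) - 1),
        "n_sites": cnt.reshape(len(rho_edges) - 1, len(z_edges) - 1),
    }
    return radial, elev, heatmap


def run_ensemble(
    model: NanoparticleModel,
    kernel: HopKernel = HopKernel(),
    repeats: int = 1000,
    seed: int = 0,
    mode: str = "as_stated",
    max_steps: int = 1_000_000,
    histogram_bins: int = 50,
) -> WalkStatistics:
    """Repeat the migration walk from every sensitizer site.

    Each initiation site gets its own RNG stream hashed from ``seed`` and the
    site id, so per-site results do not depend on iteration order.  Fully
    deterministic given ``seed``.
    """
    if repeats < 1:
        raise MigrationError("repeats must be >= 1")
    starts = model.sensitizer_sites
    if starts.size == 0:
        raise MigrationError("model has no Yb sites in the sensitizer compartment")
    table = model.neighbors(mode)
    ids, cum, deg, is_absorbing = _transition_arrays(model, kernel, table)
    # one deterministic uint32-derived seed per initiation site
    seeds = (
        np.random.SeedSequence(seed).generate_state(starts.size).astype(np.int64)
        % (2**31)
    ).astype(np.int64)
    mean, var, n_abs, n_trap = _walk_kernel(
        starts.astype(np.int64), ids, cum, deg.astype(np.int64), is_absorbing,
        int(repeats), seeds, int(max_steps),
    )
    std = np.sqrt(np.maximum(var, 0.0))
    ok = np.isfinite(mean)
    counts, edges = np.histogram(mean[ok], bins=histogram_bins)
    radial, elev, heatmap = _profiles(model, starts, mean)
    return WalkStatistics(
        site_ids=starts,
        mean_steps=mean,
        std_steps=std,
        n_absorbed=n_abs,
        n_trapped=n_trap,
        repeats=int(repeats),
        seed=int(seed),
        histogram=(counts, edges),
        radial_profile=radial,
        elevation_profile=elev,
        heatmap=heatmap,
    )


def cumulative_frequency(stats_list) -> list[CumulativeCurve]:
    """Cumulative site-count curves (sites with mean steps ≤ s) per ensemble."""
    stats_list = list(stats_list)
    if not stats_list:
        raise MigrationError("need at least one WalkStatistics")
    return [s.cumulative(label=str(i)) for i, s in enumerate(stats_list)]
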