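"""Finite spherical core/shell nanoparticle models on the P6̄ hexagonal lattice.

The β-NaREF₄ host places sensitizer-capable rare-earth sites on two Wyckoff
positions of the hexagonal cell: ``1a`` at the cell vertices (always
rare-earth occupied) and ``1f`` inside the cell at fractional coordinates
(2/3, 1/3, 1/2), where the rare earth shares the position with sodium at 50%
structural occupancy.  Only two neighbor distances matter for short-range
energy migration: the 1a–1a distance along the c axis (3.47 Å) and the 1a–1f
distance (3.84 Å).

A :class:`NanoparticleModel` is a finite spherical cut of this lattice with a
core compartment (radius ``Rc``) and an interior-shell compartment (outer
radius ``Rs``), one of which hosts the Yb³⁺ sensitizers depending on the
architecture (``outside_in``: sensitizer shell around an emitter core;
``inside_out``: sensitizer core inside an emitter shell).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "UnitCell",
    "GeometrySpec",
    "NeighborTable",
    "NanoparticleModel",
    "derive_cell_parameters",
    "build_particle",
    "neighbor_table",
    "site_census",
    "save_model",
    "load_model",
]

SITE_1A = 0
SITE_1F = 1
OCC_YB = 0
OCC_NA = 1
OCC_INERT = 2
COMP_CORE = 0
COMP_SHELL = 1
COMP_EXTERIOR = 2

SITE_TYPE_NAMES = {SITE_1A: "1a", SITE_1F: "1f"}
OCCUPANT_NAMES = {OCC_YB: "Yb", OCC_NA: "Na", OCC_INERT: "inert"}
COMPARTMENT_NAMES = {COMP_CORE: "core", COMP_SHELL: "shell", COMP_EXTERIOR: "exterior"}

_DIST_TOL = 1e-6


class LatticeError(ValueError):
    """Invalid lattice parameters or an empty/degenerate model."""


@dataclass(frozen=True)
class UnitCell:
    """Hexagonal cell parameters, fully determined by two neighbor distances.

    Attributes
    ----------
    a, c : float
        In-plane and vertical lattice constants (Å).
    d_aa : float
        1a–1a nearest-neighbor distance along c (Å); equals ``c``.
    d_af : float
        1a–1f nearest-neighbor distance (Å).
    """

    a: float
    c: float
    d_aa: float
    d_af: float

    @property
    def volume(self) -> float:
        """Cell volume (Å³): (√3/2)·a²·c."""
        return math.sqrt(3.0) / 2.0 * self.a**2 * self.c

    @property
    def yb_site_density(self) -> float:
        """Expected Yb-eligible site density (Å⁻³): 1 full 1a + ½ 1f per cell."""
        return 1.5 / self.volume

    def lattice_vectors(self) -> np.ndarray:
        """Row-stacked Cartesian lattice vectors a1, a2, a3."""
        a, c = self.a, self.c
        return np.array(
            [
                [a, 0.0, 0.0],
                [-a / 2.0, a * math.sqrt(3.0) / 2.0, 0.0],
                [0.0, 0.0, c],
            ]
        )


def derive_cell_parameters(d_aa: float, d_af: float) -> UnitCell:
    """Derive hexagonal cell constants from the two printed neighbor distances.

    The vertical constant is ``c = d_aa`` (the two 1a neighbors of a 1a site sit
    directly above and below it).  The 1f site at fractional (2/3, 1/3, 1/2) is
    at in-plane distance a/√3 from the nearest cell vertex, so
    ``d_af² = a²/3 + (c/2)²`` and hence ``a = √3·√(d_af² − (d_aa/2)²)``.

    Parameters are in Å.  Raises :class:`LatticeError` for non-positive or
    geometrically impossible inputs (``d_af ≤ d_aa/2``).
    """
    if not (d_aa > 0 and d_af > 0):
        raise LatticeError(f"distances must be positive, got d_aa={d_aa}, d_af={d_af}")
    if not d_af > d_aa / 2.0:
        raise LatticeError(
            f"geometrically impossible: d_af={d_af} must exceed d_aa/2={d_aa / 2.0}"
        )
    c = float(d_aa)
    a = math.sqrt(3.0) * math.sqrt(d_af**2 - (d_aa / 2.0) ** 2)
    return UnitCell(a=a, c=c, d_aa=float(d_aa), d_af=float(d_af))


#: Cell of the β-NaREF₄ host with the 3.47 Å / 3.84 Å neighbor distances.
DEFAULT_CELL = derive_cell_parameters(3.47, 3.84)


@dataclass(frozen=True)
class GeometrySpec:
    """Core/interior-shell geometry and sensitizer placement.

    ``yb_fraction`` dilutes the Yb-eligible sites of the sensitizer
    compartment uniformly at random (1.0 = fully doped).
    """

    Rc: float
    Rs: float
    architecture: str  # "outside_in" | "inside_out"
    yb_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.architecture not in ("outside_in", "inside_out"):
            raise LatticeError(f"unknown architecture {self.architecture!r}")
        if not (0.0 < self.Rc <= self.Rs):
            raise LatticeError(f"need 0 < Rc <= Rs, got Rc={self.Rc}, Rs={self.Rs}")
        if not (0.0 <= self.yb_fraction <= 1.0):
            raise LatticeError(f"yb_fraction must be in [0, 1], got {self.yb_fraction}")

    @classmethod
    def equal_volume(
        cls, Rc: float, architecture: str, yb_fraction: float = 1.0
    ) -> "GeometrySpec":
        """Equal core and shell volumes: Rs = 2^(1/3)·Rc."""
        return cls(Rc=Rc, Rs=2.0 ** (1.0 / 3.0) * Rc, architecture=architecture,
                   yb_fraction=yb_fraction)

    @property
    def sensitizer_compartment(self) -> int:
        return COMP_SHELL if self.architecture == "outside_in" else COMP_CORE

    @property
    def emitter_compartment(self) -> int:
        return COMP_CORE if self.architecture == "outside_in" else COMP_SHELL


@dataclass
class NeighborTable:
    """Padded per-site neighbor arrays.

    ``ids[i, :deg[i]]`` are neighbor site ids of site ``i``; unused slots are
    −1.  ``mode`` is ``"as_stated"`` (the fixed 2×1a + 3×1f / 6×1a
    coordination) or ``"geometric"`` (all sites within ``d_af + ε`` by
    brute-force search).
    """

    ids: np.ndarray  # (n, max_deg) int32, -1 padded
    dist: np.ndarray  # (n, max_deg) float64
    deg: np.ndarray  # (n,) int32
    mode: str

    def neighbors_of(self, site_id: int) -> tuple[np.ndarray, np.ndarray]:
        d = self.deg[site_id]
        return self.ids[site_id, :d], self.dist[site_id, :d]


@dataclass
class NanoparticleModel:
    """A finite spherical lattice model with frozen site occupancy.

    Site attributes are stored as parallel numpy arrays indexed by site id;
    :meth:`sites_frame` gives the tabular view.  Neighbor tables are built
    lazily per mode and cached.
    """

    cell: UnitCell
    geometry: GeometrySpec
    positions: np.ndarray  # (n, 3) Å
    site_type: np.ndarray  # (n,) int8, SITE_1A / SITE_1F
    occupant: np.ndarray  # (n,) int8, OCC_*
    compartment: np.ndarray  # (n,) int8, COMP_*
    rng_seed: int
    _tables: dict = field(default_factory=dict, repr=False)

    @property
    def n_sites(self) -> int:
        return int(self.positions.shape[0])

    @property
    def radial_distance(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)

    @property
    def polar_angle(self) -> np.ndarray:
        """Polar angle from the +z axis, radians."""
        r = self.radial_distance
        with np.errstate(invalid="ignore"):
            ct = np.where(r > 0, self.positions[:, 2] / np.where(r > 0, r, 1.0), 1.0)
        return np.arccos(np.clip(ct, -1.0, 1.0))

    @property
    def sensitizer_sites(self) -> np.ndarray:
        """Ids of Yb-occupied sites in the sensitizer compartment."""
        mask = (self.compartment == self.geometry.sensitizer_compartment) & (
            self.occupant == OCC_YB
        )
        return np.flatnonzero(mask)

    @property
    def absorbing_sites(self) -> np.ndarray:
        """Ids of emitter-compartment sites (absorbing for migration)."""
        return np.flatnonzero(self.compartment == self.geometry.emitter_compartment)

    def neighbors(self, mode: str = "as_stated") -> NeighborTable:
        if mode not in self._tables:
            self._tables[mode] = neighbor_table(self, mode)
        return self._tables[mode]

    def sites_frame(self) -> pd.DataFrame:
        r = self.radial_distance
        return pd.DataFrame(
            {
                "site_id": np.arange(self.n_sites),
                "site_type": [SITE_TYPE_NAMES[t] for t in self.site_type],
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "occupant": [OCCUPANT_NAMES[o] for o in self.occupant],
                "compartment": [COMPARTMENT_NAMES[c] for c in self.compartment],
                "radial_distance": r,
                "polar_angle": self.polar_angle,
            }
        )


def build_particle(
    cell: UnitCell, geometry: GeometrySpec, seed: int
) -> NanoparticleModel:
    """Enumerate all lattice sites within ``Rs`` and draw the frozen disorder.

    1a sites sit at integer lattice translations, 1f sites at fractional
    (2/3, 1/3, 1/2).  Each 1f site is Yb-eligible with structural probability
    1/2 (otherwise Na), drawn once per model from ``seed``.  ``yb_fraction``
    then dilutes Yb-eligible sites of the sensitizer compartment to inert,
    from an independent child stream so the Na disorder is identical across
    dilutions at the same seed.
    """
    a1, a2, a3 = cell.lattice_vectors()
    Rs = geometry.Rs
    # conservative index ranges: row spacing of the triangular lattice is a·√3/2
    ni = int(math.ceil(Rs / (cell.a * math.sqrt(3.0) / 2.0))) + 2
    nk = int(math.ceil(Rs / cell.c)) + 2
    ii, jj, kk = np.meshgrid(
        np.arange(-ni, ni + 1), np.arange(-ni, ni + 1), np.arange(-nk, nk + 1),
        indexing="ij",
    )
    frac = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    basis = np.stack([a1, a2, a3])
    pos_1a = frac @ basis
    pos_1f = (frac + np.array([2.0 / 3.0, 1.0 / 3.0, 0.5])) @ basis

    eps = 1e-9
    keep_a = np.linalg.norm(pos_1a, axis=1) <= Rs + eps
    keep_f = np.linalg.norm(pos_1f, axis=1) <= Rs + eps
    pos_1a, pos_1f = pos_1a[keep_a], pos_1f[keep_f]
    n_a, n_f = len(pos_1a), len(pos_1f)
    if n_a + n_f == 0:
        raise LatticeError(f"no lattice sites within Rs={Rs} Å (smaller than one spacing)")

    positions = np.vstack([pos_1a, pos_1f])
    site_type = np.concatenate(
        [np.full(n_a, SITE_1A, np.int8), np.full(n_f, SITE_1F, np.int8)]
    )
    r = np.linalg.norm(positions, axis=1)
    compartment = np.where(r <= geometry.Rc + eps, COMP_CORE, COMP_SHELL).astype(np.int8)

    ss = np.random.SeedSequence(seed)
    coin_rng, dilute_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    occupant = np.full(n_a + n_f, OCC_YB, np.int8)
    occupant[n_a:] = np.where(coin_rng.random(n_f) < 0.5, OCC_YB, OCC_NA)

    sens = compartment == geometry.sensitizer_compartment
    # emitter compartment hosts Er/Lu, not modeled site-by-site
    occupant[~sens & (occupant == OCC_YB)] = OCC_INERT
    if geometry.yb_fraction < 1.0:
        eligible = np.flatnonzero(sens & (occupant == OCC_YB))
        drop = dilute_rng.random(len(eligible)) >= geometry.yb_fraction
        occupant[eligible[drop]] = OCC_INERT

    return NanoparticleModel(
        cell=cell,
        geometry=geometry,
        positions=positions,
        site_type=site_type,
        occupant=occupant,
        compartment=compartment,
        rng_seed=int(seed),
    )


def _pad_table(nbrs: list[np.ndarray], dists: list[np.ndarray], mode: str) -> NeighborTable:
    n = len(nbrs)
    deg = np.array([len(x) for x in nbrs], np.int32)
    max_deg = max(1, int(deg.max()) if n else 1)
    ids = np.full((n, max_deg), -1, np.int32)
    dist = np.zeros((n, max_deg))
    for i, (nb, dd) in enumerate(zip(nbrs, dists)):
        ids[i, : len(nb)] = nb
        dist[i, : len(nb)] = dd
    return NeighborTable(ids=ids, dist=dist, deg=deg, mode=mode)


def neighbor_table(model: NanoparticleModel, mode: str = "as_stated") -> NeighborTable:
    """Build the per-site neighbor table.

    ``as_stated`` (default): the migration coordination of the stated
    neighbor shells — each 1a links to its two 1a neighbors at ``d_aa`` plus
    the six 1f candidate positions at ``d_af``; each 1f links to its six 1a
    neighbors at ``d_af``.  With the 50% Na occupancy of 1f sites this gives
    a 1a site the stated three *available* 1f targets on average, and keeps
    the relation symmetric.

    ``upper_1f``: the literal three-1f reading — each 1a links only to the
    three 1f candidates with Δz > 0 (plus its two 1a neighbors); each 1f
    still links to all six 1a.  This variant carries a net upward drift.

    ``geometric``: every site within ``d_af + ε`` by brute-force search
    (also picks up the vertical 1f–1f pairs at ``d_aa``); validation mode.

    Boundary sites simply have shorter lists.
    """
    if mode not in ("as_stated", "upper_1f", "geometric"):
        raise LatticeError(f"unknown neighbor mode {mode!r}")
    cell = model.cell
    cutoff = cell.d_af + 1e-3
    tree = cKDTree(model.positions)
    pairs_lists = tree.query_ball_tree(tree, cutoff)

    nbrs: list[np.ndarray] = []
    dists: list[np.ndarray] = []
    for i, cand in enumerate(pairs_lists):
        cand = np.array([j for j in cand if j != i], dtype=np.int64)
        if cand.size == 0:
            nbrs.append(cand)
            dists.append(np.zeros(0))
            continue
        d = np.linalg.norm(model.positions[cand] - model.positions[i], axis=1)
        if mode == "geometric":
            order = np.argsort(d, kind="stable")
            nbrs.append(cand[order])
            dists.append(d[order])
            continue
        t_i = model.site_type[i]
        t_j = model.site_type[cand]
        if t_i == SITE_1A:
            keep_aa = (t_j == SITE_1A) & (np.abs(d - cell.d_aa) < _DIST_TOL)
            keep_af = (t_j == SITE_1F) & (np.abs(d - cell.d_af) < _DIST_TOL)
            if mode == "upper_1f":
                dz = model.positions[cand, 2] - model.positions[i, 2]
                keep_af &= dz > 0
            keep = keep_aa | keep_af
        else:
            keep = (t_j == SITE_1A) & (np.abs(d - cell.d_af) < _DIST_TOL)
        nbrs.append(cand[keep])
        dists.append(d[keep])
    return _pad_table(nbrs, dists, mode)


def interior_mask(model: NanoparticleModel, table: NeighborTable) -> np.ndarray:
    """True where a site has the full bulk coordination for the table's mode.

    Flags boundary sites (those with fewer neighbors than the bulk count).
    """
    if table.mode == "as_stated":
        want = np.where(model.site_type == SITE_1A, 8, 6)
    elif table.mode == "upper_1f":
        want = np.where(model.site_type == SITE_1A, 5, 6)
    else:
        # geometric bulk: 1a sees 2×1a + 6×1f; 1f sees 6×1a + 2×1f (vertical column)
        want = np.full(model.n_sites, 8)
    return table.deg >= want


def site_census(model: NanoparticleModel) -> pd.DataFrame:
    """Counts per (compartment × site_type × occupant); sums to n_sites."""
    df = model.sites_frame()
    out = (
        df.groupby(["compartment", "site_type", "occupant"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def save_model(model: NanoparticleModel, csv_path: str | Path) -> None:
    """Serialize sites to CSV with a JSON sidecar header (cell, geometry, seed)."""
    csv_path = Path(csv_path)
    model.sites_frame().to_csv(csv_path, index=False)
    header = {
        "cell": {"a": model.cell.a, "c": model.cell.c,
                 "d_aa": model.cell.d_aa, "d_af": model.cell.d_af},
        "geometry": {"Rc": model.geometry.Rc, "Rs": model.geometry.Rs,
                     "architecture": model.geometry.architecture,
                     "yb_fraction": model.geometry.yb_fraction},
        "rng_seed": model.rng_seed,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_model(csv_path: str | Path) -> NanoparticleModel:
    csv_path = Path(csv_path)
    header = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    type_codes = {v: k for k, v in SITE_TYPE_NAMES.items()}
    occ_codes = {v: k for k, v in OCCUPANT_NAMES.items()}
    comp_codes = {v: k for k, v in COMPARTMENT_NAMES.items()}
    cell = UnitCell(**header["cell"])
    geometry = GeometrySpec(**header["geometry"])
    return NanoparticleModel(
        cell=cell,
        geometry=geometry,
        positions=df[["x", "y", "z"]].to_numpy(float),
        site_type=df["site_type"].map(type_codes).to_numpy(np.int8),
        occupant=df["occupant"].map(occ_codes).to_numpy(np.int8),
        compartment=df["compartment"].map(comp_codes).to_numpy(np.int8),
        rng_seed=int(header["rng_seed"]),
    )
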