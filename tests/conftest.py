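import numpy as np
import pytest

from ucnpkit import lattice, migration


@pytest.fixture(scope="session")
def cell():
    return lattice.DEFAULT_CELL


@pytest.fixture(scope="session")
def small_outside_in(cell):
    """Equal-volume outside-in particle small enough for exact Markov checks."""
    geo = lattice.GeometrySpec.equal_volume(12.0, "outside_in")
    return lattice.build_particle(cell, geo, seed=3)


@pytest.fixture(scope="session")
def medium_model(cell):
    """30 Å-radius sphere used for neighbor-count checks."""
    geo = lattice.GeometrySpec(Rc=15.0, Rs=30.0, architecture="outside_in")
    return lattice.build_particle(cell, geo, seed=0)


def markov_mean_steps(model, kernel=None, mode="as_stated"):
    """Independent absorbing-Markov-chain oracle for per-site mean steps.

    Builds hop probabilities directly from neighbor distances and occupancy
    (exp(−2r/L) weights) without using the simulator's probability code, and
    solves (I − Q)·t = 1 for the expected steps to absorption, counting the
    absorbing hop.  Returns {site_id: expected_steps} over sensitizer sites.
    """
    if kernel is None:
        kernel = migration.HopKernel()
    table = model.neighbors(mode)
    geo = model.geometry
    sens = model.sensitizer_sites
    emitter = geo.emitter_compartment
    avail = (
        (model.compartment == geo.sensitizer_compartment)
        & (model.occupant == lattice.OCC_YB)
    ) | (model.compartment == emitter)
    index = {int(s): i for i, s in enumerate(sens)}
    n = len(sens)
    Q = np.zeros((n, n))
    for s in sens:
        ids, dist = table.neighbors_of(int(s))
        keep = avail[ids]
        ids, dist = ids[keep], dist[keep]
        assert ids.size > 0, "oracle assumes no trapped sites"
        w = np.exp(-2.0 * (dist - dist.min()) / kernel.decay_length)
        p = w / w.sum()
        for j, pj in zip(ids, p):
            if model.compartment[j] != emitter:
                Q[index[int(s)], index[int(j)]] += pj
    t = np.linalg.solve(np.eye(n) - Q, np.ones(n))
    return {int(s): float(v) for s, v in zip(sens, t)}
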