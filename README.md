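# ucnpkit

Simulation and single-particle analysis tools for core–shell upconversion
nanoparticles (UCNPs), built around one question: how does the *topological
arrangement* of sensitizer (Yb³⁺) and emitter (Er³⁺) compartments shape
energy migration and, with it, single-particle brightness?

In the β-NaREF₄ host, an absorbed near-infrared quantum migrates between
neighboring Yb³⁺ ions until it reaches the sensitizer–emitter interface. Two
topologies compete: **outside-in** (sensitizer shell around an emitter core,
energy flows inward) and **inside-out** (sensitizer core inside an emitter
shell). `ucnpkit` provides the computational machinery to compare them, plus
the downstream analysis pipeline used in wide-field single-particle imaging
of such particles. Intended users are spectroscopists and microscopists
working on lanthanide nanocrystal photophysics.

## What is inside

* **`ucnpkit.geometry`** — closed-form mean shortest distance to the
  interface for uniformly distributed sensitizers. For a sensitizer core of
  radius R_c the volume average of (R_c − r) is **0.25·R_c**; for an
  equal-volume sensitizer shell (R_s = 2^{1/3}·R_c) the average of (r − R_c)
  is **(3/∛4 − 7/4)·R_c ≈ 0.14·R_c** — a ratio of ≈1.8 favoring the
  outside-in arrangement. Adaptive-quadrature and Monte Carlo oracles are
  included.
* **`ucnpkit.lattice`** — finite spherical P6̄ hexagonal lattice models: 1a
  sites (always rare-earth) and 1f sites (50% Na disorder), with the two
  migration-relevant neighbor distances 3.47 Å (1a–1a along c) and 3.84 Å
  (1a–1f); compartment labeling, Yb dilution, and neighbor tables.
* **`ucnpkit.migration`** — Monte Carlo random walks of the excitation over
  Yb³⁺ sites with Dexter-exchange hop probabilities ∝ exp(−2r/0.3 Å)
  (making the 3.47 Å hop 11.8× more likely than the 3.84 Å one), absorbing
  at the interface; per-site mean step counts, histograms, radial/elevation
  profiles, azimuthally averaged heatmaps, cumulative site curves.
* **`ucnpkit.photometry`** — 2D Gaussian spot fitting
  I(x,y) = I₀/(2πσ²)·exp(−((x−x₀)²+(y−y₀)²)/2σ²) + C on photon-converted
  EMCCD pixels, spot detection, brightness saturation curves, and log-log
  power-law slope n (≈2 for a two-photon process).
* **`ucnpkit.spectroscopy`** — emission-band integration (red 635–683 nm
  over green 510–534 + 535–577 nm) and double-exponential decay fitting with
  the 1/e lifetime.
* **`ucnpkit.tracking`** — localization linking, time-averaged MSD with
  MSD = 4Dτ diffusion estimates, deviation-from-line FWHM for directed
  transport, and affine (1st-degree 2D polynomial) registration of
  luminescence onto SEM coordinates.
* **`ucnpkit.synthetic`** — seeded ground-truth generators for EMCCD
  movies, trajectories, spectra, and decays, so the whole pipeline is
  testable without instrument data.

## Worked example

Compare energy migration in equal-volume outside-in and inside-out
particles (core radius 40 Å, 100 walk repeats per sensitizer site):

```python
from ucnpkit import lattice, migration, geometry

cell = lattice.DEFAULT_CELL   # derived from the 3.47 / 3.84 Å distances
for arch in ("outside_in", "inside_out"):
    geo = lattice.GeometrySpec.equal_volume(40.0, arch)
    model = lattice.build_particle(cell, geo, seed=11)
    stats = migration.run_ensemble(model, repeats=100, seed=5)
    print(f"{arch:11s}: {stats.site_ids.size} sensitizer sites, "
          f"mean steps to interface = {stats.ensemble_mean_steps:.1f}")
print(f"analytic coefficients: core "
      f"{geometry.mean_shortest_distance('inside_out').coefficient:.4f}, "
      f"shell {geometry.mean_shortest_distance('outside_in').coefficient:.4f}")
```

prints

```
outside_in : 3790 sensitizer sites, mean steps to interface = 43.3
inside_out : 3801 sensitizer sites, mean steps to interface = 58.7
analytic coefficients: core 0.2500, shell 0.1399
```

Shell-initiated migration reaches the interface in ~26% fewer steps than
core-initiated migration, the lattice-level counterpart of the 1.8× analytic
distance ratio: the outside-in topology delivers excitations to the emitter
with fewer hops, hence fewer chances to be quenched en route.

A command-line layer wraps the same functions, e.g.:

```sh
ucnpkit mean-distance --architecture outside_in --rc 59
ucnpkit build-lattice --rc 40 --seed 11 --out model.csv
ucnpkit simulate-migration --model model.csv --repeats 100 --seed 5 --out stats.json
```

## Documentation

`docs/methods.md` describes the models, their assumptions, parameter
choices, and known limitations.
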