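# Methods

This note records the models implemented in `ucnpkit`, the assumptions they
make, the defaults they ship with, and what the synthetic-data tests do and
do not establish about real measurements.

## Analytic mean distance to the interface

Sensitizers are assumed uniformly distributed in their compartment and the
lattice is treated as a continuum. The shortest distance from a sensitizer
at radius r to the interface at R_c is |r − R_c|; volume-averaging in
spherical coordinates gives 0.25·R_c for a sensitizer core and
(3/∛4 − 7/4)·R_c ≈ 0.1399·R_c for an equal-volume shell
(R_s = 2^{1/3}·R_c), a ratio of ≈1.787. `shell_coefficient(Rc, Rs)` exposes
the general-R_s shell average separately; the headline coefficient is the
equal-volume case. Two independent numerical checks are provided: the full
spherical triple integral by adaptive quadrature (agreement to ~1e-10) and
inverse-CDF uniform sampling (seeded, with standard errors).

## Lattice model

The β-NaREF₄ host is modeled as a P6̄ hexagonal lattice with two rare-earth
site classes: 1a at the cell vertices (100% rare-earth) and 1f at
fractional (2/3, 1/3, 1/2) (50% rare-earth / 50% Na, quenched disorder).
Only two printed distances determine the cell: d(1a–1a) = 3.47 Å along c
and d(1a–1f) = 3.84 Å, giving c = 3.47 Å and
a = √3·√(d_af² − (d_aa/2)²) ≈ 5.933 Å. The resulting Yb-eligible site
density is 1.5 per cell volume ≈ 14.2 nm⁻³; a 59 Å core then holds ≈12,000
Yb sites, and the equal-volume geometry holds approximately equal numbers in
core and shell.

Particles are spherical cuts of radius R_s centered on a 1a site, with a
closed core compartment [0, R_c] and half-open shell (R_c, R_s]. The Na coin
flips and the `yb_fraction` dilution are drawn from *independent* child
streams of the model seed, so the frozen Na disorder is identical across
dilution levels at the same seed — required for matched-geometry comparisons
of doping series. Emitter-compartment sites are not resolved into Er/Lu/Na;
they act only as absorbing targets.

### Neighbor coordination

Three neighbor tables are available:

* **`as_stated`** (default, used by the simulator): each 1a links to its two
  1a neighbors at 3.47 Å and to all **six** 1f candidate positions at
  3.84 Å; each 1f links to its six 1a neighbors. Because half the 1f
  positions hold Na, a bulk 1a site sees on average the canonical *three
  available* 1f targets; the relation is symmetric.
* **`upper_1f`**: the literal three-1f variant (only the 1f candidates with
  Δz > 0). This was implemented and rejected as the default: restricting to
  one z side gives every 1a→1f hop a fixed upward component and halves
  lateral mobility, which in our runs *reversed* the shell-vs-core step
  ordering the model exists to demonstrate. It is retained for comparison.
* **`geometric`**: every site within 3.84 Å + ε by brute-force search; this
  validation mode additionally picks up vertical 1f–1f pairs at 3.47 Å that
  the migration model does not use.

Boundary sites simply have shorter neighbor lists and are flagged by
`interior_mask`.

## Migration Monte Carlo

Hop weights follow the Dexter exchange form w(r) = exp(−2r/L) with
L = 0.3 Å and r in Å — the unit choice that reproduces the 11.8-fold
preference of the 3.47 Å hop over the 3.84 Å hop
(exp(2·0.37/0.3) = 11.78). At each step the walker chooses among its
currently available targets — Yb-occupied sensitizer neighbors and any
emitter-compartment neighbor — with probabilities proportional to w(r);
landing in the emitter compartment absorbs the walk, and the absorbing hop
is counted as a step (arrival is an event of the walk; all histograms shift
coherently under the opposite convention). The outer particle surface is
non-absorbing: moves beyond R_s simply do not exist.

Under dilution a site may have no available target, and a diluted cluster
may be disconnected from the interface entirely. Walks that start at (or
would enter) such sites are *trapped*: they are excluded from step
statistics and reported as `trapped_fraction`. Disconnected sites are found
up front by reverse breadth-first search from the absorbing set, so
non-terminating walks are impossible by construction; a `max_steps` cap
(10⁶) remains as a safety net. A small trapped fraction (≲0.5%) occurs even
at full doping from geometrically isolated sites in the outermost lattice
skin.

Reproducibility: every initiation site gets its own RNG stream hashed from
the master seed and the site index, so per-site statistics are independent
of iteration order and bit-identical across runs. The inner walk loop is
compiled with numba; a pure-Python `simulate_walk` is the readable reference
path, validated against the absorbing-Markov-chain fundamental-matrix
solution (I − Q)⁻¹·1 on small particles.

Aggregate views follow the conventions of the migration analysis: a
histogram of per-site mean step counts, a radial profile and an 18-bin
polar-elevation profile, and an azimuthally averaged heatmap on a
(cylindrical radius, z) grid with bin width equal to one lattice spacing
(3.47 Å). Cumulative curves count sites with mean steps ≤ s.

Problem sizes: the packaged tests and examples use equal-volume particles of
R_c = 25–40 Å at 100–2000 repeats per site (seconds to tens of seconds on
one core). The full-scale configuration — 12,000 Yb sites per compartment
(R_c = 59 Å) at 1000 repeats — runs with the same code path in well under an
hour.

### Observed behaviors worth recording

* Shell-initiated migration needs fewer steps than core-initiated at every
  tested radius ≥ 30 Å (e.g. 43.3 vs 58.7 at R_c = 40 Å), and the
  core radial profile decreases monotonically toward the interface.
* Dilution to 50% Yb slows aggregate migration and its cumulative site
  curve is dominated by the fully doped one. Site-by-site the picture is
  subtler: for sites adjacent to the interface, removing competing Yb
  neighbors *raises* the renormalized absorption probability, so many
  boundary-adjacent sites individually absorb faster under dilution; in an
  equal-volume shell (thickness ≈ 0.26·R_c, one to four lattice spacings)
  such sites are the majority. The aggregate and cumulative statements are
  the robust ones.

## Photometry

Spots are fit with the normalized-amplitude Gaussian
I(x,y) = I₀/(2πσ²)·exp(−((x−x₀)²+(y−y₀)²)/(2σ²)) + C evaluated at pixel
centers (integer pixel coordinates, origin at the top-left pixel center),
by unweighted least squares on photon-converted pixels; a Poisson-MLE
objective was considered and left out as the plain least-squares reading is
the simplest faithful one. I₀ is then the total spot flux in photons/s (the
single-particle brightness) and the fitted peak value is the
photons/s/pixel variant. Initialization uses the centroid, second moment,
minimum, and background-subtracted sum; non-convergence or a σ pinned at
its bounds raises instead of returning silently. Camera conversion is
counts·(e⁻/count)/EM-gain → photons, divided by exposure for rates; the
EMCCD calibration is user-supplied configuration, as it is
instrument-specific. Detection thresholds local maxima at median + k·MAD
(default k = 6) with a minimum separation.

Power-law slopes n are ordinary least squares of log₁₀ brightness on log₁₀
power density; the fit range should be restricted to the unsaturated regime,
which the saturation-aware synthetic generator makes explicit (its effective
slope falls once P approaches P_sat).

## Spectroscopy

Band areas are trapezoidal integrals on the native wavelength grid (no
interpolation), over closed windows: red 635–683 nm, green 510–534 and
535–577 nm; the red-to-green ratio divides the red area by the summed green
areas. Decays are fit with A₁e^{−t/τ₁} + A₂e^{−t/τ₂} + baseline (free
baseline; t = 0 at the first sample), components ordered τ₁ ≤ τ₂, and the
reported lifetime is the 1/e time of the *fitted*, baseline-subtracted
curve, found by bracketed root finding. The fitted-curve choice (rather
than the raw data crossing) makes τ_1e noise-robust; for single-exponential
input the amplitude split is non-identifiable but the fitted curve, and so
τ_1e, is well determined.

## Tracking and registration

Linking is greedy nearest-neighbor in ascending distance order within a
maximum displacement, with optional gap bridging. MSD is the time-averaged
mean over all ordered pairs at each lag (uniform sampling assumed), and the
diffusion fit is weighted least squares over the first four lags (a common
default for short noisy tracks) with MSD = 4Dτ for 2D imaging; the
intercept absorbs the 4σ² localization-noise offset. Directed segments are
summarized by the FWHM (2√(2 ln 2)·σ) of perpendicular deviations from a
total-least-squares line, with σ from a Gaussian fit to the deviation
histogram (sample-σ fallback). No stop/go segmentation is attempted; the
caller provides segment windows. Registration solves the six coefficients
of the 1st-degree 2D polynomial (affine) map by least squares and reports
the rms control-point residual; point matching is mutual-nearest-neighbor
after coarse alignment, with a spacing-derived distance gate.

## Synthetic data

The generators emulate the inputs the analyses assume, with machine-readable
truth: EMCCD frames (Poisson shot noise, gamma-distributed EM amplification
— the standard EMCCD excess-noise model — and Gaussian read noise over the
rendered Gaussian spots), brightness k·(P/(1+P/P_sat))^n, three-band
spectra at 521/541/654 nm with per-band power laws, double-exponential
decays, and 2D motion models (Brownian; directed with transverse scatter;
reflected-disk confined; two-state stop-and-go). Defaults mimic the
emulated imaging setup: 10 frames/s, 160 nm pixels, PSF σ = 76 nm.

What passing tests show: the estimators are unbiased and correctly scaled
on data drawn from the model they assume. What they do not show: robustness
to instrument realities absent from the generators — drift, focus drift,
pixel-response nonuniformity, emitter blinking, anisotropic PSFs, spectral
response of the detection path, or background structure in cells.

## Known limitations

* Migration is step-counted, not time-resolved: no rates, no upconversion
  kinetics on the emitter side, no back-transfer, and no long-range
  (multipolar) transfer channel.
* The lattice carries no strain, interdiffusion, or layer mismatch; the
  interface is geometrically sharp.
* Equal-volume geometry is assumed wherever the 0.14 coefficient or the
  1.8 ratio is quoted.
* The dilution comparison is meaningful in aggregate; per-site orderings
  near the interface are noise-sensitive and partly reversed (see above).
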