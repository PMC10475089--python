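# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. All quantities are computed by the code; the
problem sizes quoted are the ones used by the shipped tests and scripts.

## The measurement model

A membrane protein carrying a photoactivatable fluorophore is imaged at
10 Hz (frame interval Δt = 0.1 s) on an EM-CCD with 160 nm effective
pixels. Sparse activation keeps at most a few emitters per cell per frame.
An emitter contributes a diffraction-limited spot, modelled as a symmetric
2D Gaussian (default σ_PSF = 130 nm) integrated over each pixel, on a
uniform background; photon shot noise is Poisson. Under HILO illumination
only a thin section of the cell surface near the coverslip is excited;
the simulator models this as a hard visibility slab of height
`hilo_depth` (default 300 nm) above the lowest cell point.

Particles live on the surface of a spherocylinder: a cylinder of radius
r = W/2 capped by hemispheres, total pole-to-pole length L. The cell lies
flat on the coverslip. Each particle is either *immobile* (true
displacement zero) or *mobile* (Brownian surface diffusion with
coefficient D); state switching within a track is not modelled, because
retained tracks last at most 1.2 s and the analysis classifies whole
tracks. Fluorescent on-times are geometric with mean `mean_on_frames`
(default 8 frames, centring the 4–12-frame retention window);
activations are Poisson per frame until the configured particle budget is
consumed.

### Surface diffusion scheme

Mobile particles take Euler steps in the local tangent plane — two
independent N(0, 2DΔt) components along an orthonormal tangent basis —
followed by orthogonal reprojection onto the surface (clamp the axial
coordinate to the cylindrical segment, then push radially to distance r).
The scheme is convergent for DΔt ≪ r²; at the defaults
(DΔt = 2.7×10⁻³ µm², r² = 0.25 µm²) the per-step RMS arc is ~74 nm ≈ r/7.
Reprojection maps the tangent step to a slightly shorter chord, biasing
the lag-1 MSD down by ≈(σ_step/r)²/4 ≈ 2%; the projection of off-axis
surface motion onto the image plane compresses it further (cos²φ for the
circumferential component at polar angle φ). Both effects are physical
consequences of imaging curved-surface diffusion in 2D and are inherited
by the recovered D (see *Recovery behaviour*).

## Estimators

**Localization.** Candidates are local maxima of a
difference-of-Gaussians filter (σ = 1 and 3 px) exceeding
`detection_threshold` (default 5) times a robust SD (1.4826·MAD); maxima
closer than the fit window are merged to the brighter one. Each candidate
is fit over a `fit_window` (default 7×7 px) by least squares with the
pixel-integrated Gaussian A·G(x₀, y₀, σ) + b. Fits that do not converge,
or whose σ leaves [0.3, 3] px, are rejected and counted. Least squares
(not MLE) is used: at the simulated signal-to-noise levels the difference
is negligible against the 20 nm noise floor assumed downstream.
Coordinates are physical: pixel (row i, col j), 0-based, has centre
((j+0.5)·160, (i+0.5)·160) nm. Rendering + refitting round-trips positions
within 5 nm at high SNR, and the precision scales as photons^(−1/2)
(RMSE ≈ 2.4 nm at 5000 photons, background 10).

**Linking.** Consecutive-frame localizations are matched by a minimum-
total-distance one-to-one assignment with a hard gate of 320 nm, solved
with the Hungarian algorithm on the classic augmented matrix (a dummy
partner of cost equal to the gate per row and column), so any pair within
the gate beats leaving both ends unmatched, and the matching is
deterministic. No gap closing: a blink or a slab exit ends the track.
Tracks of 4–12 localizations are retained; longer tracks are rejected
whole rather than truncated, which would manufacture data. Durations are
reported as n·Δt (4 frames ↔ 0.4 s).

**Mobility classification.** A track is immobile iff the axis-aligned
bounding box of its positions has both sides < 160 nm ("explored less
than one pixel"). The statistic is exact and assumption-free, but on
4-frame mobile tracks at D = 0.0272 µm²/s it fires ~44% of the time by
chance (per-axis step SD 74 nm); averaged over the retained length
distribution the mobile→immobile contamination is ≈15–16%, measured both
by a direct Monte-Carlo of the bounding-box statistic and by the pipeline
(the two agree within ±0.03). Consequently the *classified* immobile
fraction of a mixture overstates the true immobile weight by roughly
(1 − f)·0.15, and in end-to-end runs the HILO slab adds a second
inflation: immobile tracks never leave the slab while mobile ones do, so
retention enriches immobile tracks. Users comparing conditions should
compare classified fractions between conditions (the contamination is
common-mode) rather than read them as absolute mixture weights.

**TAMSD and fits.** TAMSD(kΔt) is the mean squared planar displacement
over all n−k overlapping pairs, k = 1..n−1 (exact match to the O(n²)
definition is property-tested). α is the OLS slope of log TAMSD vs log
lag over the first four lags — the same window as the D fit, because lags
beyond 4 rest on very few pairs in ≤12-frame tracks. Tracks with fewer
than four lags (4-localization tracks) or a zero TAMSD value are excluded
with a recorded cause. α ∈ [0, 1.5] (inclusive at both ends, so retained
counts are reproducible) keeps diffusive tracks; ballistic motion (α → 2)
is excluded. D = slope/4 of a free-intercept straight-line fit of TAMSD
to the first four lags; the intercept absorbs the 4σ² static-noise offset
(0.0016 µm² at σ = 20 nm) that a through-origin fit would fold into D. A
through-origin variant is available behind a switch. Non-positive fitted
D (noise-dominated tracks) is flagged but the track stays in the mobile
mean, as no exclusion rule exists for it.

**Population statistics.** The bootstrap unit is the whole track, never
the displacement: 1000 resamples give the mean and SD of the immobile
fraction (over all retained tracks) and of the mean mobile D (over
mobile, α-retained tracks). The bootstrap SD of a Gaussian mean matches
σ/√n within 10% at n = 1000. The fixed significance rule — means
differing by > 0.005 in native units — is applied identically to
fractions (dimensionless) and D (µm²/s); the rule is symmetric, and a
self-comparison is never significant. One-way ANOVA (classical
between/within decomposition via scipy) serves the morphometry
comparisons.

**Cell geometry and polar statistics.** The pole zone of arc depth d
along the extended centreline has area 2πr·d per pole on either the cap
(Archimedes' hat-box) or the cap-plus-cylinder band, so the polar surface
fraction reduces to 2d/L — 0.192 for L = 5 µm, d = 480 nm, cross-checked
by 10⁶-point uniform surface sampling (agreement within 0.002). Particle
pole assignment projects the position onto the mask-derived centreline
and thresholds the arc distance to the nearer tip at 480 nm; one track
counts once, located by its first localization (tracks rarely cross the
boundary within 1.2 s; a majority-vote rule is available). Uniformly
distributed surface particles reproduce the analytic share — the link
between the counting statistic and the geometry.

**Morphometry.** The centreline is the ridge of the mask approximated by
principal-axis binning (one-pixel bins, centroid per bin, light
smoothing), extended along the end tangents to the outline; length is its
arc length. Width is twice the median distance-transform value along the
central 50% of the centreline, minus a half-pixel because the Euclidean
distance transform measures to background pixel *centres*. Rendered
spherocylinder masks over L ∈ {3, 5, 8} µm, W ∈ {0.8, 1.0} µm round-trip
both dimensions within one pixel. For a disk the estimator is
intrinsically anisotropic — the median of r − |x| over the central half
of a diameter is 0.875 r, so L/W approaches 8/7 ≈ 1.14 even in the
continuum — and strongly bent cells are outside the design envelope
(principal-axis binning assumes a dominant axis).

## Recovery behaviour at the default study conditions

With 2000 planar Brownian tracks (D = 0.0272 µm²/s, σ_loc = 20 nm,
geometric lengths conditioned to 4–12 frames) the per-track pipeline
recovers the population mean D within a few percent and a median α of
≈0.87–0.88. The median sits below 1 for two compounding reasons: the 4σ²
noise offset deterministically flattens the log-log slope (to ≈0.93 at
these settings), and the sampling distribution of short-track TAMSD
exponents is left-skewed. End-to-end (simulate → render → localize → link
→ analyze → summarize, ~1500 particles, 1800 frames, single cell), the
recovered mean D lands 10–20% below truth — the surface-projection and
chord effects described above — and the classified immobile fraction
overstates the simulated 13.1% for the contamination and enrichment
reasons above. These are properties of the measurement, not estimator
defects; the simulator exists precisely to make them visible.

## What the simulator does not model

No EM-CCD gain or readout noise; no astigmatic/3D PSF; no TIRF-style
exponential intensity decay (the HILO slab is a hard cutoff — a soft
profile would add parameters without a testable benefit); no state
switching within tracks; no cell-to-cell variability in D. Localization
precision and slab depth of any particular microscope are free
parameters (`localization_sigma`, default 20 nm; `hilo_depth`, default
300 nm). Passing tests on synthetic data therefore demonstrate estimator
correctness under the stated model, not robustness to every real-world
artefact (drift, dense overlapping emitters and multi-emitter fitting are
explicitly out of scope).

## Determinism

Every stochastic stage takes a `numpy.random.Generator`. The pipeline
derives per-stage generators from the single run seed via
`SeedSequence(entropy=seed, spawn_key=(stage,))`, so stages can be rerun
independently and identical configs produce identical CSVs; the run
manifest records the config hash, seed, versions and per-filter counts
needed to reproduce every number in a report.
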