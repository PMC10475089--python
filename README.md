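# sptpalm

Analysis of single-particle-tracking PALM (sptPALM) experiments on
membrane-bound proteins of rod-shaped bacteria — the kind of data produced
when peptidoglycan synthases and hydrolases carrying a photoactivatable
fluorescent tag are imaged at 10 Hz under HILO illumination — together with
a ground-truthed simulator of the whole imaging regime, so every stage of
the analysis can be validated without any experimental download.

## What it computes

Starting from a 16-bit TIFF movie (or a pre-computed localization/track
table), the pipeline:

1. **Localizes** sparse emitters per frame: difference-of-Gaussians
   detection, then a least-squares fit of a symmetric, pixel-integrated 2D
   Gaussian; the fitted centre is the particle position (160 nm pixels,
   half-pixel-centre coordinate convention).
2. **Links** localizations in consecutive frames into trajectories by a
   globally optimal one-to-one assignment within a hard 320 nm (two-pixel)
   gate; no gap closing. Tracks of 4–12 localizations (0.4–1.2 s at 10 Hz)
   are retained.
3. **Classifies** each track: *immobile* if the bounding box of all its
   positions fits within one pixel (160 nm × 160 nm), otherwise *mobile*.
4. **Fits** each mobile track's time-averaged mean squared displacement
   (TAMSD). The anomalous exponent α comes from the power law

   log TAMSD = log 4D + α · log Δt

   over the first four lags; tracks with α outside [0, 1.5] are excluded as
   non-diffusive. The diffusion coefficient D comes from a straight-line
   fit of MSD = 4DΔt to the first four lags, with a free intercept that
   absorbs the static localization-error offset 4σ².
5. **Maps** particles onto cell coordinates derived from segmentation
   masks: a region within 480 nm (three pixels) of either cell tip is a
   *pole*, the rest *nonpolar*. For an idealised spherocylinder the polar
   surface share has the closed form 2d/L (19.2% for a 5 µm × 1 µm cell at
   d = 480 nm).
6. **Summarizes** each condition with the immobile fraction and the mean
   mobile D, with means and SDs from 1000 bootstrap resamples of whole
   tracks; two condition means differing by more than 0.005 (native units)
   are flagged significant, and a one-way ANOVA is provided for cell
   morphometry (length, width, L/W).

The simulator places a configurable mixture of immobile and
surface-diffusing particles on a 3D spherocylindrical cell, steps mobile
ones in the local tangent plane (per-axis variance 2DΔt) with reprojection
onto the surface, gates visibility by a HILO slab above the coverslip,
bleaches with geometric lifetimes, and renders movies with an
integrated-Gaussian PSF and Poisson noise.

## Worked example

```python
import numpy as np
from sptpalm import MobilityModel, build_cell, pole_surface_fraction
from sptpalm.pipeline import RunConfig, run_pipeline

cell = build_cell(5.0, 1.0)          # 5 µm × 1 µm spherocylinder
cell.surface_area                     # 15.708 µm²
pole_surface_fraction(cell, 480.0)    # 0.192 — poles hold ~19% of the surface

# simulate an acquisition at the default study conditions
# (D = 0.0272 µm²/s, 13.1% immobile, 10 Hz, 20 nm localization noise)
cfg = RunConfig(seed=7, n_particles=2000, n_frames=2500, label="untreated")
res = run_pipeline(cfg)

results = MobilityModel(res.tracks, apply_length_filter=False).fit(
    label="untreated", seed=7
)
print(results.summary())
```

```
Single-particle mobility summary
==============================================
condition:            untreated
tracks retained:      378  (rejected: 0 short, 0 long)
immobile:             113  fraction 0.299 ± 0.025 (bootstrap)
mobile (α-retained):  211
excluded (α/fit):     54
mean D mobile:        0.02545 ± 0.0015 µm²/s (bootstrap)
bootstrap samples:    1000  seed: 7
==============================================
```

The mean mobile D recovers the simulated 0.0272 µm²/s within ~7%. The
classified immobile fraction (0.299) sits well above the simulated mixture
weight (0.131): short mobile tracks frequently fit inside one pixel by
chance, and the HILO slab preferentially truncates mobile tracks, so the
bounding-box count overstates the truly immobile population. The simulator
makes this contamination measurable — see `docs/methods.md` for the
quantitative analysis.

A full command-line round trip:

```bash
sptpalm demo --out run/ --seed 2 --n-particles 400
# retained 97 tracks; immobile fraction 0.351 ± 0.048; mean mobile D 0.02319 ± 0.0027 µm²/s
sptpalm report run/
```

Stage-by-stage subcommands (`simulate`, `render`, `localize`, `track`,
`analyze`, `spatial`, `summarize`) read and write CSV/TIFF at any entry
point; every run writes a `manifest.json` with the config hash, seed,
library versions, and the record counts surviving each filter.

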