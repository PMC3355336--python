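# chromacube

Comparative analytics for comprehensive two-dimensional gas
chromatography – mass spectrometry (GC×GC-MS) data, as a headless
Python library plus a batch CLI.

GC×GC-MS resolves complex metabolite mixtures on two coupled columns: a
modulator re-injects first-column effluent every *P* seconds, so each
compound gets two retention times (RT1, RT2) and a mass spectrum. A run
is a dense intensity cube over (RT1, RT2, m/z). Typical studies compare
*groups* of such runs — cases vs. controls — and need per-cell
statistics, spectral comparison and reproducible renders rather than an
interactive GUI. chromacube provides that analytics layer:

* **I/O** — ANDI-MS netCDF acquisitions folded into (RT1, RT2, m/z)
  cubes with nominal integer-mass binning; a bit-exact internal cube
  container (OMV); cropping and region/spectrum extraction.
* **TIC statistics** — total ion count grids `TIC(i,j) = Σ_m I(i,j,m)`
  with optional mass filters; for a sample group *A* the mean TIC μ_A
  and the population standard deviation

      σ_A = sqrt( (1/n_A) Σ_i (x_i − μ_A)² )

  per cell; signed difference grids; and z-value maps

      z = (μ_A − b) / σ_A

  scoring a sample grid *b* against the group (positive z = sample
  below the group mean — this orientation drives the bipolar colour
  maps). Samples are expected to be pre-normalized
  (`normalize_total` provides total-intensity normalization).
* **Spectra** — signed difference spectra over the union of mass bins,
  cosine similarity, and windowed library matching against a CSV
  spectral library.
* **Class-template volumes** — per-voxel mean and globally normalized
  variance across a labelled sample set, with variance-modulated
  opacity `α_out = α_in (1 − k·variance)`, k = 0.5 by default, and a
  deterministic front-to-back compositing projection along the mass
  axis.
* **Peaks** — strict local-maximum detection on TIC grids,
  two-threshold and score-plane filtering of candidate tables, and
  weighted 2-D Gaussian kernel density estimation over peak locations.
* **Rendering** — deterministic PNG output: colour-mapped 2-D TIC
  images, shaded height fields (colour or high-contrast grayscale),
  and bar/line spectrum plots with a mid-baseline mode for signed
  difference spectra.
* **Synthetic data** — a generator of sample cubes and case/control
  groups with known ground truth (Gaussian peaks with characteristic
  spectra, standing-current + column-bleed background, white noise,
  per-sample scaling and retention jitter), so the whole pipeline is
  testable without instrument data.

## Worked example: recovering an implanted group difference

```python
import numpy as np
from chromacube import (default_sim_spec, generate_group, compute_tic,
                        normalize_total, group_stats, z_map, detect_peaks)

spec = default_sim_spec(seed=42)
control = generate_group(spec, n=5, effect={}, group_seed=0)
case = generate_group(spec, n=5, effect={0: 3.0}, group_seed=1)  # peak 0 at 3x

ctl = group_stats([normalize_total(compute_tic(d)) for d in control], "control")
case_mean = group_stats([normalize_total(compute_tic(d)) for d in case], "case").mu
zm = z_map(ctl, case_mean)
i, j = np.unravel_index(np.argmax(np.abs(zm.values)), zm.values.shape)
print(f"extreme z = {zm.values[i, j]:.2f} at RT1 = {zm.rt1_axis[i]:.0f} s, "
      f"RT2 = {zm.rt2_axis[j]:.2f} s")
pt = detect_peaks(compute_tic(control[0]), min_intensity=80.0)
print(f"detected {len(pt)} peaks in one control sample")
```

Output:

```
extreme z = -39.66 at RT1 = 32 s, RT2 = 0.80 s
detected 10 peaks in one control sample
```

The implanted fold-change-3 peak sits at RT1 = 32 s, RT2 = 0.80 s: the
most extreme z-map cell lands exactly on it, and its sign is negative
because the case group lies *above* the control mean there. The peak
count includes the six implanted modes plus a few noise maxima that a
higher threshold removes.

The same pipeline is available from a shell:

```bash
chromacube simulate --n 5 --seed 0 --out sims/
chromacube tic --in sims/sample_000.omv --masses 50:60 --out tic.csv
chromacube zmap --group sims/sample_001.omv --group sims/sample_002.omv \
    --sample sims/sample_000.omv --out z.csv
chromacube render --in sims/sample_000.omv --view height-hc --out hf.png
```

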