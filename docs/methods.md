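# Methods

## Data model

A GC×GC-MS acquisition is stored as a dense cube `I(i, j, m)` over
strictly increasing axes RT1 (seconds, one entry per modulation), RT2
(seconds in `[0, P)` with modulation period `P`) and nominal integer
m/z bins. Intensities are non-negative 32-bit floats; the fixed
little-endian float32 C-order layout of the OMV container (RT1 slowest,
m/z fastest) is what makes write/read round-trips bit-exact, which the
suite verifies literally.

The ANDI-MS reader folds the linear scan-time axis: with first scan
time `t0` and scan interval `dt` (median inter-scan gap, so
microsecond-level acquisition jitter cannot shift scans), scan `s` at
nominal index `round((t−t0)/dt)` lands in modulation
`floor(idx / (P/dt))` and phase `idx mod (P/dt)`. Centroided m/z values
are binned to the nearest integer (59.7 and 60.3 both fall in bin 60),
summing collisions; the tail of an incomplete final modulation is
zero-padded. Total intensity is conserved exactly up to any mass-range
truncation requested.

## Group statistics

All grids assume samples were multiplicatively pre-normalized
(`normalize_total` rescales a TIC so its mean cell value is 1); the
statistics functions never normalize internally. For a group of `n`
TIC grids the per-cell standard deviation uses the population divisor
`n` (a `ddof` switch exposes the sample form; the default is the
population form deliberately). The z-map of a sample `b` is
`z = (μ − b)/σ` — positive where the sample lies *below* the group mean.
That inverted orientation is intentional: the bipolar colour mapping
(red positive / green negative) is defined against it. Where `σ = 0`
the z-value is 0 on exact agreement and `±z_clip` (default 10)
otherwise; the clip is an implementation choice that keeps maps bounded
and renderable, not a statistical claim.

Why pre-normalization matters here: a per-sample multiplicative
response factor contributes variance proportional to signal, so with
raw TICs the group σ is inflated precisely at the tallest features and
the extreme |z| of a real effect can migrate to the effect's skirt.
Total-intensity normalization removes that term; the parameter-recovery
experiment in the test suite applies it and recovers the implanted mode
within one cell in 98 of 100 replicates.

## Spectral comparison

Spectra of different supports are compared over the union of their
integer mass bins with implicit zeros. Difference spectra are signed
(rendered against a mid-height baseline). Similarity is the plain
cosine — symmetric and scale-invariant — and library matching scores
the *summed* spectrum of a selected window against every entry,
returning the top k with ties broken by compound id. Weighted dot
products, retention-index constraints and deconvolution of coeluting
peaks are out of scope.

## Class templates and opacity modulation

For a labelled sample set the template holds the voxelwise mean and the
population variance divided by its *global* maximum, so
`variance_norm ∈ [0, 1]`. Per-voxel opacity is then attenuated as
`α_out = α_in (1 − k · variance_norm)` with `k = 0.5` by default,
bounding the attenuation factor in `[1 − k, 1]`: voxels consistent
across the class stay opaque, variable voxels fade. Global (rather than
per-neighbourhood) normalization is a deliberate choice; a
locally-normalized variant would emphasise different structure and is
not provided. The projection composites front-to-back along the mass
axis (lowest bin in front, viewing the RT plane) with the standard over
operator and early termination at accumulated α ≥ 0.999.

## Colour mapping and rendering

Values are normalized by `log(1 + max(v − vmin, 0)) / log(1 + vmax − vmin)`
(default) or linearly, clamped to `[0, 1]`; signed modes normalize |v|
and carry the sign. The continuous scheme evaluates piecewise-linear
hue/saturation/brightness curves and converts through the standard
hexcone; defaults are documented constants: a blue→red sweep for
intensity, hue 0 (red) for positive and hue 120 (green) for negative
differences, with exact zero mapped to black. The discrete scheme is a
first-edge-≥-value bin lookup; `auto_bins` places edges at equal
quantiles (computed on raw values — quantiles commute with the
monotone log1p transform) and sweeps hues 240°→0°.

Rendering is deterministic by construction: one pixel per grid cell
(integer upscaling only, no interpolation), RT1 on x and RT2 on y with
the origin lower-left. The height field uses an orthographic top-down
projection instead of an interactive camera, keeping the photometric
model: a single light along +z with
`brightness = ambient + diffuse·max(n_z,0) + specular·max(n_z,0)^shininess`
(ambient 0.2, diffuse 0.6, specular 0.4, shininess 16 — documented,
arbitrary constants). Peak heights are scaled so the tallest peak spans
a quarter of the grid extent; vertex normals come from central
differences (the mean of adjacent face normals on a regular grid).
High-contrast mode renders the shade alone as grayscale, which exposes
small peaks regardless of their colour-mapped intensity.

## Peak model

`detect_peaks` marks cells strictly greater than every cell in an
odd-sized window (truncated at edges; plateau ties disqualify) and at
least `min_intensity`. The threshold should sit above the background
TIC ceiling — in the reference synthetic conditions the bleed ramp tops
out near 67 TIC counts and the weakest implanted mode is ~100, so the
bench uses 80. The two candidate scores are generic significance-like
columns filtered by conjunction of `score ≤ threshold` (direction is a
documented assumption; the scores originate in upstream statistical
detection, outside this package) or by a half-open rectangle in the
score plane. The KDE over peak locations is a weight-weighted diagonal
Gaussian product kernel with per-axis Scott bandwidths
(`σ_axis · n_eff^(−1/6)`, effective n from the weights; 1 s fallback on
a degenerate axis), evaluated on a grid padded by five bandwidths so
the trapezoid integral is 1 within 1e-3.

## Synthetic study conditions

The reference conditions (`default_sim_spec`) simulate a 40×30×24 cube
(RT1 × RT2 × m/z from 50) with a 4 s modulation period and six
well-separated Gaussian peaks whose centres lie exactly on grid cells,
amplitudes 40–150 with unit-sum characteristic spectra, widths ≈1.5
cells per axis; a standing-current offset of 2 with bleed slope
0.005 s⁻¹; white noise of unit standard deviation; rigid per-sample
retention jitter of (1.0 s, 0.033 s) ≈ a quarter cell per axis; and a
uniform per-sample intensity scale in [0.9, 1.1]. These sizes keep the
full test bench (including the 100-replicate recovery study) in the
low seconds while leaving the statistical effects (multiplicative
variance inflation, jitter-broadened σ at peak flanks) clearly visible.

What the generator does *not* emulate: coelution with overlapping
spectra, detector saturation, solvent fronts, mass-dependent peak
shapes, and non-rigid (per-peak) retention drift. Passing tests
therefore demonstrate correctness of the statistics and plumbing under
a clean additive model, not robustness to alignment error — peak
alignment is explicitly out of scope.

Noise is clipped at zero after summation (intensities must stay
non-negative), a documented deviation from pure Gaussian noise that
slightly biases near-zero background cells upward.

## Numerical choices

* Accumulations over cubes are performed in float64 regardless of the
  float32 storage type; conservation checks hold to 1e-9 relative.
* Physical-unit region selection maps to the nearest axis value with
  ties toward the lower index; the upper endpoint is inclusive.
* Group/axis mismatches raise immediately rather than broadcasting.
* Determinism: every stochastic routine takes an explicit seed; sample
  generation seeds a generator with the pair (spec seed, sample seed),
  and per-sample seeds within a group are `group_seed·100003 + i`.

## Limitations

* No peak alignment or retention-time warping before group statistics;
  jitter larger than about half a cell will smear σ and displace z
  extremes.
* The OMV container is uncompressed; cubes are held fully in memory.
* Library matching uses cosine only, and matches window sums, not
  per-voxel spectra.
* The two peak scores carry no semantics here; threshold direction
  (≤, smaller = stronger) must match the upstream tool's convention.
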