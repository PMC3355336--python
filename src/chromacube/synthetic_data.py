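"""Synthetic GCxGC-MS sample generation with known ground truth.

A simulated acquisition is the sum of three ingredients that dominate
real chromatograms:

* **Peaks** — separable 2-D Gaussians in (RT1, RT2), each with a fixed
  characteristic mass spectrum; voxel contribution is
  ``A * exp(-(rt1-c1)^2 / 2 s1^2) * exp(-(rt2-c2)^2 / 2 s2^2) * spectrum(m)``.
* **Background** — a constant standing-current offset plus a linear
  column-bleed ramp along RT1, with additive white Gaussian noise.
* **Sample effects** — one multiplicative intensity scale per sample
  (instrument response drift) and one rigid retention-time shift per
  sample (uncontrollable run-to-run jitter; rigid, not per-peak, since
  it models incidental drift rather than chemistry).

Negative values that the noise would produce are clipped at zero, a
documented deviation from pure Gaussian noise that keeps intensities
physical.  All randomness flows from ``(spec.seed, sample_seed)``
through a named NumPy generator, so identical seeds give bitwise
identical cubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from chromacube.io_formats import MSDataset, MassSpectrum


@dataclass(frozen=True)
class SimPeak:
    """Ground-truth description of one simulated chromatographic peak."""

    rt1_center: float
    rt2_center: float
    sigma_rt1: float
    sigma_rt2: float
    amplitude: float
    spectrum: MassSpectrum

    def __post_init__(self) -> None:
        if self.sigma_rt1 < 0 or self.sigma_rt2 < 0:
            raise ValueError("peak sigmas must be non-negative")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if np.any(self.spectrum.intensities < 0):
            raise ValueError("peak spectra must be non-negative")


@dataclass
class SimSpec:
    """Full description of the simulated study conditions."""

    shape: tuple[int, int, int]                 # (R1, R2, M)
    modulation_period: float                    # seconds; sets both RT axes
    mass_start: int                             # first integer m/z bin
    peaks: list[SimPeak] = field(default_factory=list)
    offset: float = 0.0                         # standing-current level
    bleed_slope: float = 0.0                    # per-second ramp along RT1
    noise_sd: float = 0.0                       # white-noise standard deviation
    jitter_sd: tuple[float, float] = (0.0, 0.0) # per-sample RT shift sd (s)
    scale_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        r1, r2, m = self.shape
        if min(r1, r2, m) < 1:
            raise ValueError("shape components must be >= 1")
        if self.modulation_period <= 0:
            raise ValueError("modulation_period must be positive")
        if self.noise_sd < 0 or min(self.jitter_sd) < 0:
            raise ValueError("noise_sd and jitter_sd must be non-negative")
        lo, hi = self.scale_range
        if lo > hi:
            raise ValueError("scale_range must satisfy lo <= hi")

    @property
    def rt1_axis(self) -> np.ndarray:
        return self.modulation_period * np.arange(self.shape[0], dtype=np.float64)

    @property
    def rt2_axis(self) -> np.ndarray:
        return (self.modulation_period / self.shape[1]) * np.arange(
            self.shape[1], dtype=np.float64)

    @property
    def mass_axis(self) -> np.ndarray:
        return self.mass_start + np.arange(self.shape[2], dtype=np.int64)


def _gauss(x: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return (x == 0).astype(np.float64)
    return np.exp(-0.5 * (x / sigma) ** 2)


def _spectrum_on_axis(spec: MassSpectrum, mass_axis: np.ndarray) -> np.ndarray:
    out = np.zeros(mass_axis.size)
    pos = np.searchsorted(mass_axis, spec.masses)
    ok = (pos < mass_axis.size) & (mass_axis[np.minimum(pos, mass_axis.size - 1)]
                                   == spec.masses)
    out[pos[ok]] = spec.intensities[ok]
    return out


def generate_sample(spec: SimSpec, sample_seed: int) -> MSDataset:
    """Simulate one acquisition cube under *spec*.

    Draw order (fixed for reproducibility): intensity scale, RT jitter,
    then the noise field.  The cube is
    ``scale * max(peaks + offset + bleed_slope*rt1 + noise, 0)``.
    """
    rng = np.random.default_rng([int(spec.seed), int(sample_seed)])
    scale = rng.uniform(*spec.scale_range)
    j1 = rng.normal(0.0, spec.jitter_sd[0]) if spec.jitter_sd[0] > 0 else 0.0
    j2 = rng.normal(0.0, spec.jitter_sd[1]) if spec.jitter_sd[1] > 0 else 0.0

    rt1 = spec.rt1_axis
    rt2 = spec.rt2_axis
    mass_axis = spec.mass_axis
    field_ = np.zeros(spec.shape, dtype=np.float64)
    for pk in spec.peaks:
        g1 = _gauss(rt1 - pk.rt1_center - j1, pk.sigma_rt1)
        g2 = _gauss(rt2 - pk.rt2_center - j2, pk.sigma_rt2)
        sp = _spectrum_on_axis(pk.spectrum, mass_axis)
        field_ += pk.amplitude * g1[:, None, None] * g2[None, :, None] * sp[None, None, :]
    field_ += spec.offset + spec.bleed_slope * rt1[:, None, None]
    if spec.noise_sd > 0:
        field_ += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    cube = scale * np.maximum(field_, 0.0)
    return MSDataset(
        sample_id=f"sim-{spec.seed}-{sample_seed}",
        rt1_axis=rt1,
        rt2_axis=rt2,
        mass_axis=mass_axis,
        intensity=cube,
        modulation_period=spec.modulation_period,
        provenance={"generator": "chromacube.synthetic_data",
                    "seed": int(spec.seed), "sample_seed": int(sample_seed)},
    )


def generate_group(
    spec: SimSpec,
    n: int,
    effect: dict[int, float] | None = None,
    group_seed: int = 0,
) -> list[MSDataset]:
    """Simulate *n* samples of one biological group.

    ``effect`` maps peak index -> amplitude fold-change, modelling a
    class with altered metabolite concentrations; an empty map gives a
    group exchangeable with the control conditions.  Per-sample seeds
    are ``group_seed * 100003 + i``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    effect = effect or {}
    for idx, fold in effect.items():
        if not 0 <= idx < len(spec.peaks):
            raise ValueError(f"effect refers to unknown peak index {idx}")
        if fold <= 0:
            raise ValueError("fold-changes must be positive")
    peaks = [
        replace(pk, amplitude=pk.amplitude * effect.get(i, 1.0))
        for i, pk in enumerate(spec.peaks)
    ]
    gspec = replace(spec, peaks=peaks)
    return [generate_sample(gspec, group_seed * 100003 + i) for i in range(n)]


def default_sim_spec(seed: int = 0) -> SimSpec:
    """Reference study conditions used throughout the test-bench.

    A 40 x 30 x 24 cube (RT1 x RT2 x m/z from 50) with a 4 s modulation
    period, six well-separated Gaussian peaks of distinct spectra and
    amplitudes 40-150 (peak widths ~1.5 grid cells per axis), a
    standing-current offset of 2 with a mild bleed ramp, unit white
    noise, quarter-cell retention jitter and +/-10 % per-sample scaling.
    """
    period = 4.0
    spectra = [
        MassSpectrum([50, 55, 63], [100.0, 35.0, 10.0]),
        MassSpectrum([52, 60, 71], [80.0, 100.0, 25.0]),
        MassSpectrum([51, 66, 73], [60.0, 90.0, 40.0]),
        MassSpectrum([56, 57, 68], [100.0, 45.0, 30.0]),
        MassSpectrum([53, 61, 72], [70.0, 100.0, 15.0]),
        MassSpectrum([54, 65, 70], [100.0, 20.0, 55.0]),
    ]
    for s in spectra:
        s.intensities /= s.intensities.sum()
    cell2 = period / 30.0  # RT2 grid spacing; centers sit on grid cells
    centers = [(32.0, 6 * cell2), (60.0, 18 * cell2), (88.0, 9 * cell2),
               (104.0, 22 * cell2), (128.0, 15 * cell2), (144.0, 4 * cell2)]
    amps = [150.0, 90.0, 120.0, 60.0, 40.0, 100.0]
    peaks = [
        SimPeak(c1, c2, sigma_rt1=6.0, sigma_rt2=0.2, amplitude=a, spectrum=sp)
        for (c1, c2), a, sp in zip(centers, amps, spectra)
    ]
    return SimSpec(
        shape=(40, 30, 24),
        modulation_period=period,
        mass_start=50,
        peaks=peaks,
        offset=2.0,
        bleed_slope=0.005,
        noise_sd=1.0,
        jitter_sd=(1.0, 0.033),
        scale_range=(0.9, 1.1),
        seed=seed,
    )


def sim_spec_to_yaml(spec: SimSpec, path) -> None:
    doc = {
        "shape": list(spec.shape),
        "modulation_period": spec.modulation_period,
        "mass_start": spec.mass_start,
        "offset": spec.offset,
        "bleed_slope": spec.bleed_slope,
        "noise_sd": spec.noise_sd,
        "jitter_sd": list(spec.jitter_sd),
        "scale_range": list(spec.scale_range),
        "seed": spec.seed,
        "peaks": [
            {
                "rt1_center": p.rt1_center, "rt2_center": p.rt2_center,
                "sigma_rt1": p.sigma_rt1, "sigma_rt2": p.sigma_rt2,
                "amplitude": p.amplitude,
                "masses": [int(m) for m in p.spectrum.masses],
                "intensities": [float(v) for v in p.spectrum.intensities],
            }
            for p in spec.peaks
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def sim_spec_from_yaml(path) -> SimSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    peaks = [
        SimPeak(p["rt1_center"], p["rt2_center"], p["sigma_rt1"], p["sigma_rt2"],
                p["amplitude"], MassSpectrum(p["masses"], p["intensities"]))
        for p in doc.get("peaks", [])
    ]
    return SimSpec(
        shape=tuple(doc["shape"]),
        modulation_period=doc["modulation_period"],
        mass_start=doc["mass_start"],
        peaks=peaks,
        offset=doc.get("offset", 0.0),
        bleed_slope=doc.get("bleed_slope", 0.0),
        noise_sd=doc.get("noise_sd", 0.0),
        jitter_sd=tuple(doc.get("jitter_sd", (0.0, 0.0))),
        scale_range=tuple(doc.get("scale_range", (1.0, 1.0))),
        seed=doc.get("seed", 0),
    )
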