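"""Class-template volumes and variance-dependent opacity modulation.

For a labelled set of samples (e.g. healthy vs. diseased) the class
template holds the voxelwise mean and *normalized variance* — the raw
population variance divided by its maximum across the volume, so it
lies in [0,1].  During compositing the opacity of each voxel is
attenuated by its variance,

    alpha_out = alpha_in * (1 - k * variance_norm)

with modulation constant ``k`` (default 0.5), so the features *common*
to a class stay opaque while voxels that vary between samples fade.
With the global normalization the attenuation factor is bounded in
``[1 - k, 1]``.

:func:`composite_mass_axis` is a deterministic front-to-back
alpha-compositing projection along the mass axis (viewing the RT1-RT2
plane), a headless stand-in for interactive volume rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chromacube.io_formats import MSDataset, FormatError, _write_omv, _read_omv, _payload_to_cube
from chromacube.colormap import ColorSpec, map_colors, scale_value

DEFAULT_K = 0.5


@dataclass
class VolumeTemplate:
    """Voxelwise mean and normalized variance of a sample class."""

    mean: np.ndarray
    variance_norm: np.ndarray
    n: int
    k: float = DEFAULT_K
    rt1_axis: np.ndarray | None = None
    rt2_axis: np.ndarray | None = None
    mass_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.variance_norm = np.asarray(self.variance_norm, dtype=np.float64)
        if self.mean.shape != self.variance_norm.shape:
            raise ValueError("mean and variance_norm must share shape")
        if np.any(self.variance_norm < 0) or np.any(self.variance_norm > 1):
            raise ValueError("variance_norm must lie in [0,1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n == 1 and np.any(self.variance_norm != 0):
            raise ValueError("a single-sample template has zero variance")
        if self.k < 0:
            raise ValueError("k must be non-negative")


def class_template(datasets: list[MSDataset], k: float = DEFAULT_K) -> VolumeTemplate:
    """Voxelwise mean and globally-normalized population variance.

    All datasets must share axes.  The raw voxel variance is divided by
    its maximum over the volume (0 where the maximum is 0), yielding
    ``variance_norm`` in [0,1].
    """
    if not datasets:
        raise ValueError("class_template requires at least one dataset")
    first = datasets[0]
    for d in datasets[1:]:
        if (not np.array_equal(d.rt1_axis, first.rt1_axis)
                or not np.array_equal(d.rt2_axis, first.rt2_axis)
                or not np.array_equal(d.mass_axis, first.mass_axis)):
            raise ValueError("datasets must share axes")
    stack = np.stack([d.intensity.astype(np.float64) for d in datasets])
    mean = stack.mean(axis=0)
    if stack.shape[0] == 1:
        var_norm = np.zeros_like(mean)
    else:
        var = stack.var(axis=0)  # population divisor
        vmax = var.max()
        var_norm = var / vmax if vmax > 0 else np.zeros_like(var)
    return VolumeTemplate(
        mean=mean, variance_norm=var_norm, n=stack.shape[0], k=k,
        rt1_axis=first.rt1_axis.copy(), rt2_axis=first.rt2_axis.copy(),
        mass_axis=first.mass_axis.copy(),
    )


def modulate_opacity(alpha_in: float, variance_norm: float, k: float = DEFAULT_K):
    """Attenuate opacity by normalized variance:
    ``alpha_out = alpha_in * (1 - k * variance_norm)``, clamped to [0,1].

    Accepts scalars or arrays.
    """
    if np.any(np.asarray(k) < 0):
        raise ValueError("k must be non-negative")
    out = np.clip(np.asarray(alpha_in, dtype=np.float64)
                  * (1.0 - k * np.asarray(variance_norm, dtype=np.float64)), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def composite_mass_axis(
    t: VolumeTemplate,
    spec: ColorSpec,
    base_alpha_scale: float = 1.0,
    background: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Front-to-back alpha compositing along the mass axis.

    Per RT cell the voxels are traversed from the lowest mass bin
    (front).  Voxel colour is the colour-mapped mean; voxel opacity is
    ``modulate_opacity(clamp(scale_value(mean) * base_alpha_scale),
    variance_norm, k)``.  Standard over-operator accumulation with
    early exit once accumulated alpha reaches 0.999; the remainder is
    filled with the background colour.  Returns (R1, R2, 3) uint8 cell
    colours (axis orientation left to the caller / renderer).
    """
    if base_alpha_scale <= 0:
        raise ValueError("base_alpha_scale must be positive")
    r1, r2, m = t.mean.shape
    color = map_colors(t.mean, spec).astype(np.float64)  # (r1, r2, m, 3)
    alpha = modulate_opacity(
        np.clip(scale_value(t.mean, spec) * base_alpha_scale, 0.0, 1.0),
        t.variance_norm,
        t.k,
    )
    acc_c = np.zeros((r1, r2, 3), dtype=np.float64)
    acc_a = np.zeros((r1, r2), dtype=np.float64)
    for mi in range(m):
        live = acc_a < 0.999
        if not live.any():
            break
        w = np.where(live, (1.0 - acc_a) * alpha[:, :, mi], 0.0)
        acc_c += w[..., None] * color[:, :, mi, :]
        acc_a += w
    acc_c += (1.0 - acc_a)[..., None] * np.asarray(background, dtype=np.float64)
    return np.rint(np.clip(acc_c, 0, 255)).astype(np.uint8)


_TEMPLATE_KIND = "chromacube-template"


def write_template(t: VolumeTemplate, path) -> str:
    """Store a template in the OMV container: JSON header (with n, k and
    axes) followed by the mean cube then the variance_norm cube."""
    header = {
        "kind": _TEMPLATE_KIND,
        "n": int(t.n),
        "k": float(t.k),
        "shape": list(t.mean.shape),
        "rt1_axis": None if t.rt1_axis is None else [float(v) for v in t.rt1_axis],
        "rt2_axis": None if t.rt2_axis is None else [float(v) for v in t.rt2_axis],
        "mass_axis": None if t.mass_axis is None else [int(v) for v in t.mass_axis],
    }
    _write_omv(path, header, np.asarray(t.mean, dtype="<f4"),
               np.asarray(t.variance_norm, dtype="<f4"))
    import os
    return os.fspath(path)


def read_template(path) -> VolumeTemplate:
    header, payload = _read_omv(path)
    if header.get("kind") != _TEMPLATE_KIND:
        raise FormatError(f"not a template container: kind={header.get('kind')!r}")
    shape = tuple(header["shape"])
    both = _payload_to_cube(payload, (2,) + shape, path)
    ax = lambda key, dt: None if header.get(key) is None else np.asarray(header[key], dtype=dt)
    return VolumeTemplate(
        mean=both[0].astype(np.float64),
        variance_norm=np.clip(both[1].astype(np.float64), 0.0, 1.0),
        n=int(header["n"]),
        k=float(header["k"]),
        rt1_axis=ax("rt1_axis", np.float64),
        rt2_axis=ax("rt2_axis", np.float64),
        mass_axis=ax("mass_axis", np.int64),
    )
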