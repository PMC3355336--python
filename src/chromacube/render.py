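"""Static raster output: 2-D TIC images, shaded height fields, spectrum plots.

All renderers are deterministic pure functions from data + settings to an
RGB pixel array; identical inputs give byte-identical PNGs.  The height
field replaces an interactive perspective camera with an orthographic
top-down projection so that output is testable, while keeping the
photometric model: a single light along +z with ambient, diffuse and
specular components,

    brightness = ambient + diffuse * max(n_z, 0) + specular * max(n_z, 0)^shininess

(the half vector coincides with +z for a top-down view).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from chromacube.io_formats import MassSpectrum
from chromacube.tic_stats import TICGrid
from chromacube.colormap import ColorSpec, map_colors

#: Documented default material (arbitrary constants, not measured values).
DEFAULT_AMBIENT = 0.2
DEFAULT_DIFFUSE = 0.6
DEFAULT_SPECULAR = 0.4
DEFAULT_SHININESS = 16.0


@dataclass(frozen=True)
class Material:
    """Phong-style surface properties for the height-field shader."""

    ambient: float = DEFAULT_AMBIENT
    diffuse: float = DEFAULT_DIFFUSE
    specular: float = DEFAULT_SPECULAR
    shininess: float = DEFAULT_SHININESS

    def __post_init__(self) -> None:
        for name in ("ambient", "diffuse", "specular"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.shininess <= 0:
            raise ValueError("shininess must be positive")


def _grid_to_image(rgb_cells: np.ndarray, scale: int) -> np.ndarray:
    """(R1, R2, 3) cell colours -> (H, W, 3) image, RT1 on x, RT2 on y,
    origin lower-left."""
    img = np.transpose(rgb_cells, (1, 0, 2))[::-1]  # rows = RT2 descending
    if scale > 1:
        img = np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
    return np.ascontiguousarray(img)


def render_tic_image(tic: TICGrid, spec: ColorSpec, scale: int = 1) -> np.ndarray:
    """Map every TIC cell through the colour spec; one pixel per cell
    (optionally integer-upscaled).  No blending or interpolation."""
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    rgb = map_colors(tic.values, spec)
    return _grid_to_image(rgb, scale)


def shade_vertex(normal, material: Material, view_cos: float = 1.0) -> float:
    """Brightness of a vertex under the top-down light.

    ``normal`` must be unit length (tolerance 1e-6).  Returns
    ``ambient + diffuse*max(n_z,0) + specular*max(n_z,0)^shininess``,
    in ``[0, 1 + specular]``.  ``view_cos`` is accepted for interface
    completeness; for the orthographic top-down camera the view and
    half vectors coincide with the light, so it does not enter.
    """
    n = np.asarray(normal, dtype=np.float64)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError(f"normal must be unit length, |n|={np.linalg.norm(n)}")
    nz = max(float(n[2]), 0.0)
    return material.ambient + material.diffuse * nz + material.specular * nz ** material.shininess


def _vertex_normals(z: np.ndarray) -> np.ndarray:
    """Per-vertex normals of the height field z(i,j), averaged from the
    four adjacent axis-aligned face normals (central differences at
    interior vertices, one-sided at edges)."""
    dzdx = np.gradient(z, axis=0)
    dzdy = np.gradient(z, axis=1)
    n = np.stack([-dzdx, -dzdy, np.ones_like(z)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return n


def render_height_field(
    tic: TICGrid,
    spec: ColorSpec,
    mode: str = "color",
    height_scale: str = "linear",
    material: Material = Material(),
    scale: int = 1,
) -> np.ndarray:
    """Shaded orthographic top-down view of the TIC as a height field.

    Intensity becomes the z coordinate, scaled linearly or
    logarithmically (log1p, so zero stays at height zero), then
    normalized so the tallest peak has unit height over a footprint of
    unit cell spacing.  ``color`` mode multiplies the colour-mapped
    value by the shade; ``high_contrast`` renders the shade alone as
    grayscale, which makes small peaks and background texture visible
    independently of their intensity colour.
    """
    if mode not in ("color", "high_contrast"):
        raise ValueError(f"unknown mode {mode!r}")
    if height_scale not in ("linear", "log"):
        raise ValueError(f"unknown height_scale {height_scale!r}")
    v = tic.values
    z = np.log1p(np.maximum(v, 0.0)) if height_scale == "log" else v.astype(np.float64)
    zmax = z.max()
    if zmax > 0:
        # aspect: peak height ~ a few cell spacings, like the on-screen view
        z = z / zmax * 0.25 * max(v.shape)
    normals = _vertex_normals(z)
    nz = np.maximum(normals[..., 2], 0.0)
    shade = material.ambient + material.diffuse * nz + material.specular * nz ** material.shininess
    if mode == "high_contrast":
        gray = np.rint(np.clip(shade / (1.0 + material.specular), 0, 1) * 255).astype(np.uint8)
        rgb = np.stack([gray] * 3, axis=-1)
    else:
        base = map_colors(v, spec).astype(np.float64)
        rgb = np.rint(np.clip(base * np.clip(shade, 0, 1)[..., None], 0, 255)).astype(np.uint8)
    return _grid_to_image(rgb, scale)


def render_spectrum(
    s: MassSpectrum,
    style: str = "bar",
    signed: bool = False,
    height: int = 200,
    bar_width: int = 3,
) -> np.ndarray:
    """Plot a mass spectrum as bars or a connected line.

    Unsigned spectra sit on a baseline at the bottom; signed spectra
    (difference spectra) put the zero baseline at mid-height with
    positive bars rising and negative bars falling.  Bar heights are
    proportional to intensity / max |intensity|.
    """
    if style not in ("bar", "line"):
        raise ValueError(f"unknown style {style!r}")
    if s.masses.size == 0:
        raise ValueError("cannot render an empty spectrum")
    n = s.masses.size
    width = n * (bar_width + 1) + 1
    img = np.full((height, width, 3), 255, dtype=np.uint8)
    peak = float(np.max(np.abs(s.intensities)))
    if signed:
        baseline = height // 2
        usable = baseline - 1
    else:
        baseline = 0
        usable = height - 2
    img[height - 1 - baseline, :, :] = 0  # baseline row (origin lower-left)

    pos_color = np.array([200, 0, 0], dtype=np.uint8)
    neg_color = np.array([0, 150, 0], dtype=np.uint8)
    uns_color = np.array([0, 0, 180], dtype=np.uint8)

    def col_x(k: int) -> int:
        return 1 + k * (bar_width + 1)

    tops = np.zeros(n, dtype=int)
    for k, inten in enumerate(s.intensities):
        frac = 0.0 if peak == 0 else float(inten) / peak
        tops[k] = int(round(frac * usable))

    if style == "bar":
        for k in range(n):
            h = tops[k]
            x0 = col_x(k)
            color = uns_color if not signed else (pos_color if h > 0 else neg_color)
            if h > 0:
                rows = slice(height - 1 - (baseline + h), height - 1 - baseline)
            elif h < 0:
                rows = slice(height - baseline, height - baseline - h)
            else:
                continue
            img[rows, x0:x0 + bar_width] = color
    else:
        color = uns_color if not signed else pos_color
        xs = [col_x(k) + bar_width // 2 for k in range(n)]
        ys = [height - 1 - (baseline + tops[k]) for k in range(n)]
        for k in range(n - 1):
            _draw_line(img, xs[k], ys[k], xs[k + 1], ys[k + 1], color)
    return img


def _draw_line(img, x0, y0, x1, y1, color) -> None:
    """Bresenham line, integer endpoints."""
    dx = abs(x1 - x0)
    dy = -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    x, y = x0, y0
    while True:
        if 0 <= y < img.shape[0] and 0 <= x < img.shape[1]:
            img[y, x] = color
        if x == x1 and y == y1:
            break
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x += sx
        if e2 <= dx:
            err += dx
            y += sy


def save_png(img: np.ndarray, path) -> None:
    """Write an (H, W, 3) uint8 array as an 8-bit RGB PNG (deterministic)."""
    Image.fromarray(np.ascontiguousarray(img), mode="RGB").save(path, format="PNG")
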