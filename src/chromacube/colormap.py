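"""Value-to-colour mapping for TIC, difference and standard-deviation views.

Two schemes are provided.  The *continuous* scheme evaluates three
piecewise-linear curves — hue, saturation, brightness — at the
normalized input and converts HSV to RGB (standard hexcone, hue in
degrees).  Signed modes (difference, stddev) use separate curve sets
for positive and negative values: by default pure red (hue 0) for
positive and pure green (hue 120) for negative, with exactly zero
mapped to a neutral colour (black by default, matching a near-black
chromatogram background).  The *discrete* scheme bins values against a
list of (upper_edge, RGB) pairs.

Intensities span several orders of magnitude, so the default scale is
log1p: ``log(1 + x)`` compresses large values without a singularity at
zero-valued cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

Curve = list[tuple[float, float]]  # (position in [0,1], value) control points


def _default_pos_curves() -> tuple[Curve, Curve, Curve]:
    # hue fixed at red, brightness ramps with magnitude
    return ([(0.0, 0.0), (1.0, 0.0)], [(0.0, 1.0), (1.0, 1.0)], [(0.0, 0.0), (1.0, 1.0)])


def _default_neg_curves() -> tuple[Curve, Curve, Curve]:
    # hue fixed at green
    return ([(0.0, 120.0), (1.0, 120.0)], [(0.0, 1.0), (1.0, 1.0)], [(0.0, 0.0), (1.0, 1.0)])


def _default_intensity_curves() -> tuple[Curve, Curve, Curve]:
    # blue -> red sweep with rising brightness
    return ([(0.0, 240.0), (1.0, 0.0)], [(0.0, 1.0), (1.0, 1.0)], [(0.0, 0.15), (1.0, 1.0)])


@dataclass
class ColorSpec:
    """Declarative description of a value-to-colour mapping.

    ``mode`` selects the semantics: ``intensity`` is unsigned;
    ``difference`` and ``stddev`` are signed (bipolar).  ``domain`` is
    the (vmin, vmax) input range; for signed modes it applies to |v|.
    """

    mode: str = "intensity"            # intensity | difference | stddev
    scheme: str = "continuous"         # continuous | discrete
    pos_curves: tuple[Curve, Curve, Curve] = field(default_factory=_default_intensity_curves)
    neg_curves: tuple[Curve, Curve, Curve] = field(default_factory=_default_neg_curves)
    bins: list[tuple[float, tuple[int, int, int]]] | None = None
    scale: str = "log1p"               # linear | log1p
    domain: tuple[float, float] = (0.0, 1.0)
    neutral_rgb: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.mode not in ("intensity", "difference", "stddev"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scheme not in ("continuous", "discrete"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scale not in ("linear", "log1p"):
            raise ValueError(f"unknown scale {self.scale!r}")
        vmin, vmax = self.domain
        if not vmax > vmin:
            raise ValueError("domain vmax must exceed vmin")
        for curves in (self.pos_curves, self.neg_curves):
            for curve in curves:
                pos = [p for p, _ in curve]
                if pos != sorted(pos):
                    raise ValueError("curve control points must be sorted by position")
        if self.bins is not None:
            edges = [e for e, _ in self.bins]
            if edges != sorted(set(edges)):
                raise ValueError("bin edges must be strictly increasing")

    @property
    def signed(self) -> bool:
        return self.mode in ("difference", "stddev")


def default_spec(mode: str = "intensity", domain: tuple[float, float] = (0.0, 1.0),
                 scale: str = "log1p") -> ColorSpec:
    """Factory for the documented default mappings per mode."""
    if mode == "intensity":
        return ColorSpec(mode=mode, domain=domain, scale=scale,
                         pos_curves=_default_intensity_curves())
    return ColorSpec(mode=mode, domain=domain, scale=scale,
                     pos_curves=_default_pos_curves(),
                     neg_curves=_default_neg_curves())


def scale_value(v, spec: ColorSpec):
    """Normalize *v* into [0,1] per the spec's scale and domain.

    Signed modes normalize |v|; the caller carries the sign.  The log1p
    scale is ``log(1 + max(v - vmin, 0)) / log(1 + vmax - vmin)``,
    devoting more of the output range to small values.  Accepts scalars
    or arrays.
    """
    vmin, vmax = spec.domain
    v = np.abs(np.asarray(v, dtype=np.float64)) if spec.signed else np.asarray(v, dtype=np.float64)
    if spec.scale == "linear":
        t = (v - vmin) / (vmax - vmin)
    else:
        t = np.log1p(np.maximum(v - vmin, 0.0)) / np.log1p(vmax - vmin)
    t = np.clip(t, 0.0, 1.0)
    return float(t) if t.ndim == 0 else t


def _eval_curve(curve: Curve, t):
    xs = np.array([p for p, _ in curve])
    ys = np.array([v for _, v in curve])
    return np.interp(t, xs, ys)


def _hsv_to_rgb_array(h, s, v) -> np.ndarray:
    """Standard hexcone HSV->RGB; h in degrees, s and v in [0,1].

    Vectorized; returns uint8 with shape ``h.shape + (3,)``.
    """
    h = np.asarray(h, dtype=np.float64) % 360.0
    s = np.clip(np.asarray(s, dtype=np.float64), 0.0, 1.0)
    v = np.clip(np.asarray(v, dtype=np.float64), 0.0, 1.0)
    hp = h / 60.0
    i = np.floor(hp).astype(int) % 6
    f = hp - np.floor(hp)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    rgb = np.stack([r, g, b], axis=-1)
    return np.rint(rgb * 255.0).astype(np.uint8)


def _hsv_to_rgb255(h, s, v) -> tuple[int, int, int]:
    return tuple(int(c) for c in _hsv_to_rgb_array(h, s, v))


def map_color(v: float, spec: ColorSpec) -> tuple[int, int, int]:
    """Map a single value to an RGB triple in [0,255]^3 (pure function)."""
    if spec.scheme == "discrete":
        if not spec.bins:
            raise ValueError("discrete scheme requires non-empty bins")
        for edge, rgb in spec.bins:
            if edge >= v:
                return tuple(rgb)
        return tuple(spec.bins[-1][1])
    if spec.signed:
        if v == 0:
            return spec.neutral_rgb
        curves = spec.pos_curves if v > 0 else spec.neg_curves
    else:
        curves = spec.pos_curves
    t = scale_value(v, spec)
    h = float(_eval_curve(curves[0], t))
    s = float(_eval_curve(curves[1], t))
    b = float(_eval_curve(curves[2], t))
    return _hsv_to_rgb255(h, s, b)


def map_colors(values: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Vectorized :func:`map_color` over an array; returns uint8 (...,3).

    Produces exactly the per-value output of :func:`map_color`.
    """
    values = np.asarray(values, dtype=np.float64)
    out = np.empty(values.shape + (3,), dtype=np.uint8)
    if spec.scheme == "discrete":
        if not spec.bins:
            raise ValueError("discrete scheme requires non-empty bins")
        edges = np.array([e for e, _ in spec.bins])
        colors = np.array([rgb for _, rgb in spec.bins], dtype=np.uint8)
        idx = np.searchsorted(edges, values, side="left")
        idx = np.minimum(idx, len(spec.bins) - 1)
        return colors[idx]
    t = scale_value(values, spec)
    t = np.atleast_1d(np.asarray(t))

    def hsv_block(curves, tt):
        return _hsv_to_rgb_array(
            _eval_curve(curves[0], tt),
            _eval_curve(curves[1], tt),
            _eval_curve(curves[2], tt),
        )

    flat_v = values.reshape(-1)
    flat_t = np.asarray(t).reshape(-1)
    res = np.empty((flat_v.size, 3), dtype=np.uint8)
    if spec.signed:
        pos = flat_v > 0
        neg = flat_v < 0
        zer = flat_v == 0
        if pos.any():
            res[pos] = hsv_block(spec.pos_curves, flat_t[pos])
        if neg.any():
            res[neg] = hsv_block(spec.neg_curves, flat_t[neg])
        if zer.any():
            res[zer] = np.array(spec.neutral_rgb, dtype=np.uint8)
    else:
        res[:] = hsv_block(spec.pos_curves, flat_t)
    out[...] = res.reshape(values.shape + (3,))
    return out


def auto_bins(values, n_bins: int) -> list[tuple[float, tuple[int, int, int]]]:
    """Automatically generate a discrete binned mapping from the data.

    Edges sit at equal quantiles of the log1p-scaled values; since
    quantiles commute with the monotone transform they are computed on
    (and reported in) raw units.  Colours sweep evenly spaced hues from
    blue (240 deg) down to red (0 deg) at full saturation and
    brightness.
    """
    values = np.asarray(list(values), dtype=np.float64)
    if values.size == 0:
        raise ValueError("auto_bins requires a non-empty value collection")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if np.ptp(values) == 0:
        warnings.warn("constant input: returning a single degenerate bin")
        return [(float(values[0]), _hsv_to_rgb255(240.0, 1.0, 1.0))]
    qs = np.linspace(0, 1, n_bins + 1)[1:]
    edges = np.quantile(values, qs)
    # collapse duplicate edges from heavily tied data
    uniq = []
    for e in edges:
        if not uniq or e > uniq[-1]:
            uniq.append(float(e))
    hues = np.linspace(240.0, 0.0, len(uniq))
    return [(e, _hsv_to_rgb255(h, 1.0, 1.0)) for e, h in zip(uniq, hues)]


def spec_to_yaml(spec: ColorSpec, path) -> None:
    doc = {
        "mode": spec.mode,
        "scheme": spec.scheme,
        "scale": spec.scale,
        "domain": [float(spec.domain[0]), float(spec.domain[1])],
        "neutral_rgb": list(spec.neutral_rgb),
        "pos_curves": [[[float(p), float(v)] for p, v in c] for c in spec.pos_curves],
        "neg_curves": [[[float(p), float(v)] for p, v in c] for c in spec.neg_curves],
        "bins": None if spec.bins is None else
                [[float(e), "#%02X%02X%02X" % tuple(rgb)] for e, rgb in spec.bins],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def spec_from_yaml(path) -> ColorSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    bins = doc.get("bins")
    if bins is not None:
        bins = [(float(e), tuple(int(h.lstrip("#")[i:i + 2], 16) for i in (0, 2, 4)))
                for e, h in bins]
    return ColorSpec(
        mode=doc["mode"],
        scheme=doc["scheme"],
        scale=doc["scale"],
        domain=tuple(doc["domain"]),
        neutral_rgb=tuple(doc.get("neutral_rgb", (0, 0, 0))),
        pos_curves=tuple([tuple(map(float, p)) for p in c] for c in doc["pos_curves"]),
        neg_curves=tuple([tuple(map(float, p)) for p in c] for c in doc["neg_curves"]),
        bins=bins,
    )
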