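"""Peak-candidate model: detection, threshold/region filtering, 2-D KDE.

Upstream statistical biomarker detection typically produces thousands
of candidate peaks, each carrying a weight (magnitude proxy), an
uncertainty (variability proxy) and two generic significance-like
scores used for filtering (smaller = stronger evidence; the comparison
direction is a documented assumption, since the scores originate
outside this package).  A simple strict-local-maximum detector is
included so the synthetic pipeline closes without external peak lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from chromacube.io_formats import MassSpectrum
from chromacube.tic_stats import TICGrid


@dataclass
class Peak:
    """One candidate: location in seconds, magnitude/variability proxies,
    two filterable scores and an optional characteristic spectrum."""

    rt1: float
    rt2: float
    weight: float
    uncertainty: float = 0.0
    score1: float = 0.0
    score2: float = 0.0
    spectrum: MassSpectrum | None = None

    def __post_init__(self) -> None:
        if self.weight < 0 or self.uncertainty < 0:
            raise ValueError("weight and uncertainty must be non-negative")


@dataclass
class PeakTable:
    peaks: list[Peak] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            [(p.rt1, p.rt2, p.weight, p.uncertainty, p.score1, p.score2)
             for p in self.peaks],
            columns=["rt1", "rt2", "weight", "uncertainty", "score1", "score2"],
        )
        df.to_csv(path, index=False, float_format="%.17g")  # round-trips doubles

    @staticmethod
    def from_csv(path, provenance: str = "") -> "PeakTable":
        df = pd.read_csv(path, float_precision="round_trip")
        peaks = [Peak(r.rt1, r.rt2, r.weight, r.uncertainty, r.score1, r.score2)
                 for r in df.itertuples()]
        return PeakTable(peaks, provenance or str(path))


def detect_peaks(tic: TICGrid, min_intensity: float = 0.0,
                 neighborhood: int = 3) -> PeakTable:
    """Strict local maxima of a TIC grid.

    A cell is a peak iff it is strictly greater than every other cell in
    its ``neighborhood x neighborhood`` window (truncated at the grid
    edges) and at least ``min_intensity``.  Plateaus (ties with a
    neighbour) are not peaks.  Weight is the cell value; uncertainty 0.
    """
    if neighborhood % 2 == 0 or neighborhood < 3:
        raise ValueError("neighborhood must be an odd integer >= 3")
    v = tic.values
    footprint = np.ones((neighborhood, neighborhood), dtype=bool)
    footprint[neighborhood // 2, neighborhood // 2] = False
    # -inf padding truncates windows at the edges
    neigh_max = maximum_filter(v, footprint=footprint, mode="constant", cval=-np.inf)
    is_peak = (v > neigh_max) & (v >= min_intensity)
    peaks = [
        Peak(rt1=float(tic.rt1_axis[i]), rt2=float(tic.rt2_axis[j]),
             weight=float(v[i, j]))
        for i, j in zip(*np.nonzero(is_peak))
    ]
    return PeakTable(peaks, provenance=f"detect_peaks(min_intensity={min_intensity})")


def filter_peaks(t: PeakTable, thr1: float, thr2: float) -> PeakTable:
    """Keep peaks with ``score1 <= thr1`` and ``score2 <= thr2``,
    preserving order.  Scores are significance-like: smaller = stronger."""
    kept = [p for p in t.peaks if p.score1 <= thr1 and p.score2 <= thr2]
    return PeakTable(kept, provenance=t.provenance)


def score_region_filter(
    t: PeakTable,
    s1_range: tuple[float, float],
    s2_range: tuple[float, float],
) -> PeakTable:
    """Keep peaks whose (score1, score2) lies in the half-open rectangle
    ``s1_range x s2_range`` of the score plane."""
    for name, (lo, hi) in (("s1_range", s1_range), ("s2_range", s2_range)):
        if not hi > lo:
            raise ValueError(f"{name} [{lo},{hi}) is empty")
    kept = [p for p in t.peaks
            if s1_range[0] <= p.score1 < s1_range[1]
            and s2_range[0] <= p.score2 < s2_range[1]]
    return PeakTable(kept, provenance=t.provenance)


def _scott_bandwidth(x: np.ndarray, w: np.ndarray) -> float:
    """Scott's rule per axis for weighted points (d=2): sigma * n_eff^(-1/6)."""
    n_eff = w.sum() ** 2 / np.sum(w ** 2)
    mu = np.average(x, weights=w)
    sd = np.sqrt(np.average((x - mu) ** 2, weights=w))
    h = sd * n_eff ** (-1.0 / 6.0)
    return float(h)


def kde2d(
    t: PeakTable,
    bandwidth: tuple[float, float] | None = None,
    grid: tuple[int, int] = (128, 128),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weight-weighted Gaussian kernel density over peak (RT1, RT2).

    Uses a diagonal product kernel with per-axis bandwidths, Scott's
    rule by default (falling back to 1 s on a degenerate axis).  The
    evaluation grid spans the data range padded by five bandwidths so
    that the trapezoid integral of the returned density is 1 within
    1e-3.

    Returns ``(density, rt1_centers, rt2_centers)`` with density shape
    ``grid``.
    """
    if len(t) == 0:
        raise ValueError("kde2d requires at least one peak")
    x = np.array([p.rt1 for p in t.peaks])
    y = np.array([p.rt2 for p in t.peaks])
    w = np.array([p.weight for p in t.peaks], dtype=np.float64)
    if w.sum() == 0:
        w = np.ones_like(w)  # all-zero weights: fall back to unweighted
    w = w / w.sum()
    if bandwidth is None:
        hx = _scott_bandwidth(x, w)
        hy = _scott_bandwidth(y, w)
        hx = hx if hx > 0 else 1.0
        hy = hy if hy > 0 else 1.0
    else:
        hx, hy = bandwidth
        if hx <= 0 or hy <= 0:
            raise ValueError("bandwidths must be positive")
    gx = np.linspace(x.min() - 5 * hx, x.max() + 5 * hx, grid[0])
    gy = np.linspace(y.min() - 5 * hy, y.max() + 5 * hy, grid[1])
    # outer product of per-axis Gaussians, summed over points
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    density = np.einsum("ip,jp,p->ij", kx, ky, w)
    return density, gx, gy
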