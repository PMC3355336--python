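"""TIC grids and comparative group statistics.

The total ion count (TIC) at each (RT1, RT2) cell is the sum of the
mass spectrum's intensities at that cell, optionally restricted to a
mass filter.  Group comparison follows the convention that the group
standard deviation uses the *population* divisor n:

    sigma_A(c) = sqrt( (1/n_A) * sum_i (x_i(c) - mu_A(c))^2 )

and the per-cell z-value of a sample grid b against the group is

    z(c) = (mu_A(c) - b(c)) / sigma_A(c)

Note the sign: z is *positive* where the sample lies below the group
mean.  This orientation is what the bipolar colour mapping assumes.
Samples are expected to be pre-normalized; no normalization is applied
here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from chromacube.io_formats import MSDataset

DEFAULT_Z_CLIP = 10.0


@dataclass
class TICGrid:
    """2-D grid of summed intensities over the mass axis."""

    rt1_axis: np.ndarray
    rt2_axis: np.ndarray
    values: np.ndarray
    mass_filter: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.rt1_axis = np.asarray(self.rt1_axis, dtype=np.float64)
        self.rt2_axis = np.asarray(self.rt2_axis, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.rt1_axis.size, self.rt2_axis.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.rt1_axis.size}, {self.rt2_axis.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TIC values must be finite")
        if self.mass_filter is not None:
            self.mass_filter = tuple(sorted(int(m) for m in self.mass_filter))

    def same_axes(self, other: "TICGrid") -> bool:
        return np.array_equal(self.rt1_axis, other.rt1_axis) and np.array_equal(
            self.rt2_axis, other.rt2_axis
        )


@dataclass
class GroupStats:
    """Per-cell mean and standard-deviation TIC of a named sample group."""

    group_name: str
    n: int
    mu: TICGrid
    sigma: TICGrid

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group must contain at least one sample")
        if not self.mu.same_axes(self.sigma):
            raise ValueError("mu and sigma must share axes")
        if np.any(self.sigma.values < 0):
            raise ValueError("sigma must be non-negative")


@dataclass
class ZMap:
    """Grid of z-values with the cap applied where sigma was zero."""

    rt1_axis: np.ndarray
    rt2_axis: np.ndarray
    values: np.ndarray
    z_clip: float = DEFAULT_Z_CLIP


def _check_axes(a: TICGrid, b: TICGrid) -> None:
    if not a.same_axes(b):
        raise ValueError("TIC grids have mismatched axes")


def compute_tic(ds: MSDataset, masses=None) -> TICGrid:
    """Sum the cube over the mass axis, optionally over selected masses.

    Parameters
    ----------
    ds
        The intensity cube.
    masses
        Optional collection of integer m/z values to include (a mass
        filter).  Every value must be present on ``ds.mass_axis``.
    """
    if masses is None:
        values = ds.intensity.astype(np.float64).sum(axis=2)
        mass_filter = None
    else:
        wanted = sorted({int(m) for m in masses})
        if not wanted:
            raise ValueError("mass filter must select at least one mass")
        pos = np.searchsorted(ds.mass_axis, wanted)
        bad = [m for m, p in zip(wanted, pos)
               if p >= ds.mass_axis.size or ds.mass_axis[p] != m]
        if bad:
            raise ValueError(f"masses not on the axis: {bad}")
        values = ds.intensity[:, :, pos].astype(np.float64).sum(axis=2)
        mass_filter = tuple(wanted)
    return TICGrid(ds.rt1_axis.copy(), ds.rt2_axis.copy(), values, mass_filter)


def group_stats(tics: list[TICGrid], group_name: str, ddof: int = 0) -> GroupStats:
    """Elementwise mean and standard deviation of a sample group.

    The default ``ddof=0`` is the population form (divide by n); pass
    ``ddof=1`` for the sample estimator.
    """
    if not tics:
        raise ValueError("group_stats requires at least one TIC grid")
    first = tics[0]
    for t in tics[1:]:
        _check_axes(first, t)
        if t.mass_filter != first.mass_filter:
            raise ValueError("all grids in a group must share the same mass filter")
    stack = np.stack([t.values for t in tics])
    n = stack.shape[0]
    mu = stack.mean(axis=0)
    if n == 1:
        sigma = np.zeros_like(mu)
    else:
        sigma = stack.std(axis=0, ddof=ddof)
    mk = lambda v: TICGrid(first.rt1_axis, first.rt2_axis, v, first.mass_filter)
    return GroupStats(group_name=group_name, n=n, mu=mk(mu), sigma=mk(sigma))


def z_map(stats: GroupStats, sample: TICGrid, z_clip: float = DEFAULT_Z_CLIP) -> ZMap:
    """Per-cell z-values of *sample* against the group.

    ``z = (mu_A - b) / sigma_A``; where ``sigma_A`` is zero the z-value
    is 0 if the sample matches the mean and ``sign(mu_A - b) * z_clip``
    otherwise, keeping the map bounded and renderable.
    """
    if z_clip <= 0:
        raise ValueError("z_clip must be positive")
    _check_axes(stats.mu, sample)
    mu = stats.mu.values
    sigma = stats.sigma.values
    b = sample.values
    diff = mu - b
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, diff / np.where(sigma > 0, sigma, 1.0),
                     np.sign(diff) * z_clip)
    return ZMap(sample.rt1_axis, sample.rt2_axis, z, z_clip)


def normalize_total(grid: TICGrid) -> TICGrid:
    """Multiplicative total-intensity normalization of a TIC grid.

    Rescales so the mean cell value is 1, removing per-sample detector
    response differences.  Group statistics assume samples were
    normalized like this (or equivalently) beforehand; the statistics
    functions themselves never normalize.
    """
    total = grid.values.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero TIC grid")
    return TICGrid(grid.rt1_axis, grid.rt2_axis,
                   grid.values / total * grid.values.size, grid.mass_filter)


def diff_grid(a: TICGrid, b: TICGrid) -> TICGrid:
    """Signed elementwise difference ``a - b`` of two TIC grids."""
    _check_axes(a, b)
    return TICGrid(a.rt1_axis, a.rt2_axis, a.values - b.values, a.mass_filter)


def tic_to_csv(grid: TICGrid, path) -> None:
    """Write a TIC grid as CSV: header row of RT2 values, first column RT1."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rt1\\rt2"] + [repr(float(v)) for v in grid.rt2_axis])
        for i, rt1 in enumerate(grid.rt1_axis):
            w.writerow([repr(float(rt1))] + [repr(float(v)) for v in grid.values[i]])


def tic_from_csv(path) -> TICGrid:
    """Read a TIC grid written by :func:`tic_to_csv`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rt2 = np.array([float(v) for v in rows[0][1:]])
    rt1 = np.array([float(r[0]) for r in rows[1:]])
    values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return TICGrid(rt1, rt2, values)
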