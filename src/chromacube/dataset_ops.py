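"""Structural operations on cubes: cropping, regions, spectrum extraction.

Regions are index-based half-open intervals ``[lo, hi)`` on each of the
three cube axes.  Users of the CLI give regions in physical units
(seconds and m/z); :func:`region_from_physical` converts by nearest axis
value with ties broken toward the lower index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from chromacube.io_formats import MSDataset, MassSpectrum


@dataclass(frozen=True)
class Region:
    """Half-open index intervals selecting a sub-block of a cube."""

    rt1_range: tuple[int, int]
    rt2_range: tuple[int, int]
    mass_range: tuple[int, int]

    def validate(self, ds: MSDataset) -> None:
        bounds = ds.shape
        for name, (lo, hi), n in zip(
            ("rt1_range", "rt2_range", "mass_range"),
            (self.rt1_range, self.rt2_range, self.mass_range),
            bounds,
        ):
            if not (0 <= lo < hi <= n):
                raise ValueError(
                    f"{name} [{lo},{hi}) is empty or out of bounds for axis size {n}"
                )

    @staticmethod
    def full(ds: MSDataset) -> "Region":
        r1, r2, m = ds.shape
        return Region((0, r1), (0, r2), (0, m))


def _nearest_index(axis: np.ndarray, value: float) -> int:
    # ties toward the lower index
    d = np.abs(axis.astype(np.float64) - float(value))
    return int(np.argmin(d))


def region_from_physical(
    ds: MSDataset,
    rt1: tuple[float, float] | None = None,
    rt2: tuple[float, float] | None = None,
    mz: tuple[float, float] | None = None,
) -> Region:
    """Build a :class:`Region` from physical coordinates.

    Each pair ``(lo, hi)`` is mapped to indices by nearest axis value;
    the upper index is made exclusive (``+1``) so the physical endpoints
    are included.  Omitted axes select their full extent.
    """
    def conv(axis, pair, n):
        if pair is None:
            return (0, n)
        lo = _nearest_index(axis, pair[0])
        hi = _nearest_index(axis, pair[1]) + 1
        return (lo, hi)

    region = Region(
        conv(ds.rt1_axis, rt1, ds.rt1_axis.size),
        conv(ds.rt2_axis, rt2, ds.rt2_axis.size),
        conv(ds.mass_axis, mz, ds.mass_axis.size),
    )
    region.validate(ds)
    return region


def crop(ds: MSDataset, region: Region) -> MSDataset:
    """Restrict *ds* to *region*, returning a new dataset.

    Values inside the region are unchanged; axes are truncated and the
    crop is recorded in the provenance map.  Nested crops compose.
    """
    region.validate(ds)
    (a1, b1), (a2, b2), (am, bm) = region.rt1_range, region.rt2_range, region.mass_range
    provenance = dict(ds.provenance)
    provenance["crop"] = f"rt1=[{a1},{b1}) rt2=[{a2},{b2}) mz=[{am},{bm})"
    return MSDataset(
        sample_id=ds.sample_id,
        rt1_axis=ds.rt1_axis[a1:b1].copy(),
        rt2_axis=ds.rt2_axis[a2:b2].copy(),
        mass_axis=ds.mass_axis[am:bm].copy(),
        intensity=ds.intensity[a1:b1, a2:b2, am:bm].copy(),
        modulation_period=ds.modulation_period,
        provenance=provenance,
    )


def extract_spectrum(ds: MSDataset, region: Region) -> MassSpectrum:
    """Sum the region over both retention-time axes into a mass spectrum.

    A 1x1 RT region yields the pointwise spectrum of that single cell,
    as used by a linked mass-spectrum view.
    """
    region.validate(ds)
    (a1, b1), (a2, b2), (am, bm) = region.rt1_range, region.rt2_range, region.mass_range
    block = ds.intensity[a1:b1, a2:b2, am:bm].astype(np.float64)
    return MassSpectrum(
        masses=ds.mass_axis[am:bm].copy(),
        intensities=block.sum(axis=(0, 1)),
    )
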