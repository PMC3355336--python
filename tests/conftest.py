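import numpy as np
import pytest
from scipy.io import netcdf_file

from chromacube import MSDataset, MassSpectrum


def make_dataset(rng: np.random.Generator, shape=(4, 3, 5), sample_id="s",
                 period=2.0) -> MSDataset:
    """Random valid dataset with float32 intensities."""
    r1, r2, m = shape
    return MSDataset(
        sample_id=sample_id,
        rt1_axis=period * np.arange(r1),
        rt2_axis=(period / r2) * np.arange(r2),
        mass_axis=50 + np.arange(m),
        intensity=rng.gamma(2.0, 10.0, size=shape).astype(np.float32),
        modulation_period=period,
        provenance={"origin": "test"},
    )


def write_andi(path, times, scan_points, dt_hint=None):
    """Write a minimal ANDI-MS NetCDF-3 file.

    ``scan_points`` is a list (per scan) of (mass, intensity) pairs.
    """
    point_count = np.array([len(p) for p in scan_points], dtype=np.int32)
    scan_index = np.concatenate([[0], np.cumsum(point_count)[:-1]]).astype(np.int32)
    masses = np.concatenate([[m for m, _ in p] for p in scan_points]) \
        if point_count.sum() else np.array([])
    intens = np.concatenate([[v for _, v in p] for p in scan_points]) \
        if point_count.sum() else np.array([])
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", len(times))
        nc.createDimension("point_number", int(point_count.sum()))
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = np.asarray(times, dtype=np.float64)
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = scan_index
        v = nc.createVariable("point_count", "i", ("scan_number",))
        v[:] = point_count
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[:] = masses
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[:] = intens
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ds(rng):
    return make_dataset(rng)


def spectrum(d: dict) -> MassSpectrum:
    masses = sorted(d)
    return MassSpectrum(masses, [d[m] for m in masses])
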