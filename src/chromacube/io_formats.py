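"""Reading ANDI-MS netCDF acquisitions and the OMV dense-cube container.

A GCxGC-MS run is acquired as a linear sequence of mass-spectral scans.
The modulator re-injects first-column effluent every ``modulation_period``
seconds, so the linear scan-time axis folds into two retention times:
RT1 (first column, slow) and RT2 (second column, fast, in
``[0, modulation_period)``).  :func:`read_andi` performs that folding and
bins centroided m/z values to nominal integer masses, producing a dense
``(R1, R2, M)`` intensity cube.

The OMV container is this package's internal on-disk cube format:

* bytes 0-3: ASCII magic ``OMV1``
* bytes 4-7: little-endian uint32 ``N`` (JSON header length)
* bytes 8..8+N: UTF-8 JSON header with ``sample_id``,
  ``modulation_period``, ``rt1_axis``, ``rt2_axis``, ``mass_axis``,
  ``provenance``
* remainder: ``R1*R2*M`` little-endian float32 values, C order with RT1
  slowest and m/z fastest.

The fixed float32 little-endian layout makes write/read round-trips
bit-exact.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.io import netcdf_file

OMV_MAGIC = b"OMV1"

#: netCDF variables an ANDI-MS file must provide.
ANDI_REQUIRED_VARS = (
    "scan_acquisition_time",
    "scan_index",
    "point_count",
    "mass_values",
    "intensity_values",
)


class FormatError(Exception):
    """A file does not conform to the expected on-disk format."""


@dataclass
class MassSpectrum:
    """Intensity vs. integer m/z.

    ``intensities`` may be signed: difference spectra carry negative
    values for masses that are more abundant in the subtrahend.
    """

    masses: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=np.int64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.masses.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("masses and intensities must be 1-D")
        if self.masses.shape != self.intensities.shape:
            raise ValueError(
                f"length mismatch: {self.masses.size} masses vs "
                f"{self.intensities.size} intensities"
            )
        if self.masses.size and np.any(np.diff(self.masses) <= 0):
            raise ValueError("masses must be strictly increasing (hence unique)")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.masses.tolist(), self.intensities.tolist()))


@dataclass
class MSDataset:
    """Dense GCxGC-MS intensity cube over (RT1, RT2, m/z bin).

    Parameters
    ----------
    sample_id
        Free-text identifier of the acquisition.
    rt1_axis, rt2_axis
        Retention times in seconds, strictly increasing.  RT2 values lie
        in ``[0, modulation_period)``.
    mass_axis
        Nominal integer m/z bins, strictly increasing.
    intensity
        Non-negative float32 cube of shape ``(R1, R2, M)``.
    modulation_period
        Modulator cycle time in seconds.
    provenance
        Free-text metadata map recording how the cube was produced.
    """

    sample_id: str
    rt1_axis: np.ndarray
    rt2_axis: np.ndarray
    mass_axis: np.ndarray
    intensity: np.ndarray
    modulation_period: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rt1_axis = np.asarray(self.rt1_axis, dtype=np.float64)
        self.rt2_axis = np.asarray(self.rt2_axis, dtype=np.float64)
        self.mass_axis = np.asarray(self.mass_axis, dtype=np.int64)
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        self.modulation_period = float(self.modulation_period)
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def validate(self) -> None:
        expected = (self.rt1_axis.size, self.rt2_axis.size, self.mass_axis.size)
        if self.intensity.shape != expected:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match axes {expected}"
            )
        for name, ax in (("rt1_axis", self.rt1_axis), ("rt2_axis", self.rt2_axis),
                         ("mass_axis", self.mass_axis)):
            if ax.size == 0:
                raise ValueError(f"{name} is empty")
            if ax.size > 1 and np.any(np.diff(ax.astype(np.float64)) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.modulation_period <= 0:
            raise ValueError("modulation_period must be positive")
        if self.rt2_axis[0] < 0 or self.rt2_axis[-1] >= self.modulation_period:
            raise ValueError("rt2_axis values must lie in [0, modulation_period)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("intensity contains negative values")

    def total_intensity(self) -> float:
        """Compensated (pairwise in float64) sum over the whole cube."""
        return float(np.sum(self.intensity, dtype=np.float64))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MSDataset):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.modulation_period == other.modulation_period
            and np.array_equal(self.rt1_axis, other.rt1_axis)
            and np.array_equal(self.rt2_axis, other.rt2_axis)
            and np.array_equal(self.mass_axis, other.mass_axis)
            and self.intensity.shape == other.intensity.shape
            and np.array_equal(
                self.intensity.view(np.uint32), other.intensity.view(np.uint32)
            )
            and self.provenance == other.provenance
        )


def _andi_var(nc, name: str) -> np.ndarray:
    if name not in nc.variables:
        raise FormatError(f"ANDI-MS file is missing required variable '{name}'")
    return np.asarray(nc.variables[name][:]).copy()


def read_andi(
    path: str | os.PathLike,
    modulation_period: float,
    mass_range: tuple[int, int] | None = None,
) -> MSDataset:
    """Read an ANDI-MS netCDF acquisition and fold it into a GCxGC cube.

    The linear scan time ``t`` is folded with period ``P``:
    ``RT1 = t0 + P * floor((t - t0)/P)`` and ``RT2 = (t - t0) mod P``
    where ``t0`` is the first scan's acquisition time.  Scans are
    assigned to grid slots by nominal index ``round((t - t0)/dt)`` with
    ``dt`` the median inter-scan gap, so microsecond-scale acquisition
    jitter does not shift scans.  Each centroided (m/z, intensity) point
    is binned to the nearest integer m/z, summing collisions; scans
    missing at the end of the last modulation are zero-padded.

    Parameters
    ----------
    path
        NetCDF-3 classic file with the ANDI-MS raw-data variables.
    modulation_period
        Modulator cycle time in seconds; must be a positive integer
        multiple of the scan interval (tolerance 1e-6).
    mass_range
        Optional half-open integer interval ``[lo, hi)`` restricting the
        mass axis.  Total intensity is conserved up to this truncation.
    """
    if modulation_period <= 0:
        raise ValueError("modulation_period must be positive")
    with netcdf_file(os.fspath(path), "r", mmap=False) as nc:
        times = _andi_var(nc, "scan_acquisition_time").astype(np.float64)
        scan_index = _andi_var(nc, "scan_index").astype(np.int64)
        point_count = _andi_var(nc, "point_count").astype(np.int64)
        mass_values = _andi_var(nc, "mass_values").astype(np.float64)
        intensity_values = _andi_var(nc, "intensity_values").astype(np.float64)

    n_scans = times.size
    if n_scans == 0:
        raise FormatError("ANDI-MS file contains no scans")
    t0 = times[0]
    if n_scans > 1:
        dt = float(np.median(np.diff(times)))
        if dt <= 0:
            raise FormatError("scan_acquisition_time is not increasing")
    else:
        dt = modulation_period
    ratio = modulation_period / dt
    scans_per_mod = int(round(ratio))
    if scans_per_mod < 1 or abs(ratio - scans_per_mod) > 1e-6 * max(1.0, ratio):
        raise ValueError(
            f"modulation_period {modulation_period} is not an integer multiple "
            f"of the scan interval {dt}"
        )

    nominal = np.rint((times - t0) / dt).astype(np.int64)
    n_mods = int(nominal[-1] // scans_per_mod) + 1
    r1 = n_mods
    r2 = scans_per_mod

    # integer mass bins; restrict before allocating the cube
    binned = np.rint(mass_values).astype(np.int64)
    if mass_range is not None:
        lo, hi = int(mass_range[0]), int(mass_range[1])
        if hi <= lo:
            raise ValueError("mass_range must be a non-empty half-open interval")
    else:
        lo, hi = int(binned.min()), int(binned.max()) + 1
    mass_axis = np.arange(lo, hi, dtype=np.int64)

    cube = np.zeros((r1, r2, mass_axis.size), dtype=np.float64)
    starts = scan_index
    for s in range(n_scans):
        a = int(starts[s])
        b = a + int(point_count[s])
        mz = binned[a:b]
        iv = intensity_values[a:b]
        keep = (mz >= lo) & (mz < hi)
        if not np.any(keep):
            continue
        idx = nominal[s]
        i, j = divmod(int(idx), scans_per_mod)
        np.add.at(cube[i, j], mz[keep] - lo, iv[keep])

    rt1_axis = t0 + modulation_period * np.arange(r1, dtype=np.float64)
    rt2_axis = dt * np.arange(r2, dtype=np.float64)
    return MSDataset(
        sample_id=os.path.basename(os.fspath(path)),
        rt1_axis=rt1_axis,
        rt2_axis=rt2_axis,
        mass_axis=mass_axis,
        intensity=cube,
        modulation_period=modulation_period,
        provenance={"source": os.fspath(path), "reader": "read_andi"},
    )


def write_cube(ds: MSDataset, path: str | os.PathLike) -> str:
    """Write *ds* to *path* in the OMV container format.

    The written file round-trips through :func:`read_cube` bit-exactly.
    """
    ds.validate()
    header = {
        "sample_id": ds.sample_id,
        "modulation_period": ds.modulation_period,
        "rt1_axis": [float(v) for v in ds.rt1_axis],
        "rt2_axis": [float(v) for v in ds.rt2_axis],
        "mass_axis": [int(v) for v in ds.mass_axis],
        "provenance": ds.provenance,
    }
    _write_omv(path, header, ds.intensity)
    return os.fspath(path)


def read_cube(path: str | os.PathLike) -> MSDataset:
    """Read an OMV container written by :func:`write_cube`."""
    header, payload = _read_omv(path)
    r1 = len(header["rt1_axis"])
    r2 = len(header["rt2_axis"])
    m = len(header["mass_axis"])
    cube = _payload_to_cube(payload, (r1, r2, m), path)
    return MSDataset(
        sample_id=header["sample_id"],
        rt1_axis=np.asarray(header["rt1_axis"], dtype=np.float64),
        rt2_axis=np.asarray(header["rt2_axis"], dtype=np.float64),
        mass_axis=np.asarray(header["mass_axis"], dtype=np.int64),
        intensity=cube,
        modulation_period=header["modulation_period"],
        provenance=header.get("provenance", {}),
    )


def _write_omv(path, header: dict, *cubes: np.ndarray) -> None:
    blob = json.dumps(header, ensure_ascii=False).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(OMV_MAGIC)
        fh.write(np.uint32(len(blob)).astype("<u4").tobytes())
        fh.write(blob)
        for cube in cubes:
            fh.write(np.ascontiguousarray(cube, dtype="<f4").tobytes())


def _read_omv(path) -> tuple[dict, bytes]:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != OMV_MAGIC:
            raise FormatError(f"bad magic {magic!r}; expected {OMV_MAGIC!r}")
        raw_n = fh.read(4)
        if len(raw_n) < 4:
            raise FormatError("truncated OMV header length")
        n = int(np.frombuffer(raw_n, dtype="<u4")[0])
        blob = fh.read(n)
        if len(blob) < n:
            raise FormatError(f"truncated OMV header: expected {n} bytes, got {len(blob)}")
        try:
            header = json.loads(blob.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise FormatError(f"invalid OMV JSON header: {exc}") from exc
        payload = fh.read()
    return header, payload


def _payload_to_cube(payload: bytes, shape: tuple[int, ...], path) -> np.ndarray:
    expected = 4 * math.prod(shape)
    if len(payload) != expected:
        raise FormatError(
            f"truncated OMV payload in {os.fspath(path)}: expected {expected} bytes "
            f"for shape {shape}, got {len(payload)}"
        )
    return np.frombuffer(payload, dtype="<f4").reshape(shape).copy()
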