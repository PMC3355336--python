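"""Mass-spectral comparison: difference spectra, cosine similarity,
windowed library matching.

Spectra with different mass supports are compared over the union of
their bins, with absent bins treated as zero intensity.  The similarity
measure is the plain cosine (normalized dot product), the dominant
convention in spectral library search; the ranking contract of
:func:`library_match` does not depend on the particular measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromacube.io_formats import MassSpectrum, MSDataset
from chromacube.dataset_ops import Region, extract_spectrum

logger = logging.getLogger(__name__)


@dataclass
class SpectralLibrary:
    """Reference spectra of known compounds, keyed by unique compound id."""

    entries: list[tuple[str, MassSpectrum]]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("compound ids must be unique")
        for cid, spec in self.entries:
            if np.any(spec.intensities < 0):
                raise ValueError(f"library spectrum {cid!r} has negative intensities")
            if not np.any(spec.intensities != 0):
                raise ValueError(f"library spectrum {cid!r} is all-zero")

    def __len__(self) -> int:
        return len(self.entries)


def _on_union(a: MassSpectrum, b: MassSpectrum):
    union = np.union1d(a.masses, b.masses)
    va = np.zeros(union.size)
    vb = np.zeros(union.size)
    va[np.searchsorted(union, a.masses)] = a.intensities
    vb[np.searchsorted(union, b.masses)] = b.intensities
    return union, va, vb


def diff_spectrum(a: MassSpectrum, b: MassSpectrum) -> MassSpectrum:
    """Signed difference ``a - b`` over the union of mass bins.

    Positive intensities mark masses more abundant in *a*, negative in
    *b*; the result is meant for a mid-baseline bar plot.
    """
    union, va, vb = _on_union(a, b)
    return MassSpectrum(union, va - vb)


def cosine_similarity(a: MassSpectrum, b: MassSpectrum) -> float:
    """Cosine of the angle between two spectra on their union of bins.

    Scale-invariant and symmetric; 1.0 for identical shapes, 0.0 for
    disjoint mass supports.
    """
    _, va, vb = _on_union(a, b)
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine_similarity requires spectra with positive norm")
    return float(np.dot(va, vb) / (na * nb))


def library_match(
    ds: MSDataset,
    region: Region,
    lib: SpectralLibrary,
    top_k: int,
) -> list[tuple[str, float]]:
    """Score the region's summed spectrum against every library entry.

    Returns the ``top_k`` entries by descending cosine score, ties
    broken by compound id ascending.  An all-zero region spectrum
    cannot be scored: a warning is logged and the result is empty.
    """
    if top_k < 1:
        raise ValueError("top_k must be positive")
    if len(lib) == 0:
        raise ValueError("library is empty")
    query = extract_spectrum(ds, region)
    if not np.any(query.intensities != 0):
        logger.warning("region spectrum is all-zero; no match possible")
        return []
    scored = [(cid, cosine_similarity(query, spec)) for cid, spec in lib.entries]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top_k]


def load_library_csv(path) -> SpectralLibrary:
    """Load a long-form library CSV with columns compound_id, mz, intensity."""
    df = pd.read_csv(path)
    required = {"compound_id", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library CSV is missing columns: {sorted(missing)}")
    entries = []
    for cid, grp in df.groupby("compound_id", sort=True):
        grp = grp.sort_values("mz")
        entries.append(
            (str(cid), MassSpectrum(grp["mz"].to_numpy(np.int64),
                                    grp["intensity"].to_numpy(np.float64)))
        )
    return SpectralLibrary(entries)
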