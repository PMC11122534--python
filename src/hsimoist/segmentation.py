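"""Foreground masking, 15-segment partitioning, mean-spectrum extraction.

The sausage is located by a single-band reflectance threshold (band nearest
695 nm, strictly greater than 0.075).  Each piece is then cut into equal-width
transverse slices along its long axis — emulating cross-sections of a
cylindrical sausage — and the unweighted mean spectrum of every slice becomes
one calibration sample.  Absorbance is ``A = -log10(R)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypercube import Hypercube

__all__ = [
    "Mask",
    "SpectrumSet",
    "threshold_mask",
    "partition_segments",
    "extract_mean_spectra",
    "to_absorbance",
    "moisture_from_weights",
]

MASK_BAND_NM = 695.0
MASK_THRESHOLD = 0.075
N_SEGMENTS = 15


@dataclass
class Mask:
    """Boolean foreground mask with the same spatial shape as its cube."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())


@dataclass
class SpectrumSet:
    """Per-segment mean spectra with block structure and reference moisture.

    One row per segment; ``block_ids`` ties the (at most 15) segments of a
    physical sausage piece together so they co-travel through a split.
    """

    spectra: np.ndarray
    wavelengths_nm: np.ndarray
    sample_ids: list
    block_ids: list
    reference_moisture_pct: np.ndarray | None = None
    domain: str = "reflectance"

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        n = self.spectra.shape[0]
        if len(self.sample_ids) != n or len(self.block_ids) != n:
            raise ValueError("sample_ids/block_ids length must match spectra rows")
        if self.spectra.shape[1] != len(self.wavelengths_nm):
            raise ValueError("spectra columns must match wavelength grid")
        counts = pd.Series(self.block_ids).value_counts()
        if (counts > N_SEGMENTS).any():
            raise ValueError("a block_id occurs more than 15 times")
        if self.reference_moisture_pct is not None:
            self.reference_moisture_pct = np.asarray(
                self.reference_moisture_pct, dtype=float
            )
            y = self.reference_moisture_pct
            if len(y) != n:
                raise ValueError("reference_moisture_pct length mismatch")
            if np.any((y <= 0) | (y >= 100)):
                raise ValueError("reference moisture must lie in (0, 100) %")
        if self.domain not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown domain {self.domain!r}")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    def subset(self, idx) -> "SpectrumSet":
        idx = np.asarray(idx)
        return SpectrumSet(
            self.spectra[idx],
            self.wavelengths_nm,
            [self.sample_ids[i] for i in idx],
            [self.block_ids[i] for i in idx],
            None
            if self.reference_moisture_pct is None
            else self.reference_moisture_pct[idx],
            self.domain,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: ids, domain, moisture, then one column per wavelength."""
        df = pd.DataFrame(
            self.spectra, columns=[f"{w:g}" for w in self.wavelengths_nm]
        )
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "block_id", self.block_ids)
        df.insert(2, "domain", self.domain)
        if self.reference_moisture_pct is not None:
            df.insert(3, "moisture_pct", self.reference_moisture_pct)
        return df

    @classmethod
    def concat(cls, sets: list["SpectrumSet"]) -> "SpectrumSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        wl = sets[0].wavelengths_nm
        dom = sets[0].domain
        for s in sets[1:]:
            if not np.array_equal(s.wavelengths_nm, wl) or s.domain != dom:
                raise ValueError("spectrum sets disagree on grid or domain")
        ys = [s.reference_moisture_pct for s in sets]
        y = None if any(v is None for v in ys) else np.concatenate(ys)
        return cls(
            np.vstack([s.spectra for s in sets]),
            wl,
            sum([s.sample_ids for s in sets], []),
            sum([s.block_ids for s in sets], []),
            y,
            dom,
        )


def threshold_mask(
    cube: Hypercube,
    band_nm: float = MASK_BAND_NM,
    threshold: float = MASK_THRESHOLD,
) -> Mask:
    """Foreground = pixels whose reflectance at the band nearest ``band_nm``
    strictly exceeds ``threshold`` (default 695 nm, 0.075)."""
    if cube.kind != "reflectance":
        raise ValueError("threshold_mask expects a reflectance cube")
    lo, hi = cube.wavelengths_nm[0], cube.wavelengths_nm[-1]
    if not (lo <= band_nm <= hi):
        raise ValueError(f"band {band_nm} nm outside grid [{lo}, {hi}] nm")
    grid = cube.data[:, :, cube.band_index(band_nm)] > threshold
    if not grid.any():
        warnings.warn("threshold mask is empty", stacklevel=2)
    return Mask(grid)


def partition_segments(mask: Mask, n_segments: int = N_SEGMENTS) -> np.ndarray:
    """Split the foreground into ``n_segments`` equal-width transverse slices.

    The slicing axis is the longer extent of the foreground bounding box
    (the sausage's long axis); slice widths differ by at most one pixel.
    Returns an integer label image: 0 background, 1..n_segments foreground.
    """
    if mask.n_foreground == 0:
        raise ValueError("cannot partition an empty mask")
    rows, cols = np.nonzero(mask.grid)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    if (r1 - r0) >= (c1 - c0):
        axis_coord, lo, hi = rows, r0, r1
    else:
        axis_coord, lo, hi = cols, c0, c1
    extent = hi - lo + 1
    if extent < n_segments:
        raise ValueError(
            f"foreground extent {extent} px along the long axis is smaller "
            f"than n_segments={n_segments}"
        )
    # integer partition: bin edges via linspace, widths differ by <= 1
    edges = lo + np.floor(np.arange(n_segments + 1) * extent / n_segments).astype(int)
    labels = np.zeros(mask.grid.shape, dtype=int)
    seg_of = np.searchsorted(edges, axis_coord, side="right") - 1
    seg_of = np.clip(seg_of, 0, n_segments - 1)
    labels[rows, cols] = seg_of + 1
    return labels


def extract_mean_spectra(
    cube: Hypercube,
    segments: np.ndarray,
    block_id: str,
    reference_moisture_pct: np.ndarray | None = None,
) -> SpectrumSet:
    """One unweighted mean spectrum per segment label.

    ``sample_ids`` encode ``(block_id, segment_index)`` as
    ``"{block_id}:s{index:02d}"``.
    """
    segments = np.asarray(segments)
    if segments.shape != cube.shape[:2]:
        raise ValueError("segment label image shape does not match cube")
    seg_ids = np.unique(segments)
    seg_ids = seg_ids[seg_ids > 0]
    if len(seg_ids) == 0:
        raise ValueError("no segments present")
    spectra = np.empty((len(seg_ids), cube.n_bands))
    for i, s in enumerate(seg_ids):
        sel = segments == s
        if not sel.any():
            raise ValueError(f"segment {s} is empty")
        spectra[i] = cube.data[sel].mean(axis=0)
    sample_ids = [f"{block_id}:s{int(s):02d}" for s in seg_ids]
    return SpectrumSet(
        spectra,
        cube.wavelengths_nm,
        sample_ids,
        [block_id] * len(seg_ids),
        reference_moisture_pct,
        domain="reflectance" if cube.kind == "reflectance" else cube.kind,
    )


def to_absorbance(x, floor: float = 1e-6):
    """Reflectance to absorbance, ``A = -log10(R)``, elementwise.

    Accepts a :class:`SpectrumSet` or a :class:`Hypercube`.  Values of R at or
    below zero are clamped to ``floor`` before the log; the clamp count is
    reported via a warning (noise can push calibrated reflectance <= 0, a hard
    failure would be brittle).
    """
    if isinstance(x, SpectrumSet):
        if x.domain != "reflectance":
            raise ValueError("to_absorbance expects reflectance input")
        vals, n_clamped = _neg_log10(x.spectra, floor)
        return SpectrumSet(
            vals, x.wavelengths_nm, list(x.sample_ids), list(x.block_ids),
            x.reference_moisture_pct, domain="absorbance",
        )
    if isinstance(x, Hypercube):
        if x.kind != "reflectance":
            raise ValueError("to_absorbance expects reflectance input")
        vals, n_clamped = _neg_log10(x.data, floor)
        return Hypercube(vals, x.wavelengths_nm, kind="absorbance")
    raise TypeError(f"unsupported input type {type(x).__name__}")


def _neg_log10(values: np.ndarray, floor: float) -> tuple[np.ndarray, int]:
    bad = values <= 0
    n_clamped = int(bad.sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped} reflectance values <= 0 clamped to {floor} before log",
            stacklevel=3,
        )
    return -np.log10(np.maximum(values, floor)), n_clamped


def moisture_from_weights(w1: float, w2: float) -> float:
    """Oven-drying moisture: ``(W1 - W2) / W1 * 100`` with W1 the wet and W2
    the dried mass in grams."""
    if w1 <= 0:
        raise ValueError("wet mass w1 must be positive")
    if w2 < 0:
        raise ValueError("dried mass w2 cannot be negative")
    if w2 > w1:
        raise ValueError("dried mass exceeds wet mass (mass gain impossible)")
    return (w1 - w2) / w1 * 100.0
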