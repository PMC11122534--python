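"""Synthetic hyperspectral scenes with known moisture ground truth.

The generator emulates the statistical structure the analysis assumes, so
every stage of the pipeline is testable without camera data:

* reflectance continua with absorption features at 430 nm (Soret band of heme
  pigments), 560 and 595 nm (oxymyoglobin) and the 780 / 980 nm water
  overtone bands, whose depths increase affinely with local moisture;
* per-piece moisture means spanning 45-65 % with a within-piece spatial
  gradient, the realistic range for these products;
* per-pixel multiplicative/additive scatter (the distortion SNV and MSC are
  designed to remove) and additive sensor noise on the raw counts;
* a spectrally flat dark background (reflectance 0.02) separable from tissue
  by the "reflectance at 695 nm > 0.075" rule in the noiseless limit;
* white/dark reference frames, with raw counts produced by inverting the
  radiometric calibration so that calibrating the raw cube recovers the
  scattered reflectance exactly (up to noise).

Everything is deterministic given the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypercube import Hypercube, ReferenceFrames, default_wavelength_grid
from .segmentation import Mask

__all__ = ["SceneSpec", "Scene", "generate_scene", "generate_reference_table"]

#: absorption features: centre nm -> (base depth, width sigma nm)
FIXED_BANDS = {430.0: (0.10, 12.0), 560.0: (0.06, 10.0), 595.0: (0.05, 10.0)}
#: water overtone bands: centre nm -> (depth at 55 % moisture, depth per % , width)
WATER_BANDS = {780.0: (0.04, 0.0020, 18.0), 980.0: (0.08, 0.0035, 25.0)}


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene; defaults are the study conditions."""

    rows_per_piece: int = 24
    cols: int = 100
    n_pieces: int = 6
    n_segments: int = 15
    margin: int = 2
    wavelengths_nm: np.ndarray = field(default_factory=default_wavelength_grid)
    moisture_range_pct: tuple[float, float] = (45.0, 65.0)
    moisture_gradient_pct: float = 3.0  # peak-to-centre amplitude along the axis
    continuum_lo: float = 0.30
    continuum_hi: float = 0.55
    sigma_a: float = 0.0   # sd of the multiplicative scatter factor
    sigma_b: float = 0.0   # sd of the additive scatter offset
    scatter_length_px: float = 8.0  # correlation length of the scatter field
    noise_sd: float = 0.0  # sensor noise on raw counts
    background_reflectance: float = 0.02
    white_level: float = 0.90
    dark_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.white_level <= self.dark_level:
            raise ValueError("white level must exceed dark level")
        lo, hi = self.moisture_range_pct
        if not (0 < lo < hi < 100):
            raise ValueError("moisture range must lie inside (0, 100)")

    @property
    def rows(self) -> int:
        return self.n_pieces * self.rows_per_piece


@dataclass
class Scene:
    """Generated scene: raw cube + references, plus the ground truth."""

    raw: Hypercube
    refs: ReferenceFrames
    reflectance: Hypercube       # scattered, noiseless reflectance (truth input)
    truth_moisture: np.ndarray   # per-pixel moisture %, NaN on background
    truth_mask: Mask
    piece_labels: np.ndarray     # 0 background, 1..n_pieces
    block_ids: list
    spec: SceneSpec


def moisture_to_reflectance(moisture_pct, spec: SceneSpec) -> np.ndarray:
    """Forward spectral model: continuum minus Gaussian absorption bands, the
    780/980 nm depths affine in moisture with positive slope (wetter tissue
    absorbs more)."""
    wl = spec.wavelengths_nm
    m = np.atleast_1d(np.asarray(moisture_pct, dtype=float))
    frac = (wl - wl[0]) / (wl[-1] - wl[0])
    continuum = spec.continuum_lo + (spec.continuum_hi - spec.continuum_lo) * frac
    r = np.tile(continuum, m.shape + (1,))
    for centre, (depth, width) in FIXED_BANDS.items():
        r -= depth * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    for centre, (d0, slope, width) in WATER_BANDS.items():
        depth = d0 + slope * (m - 55.0)
        r -= depth[..., None] * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    return r


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], length_px: float, sd: float
) -> np.ndarray:
    """Zero-mean Gaussian random field with the given marginal sd and spatial
    correlation length (white noise smoothed by a Gaussian kernel, rescaled)."""
    from scipy.ndimage import gaussian_filter

    if sd == 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    smooth = gaussian_filter(raw, sigma=length_px, mode="reflect")
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    return smooth * (sd / s)


def generate_scene(spec: SceneSpec) -> Scene:
    """Build a raw cube + reference frames with full ground truth.

    Pieces are horizontal rectangles stacked vertically, long axis along the
    columns; each piece's moisture mean is drawn uniformly from the configured
    range, with a linear gradient along the long axis.
    """
    rng = np.random.default_rng(spec.seed)
    wl = spec.wavelengths_nm
    rows, cols, n_bands = spec.rows, spec.cols, len(wl)

    piece_labels = np.zeros((rows, cols), dtype=int)
    truth_moisture = np.full((rows, cols), np.nan)
    block_ids = []
    lo, hi = spec.moisture_range_pct
    for k in range(spec.n_pieces):
        r0 = k * spec.rows_per_piece + spec.margin
        r1 = (k + 1) * spec.rows_per_piece - spec.margin
        c0, c1 = spec.margin, cols - spec.margin
        if c1 - c0 < spec.n_segments:
            raise ValueError("piece extent smaller than n_segments")
        piece_labels[r0:r1, c0:c1] = k + 1
        mean_m = rng.uniform(lo, hi)
        axis = np.linspace(-1.0, 1.0, c1 - c0)
        m_row = mean_m + spec.moisture_gradient_pct * axis
        truth_moisture[r0:r1, c0:c1] = np.clip(m_row, 1.0, 99.0)[None, :]
        block_ids.append(f"piece{k + 1:02d}")
    mask = Mask(piece_labels > 0)

    # ideal reflectance from the forward model
    refl = np.full((rows, cols, n_bands), spec.background_reflectance)
    fg = mask.grid
    refl[fg] = moisture_to_reflectance(truth_moisture[fg], spec)

    # multiplicative/additive scatter: a smooth low-frequency field, as
    # produced by surface curvature and uneven illumination — not i.i.d.
    # pixel noise, which would vanish from segment means
    if spec.sigma_a or spec.sigma_b:
        a = 1.0 + _smooth_field(rng, (rows, cols), spec.scatter_length_px,
                                spec.sigma_a)
        b = _smooth_field(rng, (rows, cols), spec.scatter_length_px, spec.sigma_b)
        refl = a[:, :, None] * refl + b[:, :, None]

    # reference frames: white with a gentle band-dependent roll-off, flat dark
    white_band = spec.white_level * (1.0 - 0.05 * ((wl - wl.mean()) / (wl[-1] - wl[0])) ** 2)
    white = np.broadcast_to(white_band, (rows, cols, n_bands)).copy()
    dark = np.full((rows, cols, n_bands), spec.dark_level)
    if np.any(white - dark <= 0):
        raise ValueError("scene parameters produce non-positive white-dark contrast")

    # invert the calibration to raw counts, then add sensor noise
    raw = refl * (white - dark) + dark
    if spec.noise_sd:
        raw = raw + spec.noise_sd * rng.standard_normal(raw.shape)

    return Scene(
        raw=Hypercube(raw, wl, kind="raw"),
        refs=ReferenceFrames(white=white, dark=dark),
        reflectance=Hypercube(refl, wl, kind="reflectance"),
        truth_moisture=truth_moisture,
        truth_mask=mask,
        piece_labels=piece_labels,
        block_ids=block_ids,
        spec=spec,
    )


def generate_reference_table(
    truth_moisture: np.ndarray,
    segments: np.ndarray,
    block_id: str,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-segment reference moisture: the mean of the truth map over each
    segment plus optional measurement noise (default sd 0.5 %, emulating
    triplicate oven-drying variation)."""
    segments = np.asarray(segments)
    if segments.shape != truth_moisture.shape:
        raise ValueError("segment labels and truth map shapes differ")
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for s in np.unique(segments[segments > 0]):
        sel = segments == s
        vals = truth_moisture[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"segment {s} has no truth values")
        ref = float(vals.mean())
        if noise_sd:
            ref += float(noise_sd * rng.standard_normal())
        rows.append(
            {
                "sample_id": f"{block_id}:s{int(s):02d}",
                "block_id": block_id,
                "segment_index": int(s),
                "moisture_pct": ref,
            }
        )
    return pd.DataFrame(rows)
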