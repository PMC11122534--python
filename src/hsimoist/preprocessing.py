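"""Spectral pre-treatments and ordered pre-processing chains.

The five chains reported in the comparison table are: raw (empty chain),
first derivative, SNV, SNV + first derivative, and first derivative + SNV.
Normalization (unit L2) and MSC are also provided.  All transforms are
row-local except MSC, whose reference spectrum is fitted once on the
calibration set and frozen — applying a fitted chain to new rows never
touches their statistics, so there is no train/test leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessChain",
    "snv",
    "msc_fit",
    "msc_apply",
    "deriv1",
    "normalize",
    "STANDARD_CHAINS",
]

#: the pre-treatment rows of the standard comparison grid
STANDARD_CHAINS: dict[str, list[str]] = {
    "Raw data (untreated)": [],
    "1st Derivative": ["deriv1"],
    "SNV": ["snv"],
    "SNV + 1st Derivative": ["snv", "deriv1"],
    "1st Derivative + SNV": ["deriv1", "snv"],
}

SG_WINDOW = 7
SG_POLYORDER = 2


def _as_matrix(spectra) -> np.ndarray:
    x = np.asarray(spectra, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("spectra must be a 1-D spectrum or 2-D matrix")
    return x


def snv(spectra) -> np.ndarray:
    """Standard normal variate: per row, subtract the mean and divide by the
    sample (ddof=1) standard deviation.  Output rows have mean 0, sd 1.

    A constant row carries no spectral shape and raises ``ValueError``.
    """
    x = _as_matrix(spectra)
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 bands per row")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = np.nonzero(sd.ravel() == 0)[0]
    if zero.size:
        raise ValueError(f"SNV: zero-variance (constant) spectrum at row {zero[0]}")
    return (x - mu) / sd


def msc_fit(calibration_spectra) -> np.ndarray:
    """MSC reference spectrum = column-wise mean of the calibration set."""
    x = _as_matrix(calibration_spectra)
    if x.shape[0] < 2:
        raise ValueError("MSC reference needs at least 2 calibration rows")
    return x.mean(axis=0)


def msc_apply(spectra, reference) -> np.ndarray:
    """Multiplicative scatter correction against a fitted reference.

    Each row x is regressed on the reference with intercept, x ~ a*ref + b
    (ordinary least squares), and corrected to (x - b) / a.
    """
    x = _as_matrix(spectra)
    ref = np.asarray(reference, dtype=float).ravel()
    if len(ref) != x.shape[1]:
        raise ValueError("reference length does not match spectra")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference is constant")
    a = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    b = x.mean(axis=1) - a * ref.mean()
    tiny = np.abs(a) < 1e-12
    if tiny.any():
        raise ValueError(
            f"MSC: spectrum at row {int(np.nonzero(tiny)[0][0])} is orthogonal "
            "to the reference shape (fitted slope ~ 0)"
        )
    return (x - b[:, None]) / a[:, None]


def deriv1(
    spectra,
    wavelengths,
    window: int = SG_WINDOW,
    polyorder: int = SG_POLYORDER,
) -> np.ndarray:
    """Savitzky-Golay first derivative (default window 7, order 2), per nm.

    Band spacing is taken from the wavelength vector (must be uniform); the
    edges are handled by polynomial fits on the one-sided windows.
    """
    x = _as_matrix(spectra)
    wl = np.asarray(wavelengths, dtype=float)
    if len(wl) != x.shape[1]:
        raise ValueError("wavelength vector does not match spectra")
    if x.shape[1] < window:
        raise ValueError(
            f"need at least {window} bands for the derivative window, got {x.shape[1]}"
        )
    spacing = np.diff(wl)
    if not np.allclose(spacing, spacing[0]):
        raise ValueError("derivative requires a uniform wavelength grid")
    return savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=1,
        delta=spacing[0], axis=1, mode="interp",
    )


def normalize(spectra) -> np.ndarray:
    """Scale each row to unit Euclidean length."""
    x = _as_matrix(spectra)
    norms = np.linalg.norm(x, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise ValueError(f"cannot normalize all-zero spectrum at row {zero[0]}")
    return x / norms[:, None]


@dataclass
class PreprocessChain:
    """Ordered pre-treatment pipeline; order matters (SNV + 1st Derivative is
    not 1st Derivative + SNV).

    A chain containing ``msc`` must be fitted on the calibration set before
    application; the learned reference spectrum is frozen thereafter.
    """

    steps: list[str] = field(default_factory=list)
    msc_reference: np.ndarray | None = None
    sg_window: int = SG_WINDOW
    sg_polyorder: int = SG_POLYORDER

    _KNOWN = ("snv", "msc", "deriv1", "normalize")

    def __post_init__(self) -> None:
        for s in self.steps:
            if s not in self._KNOWN:
                raise ValueError(
                    f"unknown pre-processing step {s!r}; known: {self._KNOWN}"
                )

    @property
    def needs_fit(self) -> bool:
        return "msc" in self.steps

    @property
    def is_fitted(self) -> bool:
        return not self.needs_fit or self.msc_reference is not None

    def fit(self, calibration_spectra, wavelengths) -> "PreprocessChain":
        """Learn stateful step parameters (the MSC reference) from the
        calibration set.  Steps before ``msc`` are applied first so the
        reference lives in the space MSC actually sees."""
        if not self.needs_fit:
            return self
        x = _as_matrix(calibration_spectra)
        for s in self.steps:
            if s == "msc":
                self.msc_reference = msc_fit(x)
                break
            x = self._apply_step(s, x, wavelengths)
        return self

    def _apply_step(self, step: str, x: np.ndarray, wavelengths) -> np.ndarray:
        if step == "snv":
            return snv(x)
        if step == "deriv1":
            return deriv1(x, wavelengths, self.sg_window, self.sg_polyorder)
        if step == "normalize":
            return normalize(x)
        if step == "msc":
            if self.msc_reference is None:
                raise RuntimeError("chain contains msc but has not been fitted")
            return msc_apply(x, self.msc_reference)
        raise ValueError(step)

    def apply(self, spectra, wavelengths) -> np.ndarray:
        """Apply the steps left-to-right.  Deterministic and stateless once
        fitted."""
        x = _as_matrix(np.array(spectra, dtype=float, copy=True))
        for s in self.steps:
            x = self._apply_step(s, x, wavelengths)
        return x

    def to_dict(self) -> dict:
        return {
            "steps": list(self.steps),
            "msc_reference": None
            if self.msc_reference is None
            else self.msc_reference.tolist(),
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessChain":
        ref = d.get("msc_reference")
        return cls(
            steps=list(d["steps"]),
            msc_reference=None if ref is None else np.asarray(ref, dtype=float),
            sg_window=d.get("sg_window", SG_WINDOW),
            sg_polyorder=d.get("sg_polyorder", SG_POLYORDER),
        )
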