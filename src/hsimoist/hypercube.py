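"""Hypercube container, ENVI-style I/O, radiometric calibration and RGB display.

A hypercube is a ``rows x cols x bands`` array with an ascending wavelength
vector in nanometres.  Raw camera counts are converted to reflectance with a
white (100 % reference) and a dark (lens covered) frame:

    R = (raw - dark) / (white - dark)

Values of exactly ``dark`` map to 0, values of exactly ``white`` map to 1;
specular highlights may exceed 1 and are reported, not clipped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hypercube",
    "ReferenceFrames",
    "CalibrationSummary",
    "default_wavelength_grid",
    "read_cube",
    "write_cube",
    "calibrate",
    "rgb_reconstruction",
]

#: default grid: 151 bands, 350-1100 nm at 5 nm spacing
DEFAULT_WL_START = 350.0
DEFAULT_WL_STOP = 1100.0
DEFAULT_N_BANDS = 151


def default_wavelength_grid(
    start: float = DEFAULT_WL_START,
    stop: float = DEFAULT_WL_STOP,
    n_bands: int = DEFAULT_N_BANDS,
) -> np.ndarray:
    """Evenly spaced wavelength vector in nm (default 350-1100 nm, 151 bands)."""
    return np.linspace(start, stop, n_bands)


@dataclass
class Hypercube:
    """3-D spectral image: ``data[row, col, band]`` plus its wavelength grid.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, n_bands)
        Raw counts, reflectance (unitless) or absorbance.
    wavelengths_nm : ndarray, shape (n_bands,)
        Strictly increasing band centres in nm.
    kind : {"raw", "reflectance", "absorbance"}
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {len(self.wavelengths_nm)} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if self.kind not in ("raw", "reflectance", "absorbance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the grid band nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))


@dataclass
class ReferenceFrames:
    """White (100 % reference) and dark (lens covered) frames.

    Each may be a full per-pixel frame matching the cube's spatial/band shape,
    or a per-band vector (mean over a reference region); vectors broadcast
    over the spatial axes.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")
        if self.white.ndim not in (1, 3):
            raise ValueError("reference frames must be per-band vectors or 3-D frames")


@dataclass
class CalibrationSummary:
    """Bookkeeping from a calibration run (dead pixels, out-of-range values)."""

    n_dead: int = 0
    n_above_one: int = 0
    n_below_zero: int = 0
    dead_fraction: float = 0.0
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# ENVI-style I/O (ASCII header + flat binary)

_ENVI_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8"), 12: np.dtype("<u2"),
                2: np.dtype("<i2"), 3: np.dtype("<i4"), 1: np.dtype("u1")}
_DTYPE_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5,
                np.dtype("uint16"): 12, np.dtype("int16"): 2,
                np.dtype("int32"): 3, np.dtype("uint8"): 1}


def _parse_envi_header(path: str) -> dict:
    with open(path, "r") as fh:
        text = fh.read()
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError(f"{path}: not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    # key = value, where a { value may span lines until its closing }
    body = text.lstrip()[4:]
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i]
        i += 1
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            parts = [val]
            while i < len(lines):
                parts.append(lines[i])
                if "}" in lines[i]:
                    i += 1
                    break
                i += 1
            val = " ".join(parts)
        fields[key] = val
    return fields


def read_cube(path: str, format: str = "envi") -> Hypercube:
    """Read an ENVI header/binary pair written by :func:`write_cube`.

    ``path`` may point at either the ``.hdr`` or the binary payload; both
    band-sequential (bsq) and band-interleaved-by-pixel (bip) layouts are
    accepted.  Header/payload inconsistencies raise ``ValueError`` naming the
    offending field.
    """
    if format != "envi":
        raise ValueError(f"unsupported format {format!r}")
    if path.endswith(".hdr"):
        hdr_path, bin_path = path, path[:-4]
    else:
        hdr_path, bin_path = path + ".hdr", path
    if not os.path.exists(hdr_path):
        raise FileNotFoundError(hdr_path)
    if not os.path.exists(bin_path):
        raise FileNotFoundError(bin_path)
    h = _parse_envi_header(hdr_path)

    def _intfield(name: str) -> int:
        if name not in h:
            raise ValueError(f"{hdr_path}: missing required header field '{name}'")
        return int(h[name])

    lines, samples, bands = _intfield("lines"), _intfield("samples"), _intfield("bands")
    code = _intfield("data type")
    if code not in _ENVI_DTYPES:
        raise ValueError(f"{hdr_path}: unsupported 'data type' code {code}")
    dtype = _ENVI_DTYPES[code]
    interleave = h.get("interleave", "bsq").strip().lower()
    if interleave not in ("bsq", "bip"):
        raise ValueError(f"{hdr_path}: unsupported 'interleave' {interleave!r}")

    if "wavelength" not in h:
        raise ValueError(f"{hdr_path}: missing 'wavelength' field")
    wl_text = h["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(tok) for tok in wl_text.replace(",", " ").split()])
    if len(wavelengths) != bands:
        raise ValueError(
            f"{hdr_path}: field 'wavelength' lists {len(wavelengths)} values "
            f"but 'bands' declares {bands}"
        )

    n_expected = lines * samples * bands
    flat = np.fromfile(bin_path, dtype=dtype)
    if flat.size != n_expected:
        raise ValueError(
            f"{bin_path}: payload holds {flat.size} values but header "
            f"(lines x samples x bands) implies {n_expected}"
        )
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:  # bip: band axis fastest
        data = flat.reshape(lines, samples, bands)
    kind = h.get("hsimoist kind", "raw").strip()
    if kind not in ("raw", "reflectance", "absorbance"):
        kind = "raw"
    return Hypercube(np.ascontiguousarray(data), wavelengths, kind=kind)


def write_cube(cube: Hypercube, path: str) -> None:
    """Write ``cube`` as an ENVI band-sequential header/binary pair.

    ``path`` names the binary payload; ``path + '.hdr'`` receives the header.
    Round-trips bit-for-bit through :func:`read_cube` for supported dtypes.
    """
    dtype = cube.data.dtype
    if dtype not in _DTYPE_CODES:
        dtype = np.dtype("float64")
    code = _DTYPE_CODES[np.dtype(dtype)]
    rows, cols, bands = cube.shape
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"hsimoist kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(path + ".hdr", "w") as fh:
        fh.write(header)
    # bsq layout: band-major
    payload = np.ascontiguousarray(
        cube.data.transpose(2, 0, 1), dtype=_ENVI_DTYPES[code]
    )
    payload.tofile(path)


# ---------------------------------------------------------------------------
# Radiometric calibration


def calibrate(
    raw: Hypercube,
    refs: ReferenceFrames,
    eps: float = 1e-9,
    return_summary: bool = False,
):
    """Convert raw counts to reflectance: ``(raw - dark) / (white - dark)``.

    Where ``white - dark <= eps`` the pixel is treated as dead: the output is
    set to 0 and the voxel counted in the calibration summary.  Values outside
    [0, 1] (specular highlights, noise undershoot) are permitted and counted.
    """
    if raw.kind != "raw":
        raise ValueError(f"calibrate expects kind='raw', got {raw.kind!r}")
    white = refs.white
    dark = refs.dark
    if white.ndim == 1:
        if len(white) != raw.n_bands:
            raise ValueError("per-band reference length does not match cube bands")
        white = white[None, None, :]
        dark = dark[None, None, :]
    elif white.shape != raw.shape:
        raise ValueError("reference frame shape does not match cube shape")

    denom = white - dark
    dead = denom <= eps
    safe = np.where(dead, 1.0, denom)
    out = (raw.data.astype(float) - dark) / safe
    out = np.where(np.broadcast_to(dead, out.shape), 0.0, out)

    summary = CalibrationSummary(
        n_dead=int(np.broadcast_to(dead, out.shape).sum()),
        n_above_one=int((out > 1.0).sum()),
        n_below_zero=int((out < 0.0).sum()),
    )
    summary.dead_fraction = summary.n_dead / out.size
    cube = Hypercube(out, raw.wavelengths_nm, kind="reflectance")
    if return_summary:
        return cube, summary
    return cube


def rgb_reconstruction(
    cube: Hypercube,
    bands_nm: tuple[float, float, float] = (650.0, 550.0, 450.0),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """3-channel display image from the grid bands nearest 650/550/450 nm.

    Each channel is min-max scaled, over the mask when given, else over the
    full frame.  Returns a float array in [0, 1], shape (rows, cols, 3).
    """
    if cube.kind != "reflectance":
        raise ValueError("rgb_reconstruction expects a reflectance cube")
    lo, hi = cube.wavelengths_nm[0], cube.wavelengths_nm[-1]
    for b in bands_nm:
        if not (lo <= b <= hi):
            raise ValueError(
                f"display band {b} nm outside wavelength grid [{lo}, {hi}] nm"
            )
    out = np.zeros(cube.shape[:2] + (3,), dtype=float)
    for ch, b in enumerate(bands_nm):
        plane = cube.data[:, :, cube.band_index(b)].astype(float)
        region = plane[mask] if mask is not None else plane
        pmin, pmax = float(region.min()), float(region.max())
        if pmax > pmin:
            out[:, :, ch] = np.clip((plane - pmin) / (pmax - pmin), 0.0, 1.0)
        # constant plane stays 0 (uniform colour)
    return out
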