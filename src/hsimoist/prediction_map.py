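"""Pixel-wise moisture maps: unfold, predict, refold, render.

The hypercube is unfolded into a pixels x wavelengths table (keeping each
pixel's coordinates), every masked pixel spectrum is pushed through the fitted
model's pre-processing chain and linear form, and the predictions are
reassembled into a 2-D map rendered on a linear color scale beside the RGB
reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hypercube import Hypercube, rgb_reconstruction
from .plsr import PLSRResults
from .segmentation import Mask, to_absorbance

__all__ = ["PredictionMap", "unfold", "refold", "predict_pixels", "render"]


@dataclass
class PredictionMap:
    """2-D moisture map (%), finite exactly on the mask, NaN elsewhere."""

    values: np.ndarray
    mask: Mask
    scale_range: tuple[float, float]
    model_id: str = ""
    n_failed_pixels: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.grid.shape:
            raise ValueError("map and mask shapes differ")
        lo, hi = self.scale_range
        if not lo < hi:
            raise ValueError("scale_range lo must be < hi")

    @property
    def foreground_values(self) -> np.ndarray:
        vals = self.values[self.mask.grid]
        return vals[np.isfinite(vals)]


def unfold(cube: Hypercube, mask: Mask) -> dict:
    """Masked pixels as a flat table: coordinate arrays plus a
    (n_pixels, n_bands) spectrum matrix, in deterministic row-major order.

    An empty mask yields an empty table, not an error.
    """
    if mask.grid.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    rows, cols = np.nonzero(mask.grid)  # nonzero scans row-major
    return {
        "rows": rows,
        "cols": cols,
        "spectra": cube.data[rows, cols, :],
        "shape": cube.shape[:2],
        "wavelengths_nm": cube.wavelengths_nm,
    }


def refold(table: dict, values: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`unfold`.

    With ``values`` given, scatters the per-pixel vector into a 2-D grid
    (NaN outside the mask); without, rebuilds the masked voxels of the cube.
    """
    shape = table["shape"]
    if values is not None:
        out = np.full(shape, np.nan)
        out[table["rows"], table["cols"]] = values
        return out
    n_bands = table["spectra"].shape[1]
    out = np.zeros(shape + (n_bands,))
    out[table["rows"], table["cols"], :] = table["spectra"]
    return out


def predict_pixels(
    table: dict,
    results: PLSRResults,
    scale_range: tuple[float, float] | None = None,
) -> PredictionMap:
    """Apply a fitted model to every unfolded pixel and refold into a map.

    Pixels on which the pre-processing chain fails (e.g. a constant spectrum
    under SNV) are set undefined and counted, never fatal.  The default color
    scale spans the 2nd-98th percentile of the predictions, rounded outward to
    whole percent.
    """
    spectra = np.asarray(table["spectra"], dtype=float)
    n_pix = spectra.shape[0]
    preds = np.full(n_pix, np.nan)
    n_failed = 0
    if n_pix:
        try:
            preds = results.predict(spectra, table.get("wavelengths_nm"))
        except ValueError as err:
            if "mismatch" in str(err):
                raise
            # chain failed on some row: fall back to per-pixel application
            for i in range(n_pix):
                try:
                    preds[i] = results.predict(spectra[i])
                except ValueError:
                    n_failed += 1
    if n_failed:
        warnings.warn(f"{n_failed} pixels failed the pre-processing chain",
                      stacklevel=2)

    grid = np.zeros(table["shape"], dtype=bool)
    grid[table["rows"], table["cols"]] = True
    values = refold(table, preds)
    if scale_range is None:
        finite = preds[np.isfinite(preds)]
        if finite.size:
            lo = float(np.floor(np.percentile(finite, 2)))
            hi = float(np.ceil(np.percentile(finite, 98)))
            if lo == hi:
                lo, hi = lo - 1.0, hi + 1.0
        else:
            lo, hi = 0.0, 100.0
        scale_range = (lo, hi)
    return PredictionMap(
        values=values,
        mask=Mask(grid),
        scale_range=scale_range,
        n_failed_pixels=n_failed,
    )


def map_cube(
    cube: Hypercube,
    mask: Mask,
    results: PLSRResults,
    scale_range: tuple[float, float] | None = None,
) -> PredictionMap:
    """Convenience: unfold, convert domain if the model needs absorbance,
    predict, refold."""
    work = cube
    if results.domain == "absorbance" and cube.kind == "reflectance":
        work = to_absorbance(cube)
    elif results.domain != work.kind:
        raise ValueError(
            f"model domain {results.domain!r} incompatible with cube kind {cube.kind!r}"
        )
    return predict_pixels(unfold(work, mask), results, scale_range)


def render(
    pmap: PredictionMap,
    rgb: np.ndarray | None = None,
    path: str | None = None,
    cmap: str = "viridis",
    title: str = "Predicted moisture (%)",
):
    """Side-by-side panel: RGB reconstruction and the color-mapped moisture
    map with a labeled color bar over ``scale_range``.

    Out-of-range predictions are clipped to the scale ends and counted in the
    returned info dict; background pixels render neutral (from the dimmed RGB
    when given).  Returns ``(figure, info)``; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = pmap.scale_range
    vals = pmap.values
    n_clipped = int(np.sum((vals < lo) | (vals > hi)))
    shown = np.clip(vals, lo, hi)

    n_panels = 2 if rgb is not None else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 4))
    axes = np.atleast_1d(axes)
    if rgb is not None:
        axes[0].imshow(rgb)
        axes[0].set_title("RGB reconstruction")
        axes[0].axis("off")
        background = rgb * 0.35  # dimmed RGB behind the map
        axes[-1].imshow(background)
    im = axes[-1].imshow(
        np.ma.masked_invalid(shown), cmap=cmap, vmin=lo, vmax=hi,
        interpolation="nearest",
    )
    axes[-1].set_title(title)
    axes[-1].axis("off")
    cbar = fig.colorbar(im, ax=axes[-1], fraction=0.046)
    cbar.set_label("moisture (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    info = {"n_clipped": n_clipped, "scale_range": (lo, hi),
            "n_failed_pixels": pmap.n_failed_pixels}
    return fig, info
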