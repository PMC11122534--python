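"""Kennard-Stone sample selection and the 2/3 : 1/3 calibration split.

Kennard-Stone starts from the pair of samples with the largest Euclidean
distance and then greedily adds the sample whose minimum distance to the
already-selected set is largest — covering the spectral hull with the
calibration set.  Ties are broken toward the lowest row index, so selection
is fully deterministic.  The block-constrained mode runs the selection on
per-piece mean spectra so that all 15 segments of a physical sausage land in
the same set (the split is "of complete sausages").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .segmentation import SpectrumSet

__all__ = ["SplitResult", "kennard_stone", "split_dataset"]

CAL_FRACTION = 2.0 / 3.0


@dataclass
class SplitResult:
    """Disjoint calibration/prediction id lists plus the selection order."""

    calibration_ids: list
    prediction_ids: list
    selection_order: list

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.prediction_ids):
            raise ValueError("calibration and prediction sets overlap")

    @property
    def n_cal(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_pred(self) -> int:
        return len(self.prediction_ids)


def kennard_stone(spectra, n_select: int) -> np.ndarray:
    """Greedy maximin selection of ``n_select`` row indices.

    The first two picks are the most distant pair (lower indices on ties);
    every further pick maximizes its minimum distance to the selected set.
    Prefix property: the first k picks are identical for any larger
    ``n_select``.
    """
    x = np.asarray(spectra, dtype=float)
    if x.ndim != 2:
        raise ValueError("spectra must be a 2-D matrix")
    n = x.shape[0]
    if not (2 <= n_select <= n):
        raise ValueError(f"n_select must be in [2, {n}], got {n_select}")

    d = cdist(x, x)
    # most distant pair; np.argmax scans row-major so ties fall to the
    # lexicographically smallest (i, j)
    flat = int(np.argmax(d))
    i, j = divmod(flat, n)
    if i > j:
        i, j = j, i
    selected = [i, j]
    # min distance of every point to the selected set
    mind = np.minimum(d[i], d[j])
    mind[selected] = -np.inf
    while len(selected) < n_select:
        k = int(np.argmax(mind))  # argmax takes the first (lowest) index on ties
        selected.append(k)
        mind = np.minimum(mind, d[k])
        mind[k] = -np.inf
    return np.array(selected, dtype=int)


def split_dataset(
    data: SpectrumSet,
    calibration_fraction: float = CAL_FRACTION,
    by_block: bool = False,
) -> SplitResult:
    """Kennard-Stone 2/3 : 1/3 split of a spectrum set.

    ``by_block=False`` selects ``floor(n * fraction)`` individual segment
    spectra for calibration.  ``by_block=True`` selects
    ``floor(n_blocks * fraction)`` whole pieces on their block-mean spectra;
    every segment follows its piece.
    """
    if data.n_samples == 0:
        raise ValueError("empty spectrum set")
    if not (0.0 < calibration_fraction < 1.0):
        raise ValueError("calibration_fraction must lie in (0, 1)")

    # floor of n*fraction; the tiny offset keeps exact ratios (1023 * 2/3 = 682)
    # from landing one below the integer through float rounding
    if not by_block:
        n_cal = int(np.floor(data.n_samples * calibration_fraction + 1e-9))
        n_cal = max(2, n_cal)
        order = kennard_stone(data.spectra, n_cal)
        cal = set(order.tolist())
        return SplitResult(
            calibration_ids=[data.sample_ids[i] for i in sorted(cal)],
            prediction_ids=[
                data.sample_ids[i] for i in range(data.n_samples) if i not in cal
            ],
            selection_order=[data.sample_ids[i] for i in order],
        )

    blocks = list(dict.fromkeys(data.block_ids))  # first-appearance order
    block_means = np.vstack(
        [
            data.spectra[[k for k, b in enumerate(data.block_ids) if b == blk]].mean(
                axis=0
            )
            for blk in blocks
        ]
    )
    n_cal_blocks = int(np.floor(len(blocks) * calibration_fraction + 1e-9))
    n_cal_blocks = max(2, min(n_cal_blocks, len(blocks) - 1))
    order = kennard_stone(block_means, n_cal_blocks)
    cal_blocks = {blocks[i] for i in order}
    return SplitResult(
        calibration_ids=[
            sid for sid, b in zip(data.sample_ids, data.block_ids) if b in cal_blocks
        ],
        prediction_ids=[
            sid
            for sid, b in zip(data.sample_ids, data.block_ids)
            if b not in cal_blocks
        ],
        selection_order=[blocks[i] for i in order],
    )
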