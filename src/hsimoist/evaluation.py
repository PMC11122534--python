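"""Model evaluation: R2 / RMSE metrics and the pre-treatment comparison grid.

For every (pre-processing chain, spectral domain) combination the grid fit
reports six figures: R2 and RMSE on the calibration set (R2c / RMSEC), on the
held-out prediction set (R2p / RMSEP) and under full cross-validation
(R2cv / RMSECV).  All prediction-set figures use only statistics frozen from
calibration — no recentring on prediction data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import STANDARD_CHAINS, PreprocessChain
from .plsr import MoisturePLSR, PLSRResults
from .segmentation import SpectrumSet, to_absorbance
from .splitting import SplitResult

__all__ = ["EvaluationReport", "r_squared", "rmse", "evaluate_grid", "reports_to_frame",
           "scatter_table"]


def r_squared(y_true, y_pred, definition: str = "one_minus_ss") -> float:
    """Coefficient of determination, ``1 - SS_res / SS_tot`` (default).

    ``SS_tot`` is taken about the mean of ``y_true``; this definition keeps R2
    consistent with RMSE and penalizes bias.  ``definition="pearson_sq"``
    gives the squared-correlation variant for comparison.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if len(y_true) < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant; R2 undefined")
    if definition == "pearson_sq":
        return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    if definition != "one_minus_ss":
        raise ValueError(f"unknown R2 definition {definition!r}")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def rmse(y_true, y_pred) -> float:
    """Root mean square error, same units as the inputs (%)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if len(y_true) == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


@dataclass
class EvaluationReport:
    """One grid row: six metrics for a chain x domain combination."""

    chain_label: str
    domain: str
    n_latent: int
    n_cal: int
    n_pred: int
    r2_cal: float
    rmsec: float
    r2_pred: float
    rmsep: float
    r2_cv: float
    rmsecv: float
    results: PLSRResults | None = None

    def __post_init__(self) -> None:
        for name in ("rmsec", "rmsep", "rmsecv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cannot be negative")
        for name in ("r2_cal", "r2_pred", "r2_cv"):
            if getattr(self, name) > 1 + 1e-12:
                raise ValueError(f"{name} cannot exceed 1")


def _index_of(data: SpectrumSet, ids) -> np.ndarray:
    pos = {sid: k for k, sid in enumerate(data.sample_ids)}
    return np.array([pos[sid] for sid in ids], dtype=int)


def evaluate_grid(
    data: SpectrumSet,
    split: SplitResult,
    chains: dict[str, list[str]] | None = None,
    domains: tuple[str, ...] = ("reflectance", "absorbance"),
    max_lv: int | None = None,
    cv_scheme: str = "loo",
) -> list[EvaluationReport]:
    """Fit and score every chain x domain combination on a fixed split.

    ``data`` must be in reflectance; the absorbance rows are derived from it.
    Deterministic given data and split.
    """
    if data.reference_moisture_pct is None:
        raise ValueError("reference moisture required for evaluation")
    if data.domain != "reflectance":
        raise ValueError("evaluate_grid expects reflectance input")
    if chains is None:
        chains = STANDARD_CHAINS
    cal_idx = _index_of(data, split.calibration_ids)
    pred_idx = _index_of(data, split.prediction_ids)

    reports: list[EvaluationReport] = []
    for domain in domains:
        dset = data if domain == "reflectance" else to_absorbance(data)
        cal = dset.subset(cal_idx)
        pred = dset.subset(pred_idx)
        for label, steps in chains.items():
            model = MoisturePLSR.from_spectrum_set(cal, PreprocessChain(list(steps)))
            cv = model.cross_validate(max_lv=max_lv, scheme=cv_scheme)
            res = model.fit(n_latent=cv.chosen_lv)
            res.cv_report = cv
            y_pred_hat = res.predict(pred.spectra)
            reports.append(
                EvaluationReport(
                    chain_label=label,
                    domain=domain,
                    n_latent=res.n_latent,
                    n_cal=cal.n_samples,
                    n_pred=pred.n_samples,
                    r2_cal=res.r2_cal,
                    rmsec=res.rmsec,
                    r2_pred=r_squared(pred.reference_moisture_pct, y_pred_hat),
                    rmsep=rmse(pred.reference_moisture_pct, y_pred_hat),
                    r2_cv=r_squared(cal.reference_moisture_pct, cv.cv_predictions),
                    rmsecv=cv.rmsecv,
                    results=res,
                )
            )
    return reports


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Comparison table mirroring the standard chemometrics report layout."""
    return pd.DataFrame(
        [
            {
                "domain": r.domain,
                "treatment": r.chain_label,
                "n_latent": r.n_latent,
                "R2c": r.r2_cal,
                "RMSEC_pct": r.rmsec,
                "R2p": r.r2_pred,
                "RMSEP_pct": r.rmsep,
                "R2cv": r.r2_cv,
                "RMSECV_pct": r.rmsecv,
            }
            for r in reports
        ]
    )


def scatter_table(
    data: SpectrumSet, split: SplitResult, results: PLSRResults
) -> pd.DataFrame:
    """Measured-vs-predicted table for the scatter plot (one row per sample,
    tagged calibration/prediction)."""
    if data.reference_moisture_pct is None:
        raise ValueError("reference moisture required")
    spectra = data.spectra
    if data.domain != results.domain:
        if results.domain == "absorbance" and data.domain == "reflectance":
            spectra = to_absorbance(data).spectra
        else:
            raise ValueError("domain mismatch between data and model")
    preds = results.predict(spectra)
    setname = {sid: "calibration" for sid in split.calibration_ids}
    setname.update({sid: "prediction" for sid in split.prediction_ids})
    return pd.DataFrame(
        {
            "sample_id": data.sample_ids,
            "measured_pct": data.reference_moisture_pct,
            "predicted_pct": preds,
            "set": [setname.get(sid, "unsplit") for sid in data.sample_ids],
        }
    )
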