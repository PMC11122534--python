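"""Partial least squares regression (NIPALS, single response) for moisture.

The model projects mean-centered spectra onto latent variables that maximize
covariance with the (mean-centered) moisture response, then collapses the
decomposition to the linear form

    moisture = sum_i  x_i * b_i  +  A

where ``x_i`` is the pre-processed spectral value at wavelength i, ``b_i`` the
regression coefficient and ``A`` the intercept.  With as many latent variables
as the rank of X the fit coincides with ordinary least squares on the centered
data; fewer latent variables regularize.

Organisation follows the model/results convention: :class:`MoisturePLSR` is
built from data and configuration, ``fit()`` returns a :class:`PLSRResults`
carrying estimates, diagnostics and ``summary()``; cross-validation hangs off
the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import PreprocessChain
from .segmentation import SpectrumSet

__all__ = ["MoisturePLSR", "PLSRResults", "CVReport", "nipals_pls1"]

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500
OUTLIER_SIGMA = 3.0


def nipals_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
) -> dict:
    """NIPALS decomposition for a single response; X is deflated, y is not.

    Parameters are the *centered* matrices.  Returns weights W, loadings P,
    response loadings q and scores T, truncated early if a residual direction
    degenerates (covariance below ``tol``).
    """
    X = np.array(X, dtype=float, copy=True)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    a = 0
    for a in range(n_components):
        w = X.T @ y
        # for one response the weight direction is closed-form; the iteration
        # cap applies to the degenerate-restart loop of the multi-Y case and
        # is kept for interface parity
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < tol:
            break
        p_load = X.T @ t / tt
        q = float(y @ t / tt)
        X -= np.outer(t, p_load)
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_load, q, t
        a += 1
    return {"W": W[:, :a], "P": P[:, :a], "q": Q[:a], "T": T[:, :a], "n_components": a}


def _collapse(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """Coefficient vector of the first ``a`` latent variables:
    B = W_a (P_a' W_a)^{-1} q_a."""
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


@dataclass
class CVReport:
    """Cross-validation outcome: RMSECV per candidate latent count, the chosen
    count (smallest at ties), held-out residuals and outlier flags."""

    rmsecv_by_lv: np.ndarray
    chosen_lv: int
    residuals: np.ndarray
    cv_predictions: np.ndarray
    outlier_flags: np.ndarray
    scheme: str

    @property
    def rmsecv(self) -> float:
        return float(self.rmsecv_by_lv[self.chosen_lv - 1])


class MoisturePLSR:
    """PLSR model of moisture (%) against pre-processed spectra.

    Parameters
    ----------
    spectra : ndarray (n_samples, n_bands)
        Raw reflectance or absorbance spectra (the pre-processing chain is
        applied internally).
    moisture_pct : ndarray (n_samples,)
        Reference moisture, %.
    wavelengths_nm : ndarray (n_bands,)
    chain : PreprocessChain, optional
        Pre-treatment applied before centering; fitted on this data at
        ``fit()`` time if it carries state (MSC).
    domain : {"reflectance", "absorbance"}
    block_ids : sequence, optional
        Piece labels enabling leave-one-block-out cross-validation.
    """

    def __init__(
        self,
        spectra,
        moisture_pct,
        wavelengths_nm,
        chain: PreprocessChain | None = None,
        domain: str = "reflectance",
        block_ids=None,
        sample_ids=None,
    ):
        self.X_raw = np.asarray(spectra, dtype=float)
        self.y = np.asarray(moisture_pct, dtype=float).ravel()
        self.wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        if self.X_raw.ndim != 2:
            raise ValueError("spectra must be 2-D")
        if self.X_raw.shape[0] != len(self.y):
            raise ValueError("spectra rows and moisture length disagree")
        if self.X_raw.shape[1] != len(self.wavelengths_nm):
            raise ValueError("spectra columns and wavelength grid disagree")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("moisture values must be finite")
        self.chain = chain if chain is not None else PreprocessChain([])
        self.domain = domain
        self.block_ids = None if block_ids is None else list(block_ids)
        self.sample_ids = (
            list(sample_ids)
            if sample_ids is not None
            else list(range(self.X_raw.shape[0]))
        )

    @classmethod
    def from_spectrum_set(
        cls, data: SpectrumSet, chain: PreprocessChain | None = None
    ) -> "MoisturePLSR":
        if data.reference_moisture_pct is None:
            raise ValueError("spectrum set carries no reference moisture")
        return cls(
            data.spectra,
            data.reference_moisture_pct,
            data.wavelengths_nm,
            chain=chain,
            domain=data.domain,
            block_ids=data.block_ids,
            sample_ids=data.sample_ids,
        )

    @property
    def n_samples(self) -> int:
        return self.X_raw.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X_raw.shape[1]

    def default_max_lv(self) -> int:
        return int(min(20, self.n_samples - 1, self.n_bands))

    # -- fitting ------------------------------------------------------------

    def _preprocessed(self) -> np.ndarray:
        chain = self.chain
        if chain.needs_fit and not chain.is_fitted:
            chain.fit(self.X_raw, self.wavelengths_nm)
        return chain.apply(self.X_raw, self.wavelengths_nm)

    def fit(self, n_latent: int | None = None, cv_scheme: str = "loo") -> "PLSRResults":
        """Fit the model; if ``n_latent`` is omitted it is chosen by
        cross-validation (minimum RMSECV, smaller count at ties)."""
        cv = None
        if n_latent is None:
            cv = self.cross_validate(scheme=cv_scheme)
            n_latent = cv.chosen_lv
        Xp = self._preprocessed()
        if n_latent > min(self.n_samples - 1, self.n_bands):
            raise ValueError(
                f"n_latent={n_latent} exceeds min(n_samples-1, n_bands)="
                f"{min(self.n_samples - 1, self.n_bands)}"
            )
        x_mean = Xp.mean(axis=0)
        y_mean = float(self.y.mean())
        Xc = Xp - x_mean
        if not np.any(Xc):
            raise ValueError("degenerate spectra: zero total variance after centering")
        dec = nipals_pls1(Xc, self.y - y_mean, n_latent)
        a = dec["n_components"]
        coef = _collapse(dec["W"], dec["P"], dec["q"], a)
        intercept = y_mean - float(x_mean @ coef)
        return PLSRResults(
            model=self,
            coefficients=coef,
            intercept=intercept,
            n_latent=a,
            x_mean=x_mean,
            y_mean=y_mean,
            decomposition=dec,
            cv_report=cv,
        )

    # -- cross-validation ---------------------------------------------------

    def _folds(self, scheme: str):
        n = self.n_samples
        if scheme == "loo":
            return [np.array([i]) for i in range(n)]
        if scheme == "leave-one-block-out":
            if self.block_ids is None:
                raise ValueError("leave-one-block-out requires block_ids")
            blocks = list(dict.fromkeys(self.block_ids))
            return [
                np.array([i for i, b in enumerate(self.block_ids) if b == blk])
                for blk in blocks
            ]
        raise ValueError(f"unknown cross-validation scheme {scheme!r}")

    def cross_validate(
        self,
        max_lv: int | None = None,
        scheme: str = "loo",
        outlier_sigma: float = OUTLIER_SIGMA,
    ) -> CVReport:
        """Full cross-validation: per fold, the chain state (MSC reference)
        and centering are refit on the training part only; held-out residuals
        accumulate RMSECV per latent count.  Samples whose held-out residual
        exceeds ``outlier_sigma * RMSECV`` at the chosen count are flagged as
        spectral outliers (reported, never auto-removed)."""
        folds = self._folds(scheme)
        n = self.n_samples
        min_train = min(n - len(f) for f in folds)
        if min_train < 2:
            raise ValueError("a cross-validation fold leaves < 2 training samples")
        if max_lv is None:
            max_lv = int(min(20, min_train - 1, self.n_bands))
        max_lv = int(min(max_lv, min_train - 1, self.n_bands))
        if max_lv < 1:
            raise ValueError("max_lv must be >= 1")

        preds = np.full((n, max_lv), np.nan)
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            chain = PreprocessChain(
                steps=list(self.chain.steps),
                sg_window=self.chain.sg_window,
                sg_polyorder=self.chain.sg_polyorder,
            )
            chain.fit(self.X_raw[train_idx], self.wavelengths_nm)
            Xp_tr = chain.apply(self.X_raw[train_idx], self.wavelengths_nm)
            Xp_te = chain.apply(self.X_raw[test_idx], self.wavelengths_nm)
            x_mean = Xp_tr.mean(axis=0)
            y_mean = float(self.y[train_idx].mean())
            dec = nipals_pls1(Xp_tr - x_mean, self.y[train_idx] - y_mean, max_lv)
            for a in range(1, max_lv + 1):
                aa = min(a, dec["n_components"])
                if aa == 0:
                    preds[test_idx, a - 1] = y_mean
                    continue
                coef = _collapse(dec["W"], dec["P"], dec["q"], aa)
                preds[test_idx, a - 1] = (Xp_te - x_mean) @ coef + y_mean

        resid = self.y[:, None] - preds
        rmsecv_by_lv = np.sqrt(np.mean(resid**2, axis=0))
        chosen = int(np.argmin(rmsecv_by_lv)) + 1  # first minimum -> smaller lv
        residuals = resid[:, chosen - 1]
        rmsecv = rmsecv_by_lv[chosen - 1]
        flags = np.abs(residuals) > outlier_sigma * rmsecv
        return CVReport(
            rmsecv_by_lv=rmsecv_by_lv,
            chosen_lv=chosen,
            residuals=residuals,
            cv_predictions=preds[:, chosen - 1],
            outlier_flags=flags,
            scheme=scheme,
        )


@dataclass
class PLSRResults:
    """Fitted PLSR: collapsed coefficients + intercept bound to a wavelength
    grid, a domain and a (frozen) pre-processing chain."""

    model: MoisturePLSR | None
    coefficients: np.ndarray
    intercept: float
    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    decomposition: dict | None = None
    cv_report: CVReport | None = None
    chain: PreprocessChain = field(default=None)  # type: ignore[assignment]
    wavelengths_nm: np.ndarray = field(default=None)  # type: ignore[assignment]
    domain: str = ""

    def __post_init__(self) -> None:
        if self.model is not None:
            self.chain = self.model.chain
            self.wavelengths_nm = self.model.wavelengths_nm
            self.domain = self.model.domain
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        if len(self.coefficients) != len(self.wavelengths_nm):
            raise ValueError("coefficient vector does not match wavelength grid")

    # -- prediction ----------------------------------------------------------

    def predict(self, spectra, wavelengths_nm=None, domain: str | None = None):
        """Predicted moisture (%) for raw (un-preprocessed) spectra.

        The fitted chain is applied, then the collapsed linear form.  If a
        wavelength grid or domain is supplied it must match the model's.
        """
        if wavelengths_nm is not None:
            wl = np.asarray(wavelengths_nm, dtype=float)
            if len(wl) != len(self.wavelengths_nm) or not np.allclose(
                wl, self.wavelengths_nm
            ):
                raise ValueError(
                    "wavelength grid mismatch: model expects "
                    f"[{self.wavelengths_nm[0]}..{self.wavelengths_nm[-1]}] nm x "
                    f"{len(self.wavelengths_nm)} bands, got "
                    f"[{wl[0]}..{wl[-1]}] nm x {len(wl)}"
                )
        if domain is not None and domain != self.domain:
            raise ValueError(f"domain mismatch: model is {self.domain!r}, got {domain!r}")
        x = np.asarray(spectra, dtype=float)
        one_d = x.ndim == 1
        xp = self.chain.apply(x, self.wavelengths_nm)
        out = xp @ self.coefficients + self.intercept
        return float(out[0]) if one_d else out

    @property
    def fittedvalues(self) -> np.ndarray:
        if self.model is None:
            raise ValueError("results were deserialized without training data")
        return self.predict(self.model.X_raw)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    @property
    def rmsec(self) -> float:
        return float(np.sqrt(np.mean(self.resid**2)))

    @property
    def r2_cal(self) -> float:
        y = self.model.y
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(self.resid**2)) / ss_tot

    def summary(self) -> str:
        lines = [
            "PLSR moisture model",
            "=" * 46,
            f"domain:            {self.domain}",
            f"pre-processing:    {' -> '.join(self.chain.steps) or '(none)'}",
            f"bands:             {len(self.wavelengths_nm)} "
            f"({self.wavelengths_nm[0]:g}-{self.wavelengths_nm[-1]:g} nm)",
            f"latent variables:  {self.n_latent}",
            f"intercept (A):     {self.intercept:.4f} %",
        ]
        if self.model is not None:
            lines += [
                f"n (calibration):   {self.model.n_samples}",
                f"R2 calibration:    {self.r2_cal:.4f}",
                f"RMSEC:             {self.rmsec:.4f} %",
            ]
        if self.cv_report is not None:
            lines += [
                f"{'RMSECV (' + self.cv_report.scheme + '):':<19}"
                f"{self.cv_report.rmsecv:.4f} %",
                f"flagged outliers:  {int(self.cv_report.outlier_flags.sum())}",
            ]
        return "\n".join(lines)

    # -- serialization --------------------------------------------------------

    FORMAT_VERSION = 1

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "format_version": self.FORMAT_VERSION,
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "domain": self.domain,
            "chain": self.chain.to_dict(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "n_latent": self.n_latent,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "PLSRResults":
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        return cls(
            model=None,
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            n_latent=int(payload["n_latent"]),
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            y_mean=float(payload["y_mean"]),
            chain=PreprocessChain.from_dict(payload["chain"]),
            wavelengths_nm=np.asarray(payload["wavelengths_nm"], dtype=float),
            domain=payload["domain"],
        )
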