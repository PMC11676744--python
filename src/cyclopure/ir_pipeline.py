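"""Mid-IR quantification pipeline: normalisation, AsLS baseline correction,
alkyne-band-area calibration and PLS calibration with contiguous-block CV.

The linear peptide carries terminal alkyne/azide groups whose stretch bands
fall in 2040-2170 cm^-1, a window empty in the cyclic isomer's spectrum.
Quantification therefore proceeds either univariately (integrated area of
that band vs. molar ratio) or multivariately (PLS1 on the full spectrum).

Baseline drift, mostly from scattering, is removed with asymmetric least
squares (AsLS): a Whittaker smoother whose residual weights are iterated to
``p`` above the baseline (peaks) and ``1 - p`` below it (noise), so the
smooth component hugs the spectrum's lower envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import solveh_banded
from sklearn.cross_decomposition import PLSRegression

from .exceptions import ConfigurationError, ExtrapolationError

__all__ = [
    "IRSpectrum",
    "IRDataset",
    "AslsParams",
    "PLSModel",
    "normalise_mean",
    "whittaker_asls",
    "asls_baseline",
    "tune_asls",
    "band_area",
    "band_maximum",
    "fit_pls",
    "ALKYNE_WINDOW",
]

#: Wavenumber window (cm^-1) of the linear-peptide-specific alkyne/azide band.
ALKYNE_WINDOW = (2040.0, 2170.0)


@dataclass(frozen=True)
class IRSpectrum:
    """One absorbance spectrum on a strictly increasing wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    ratio: float | None = None

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)
        if w.shape != a.shape or w.ndim != 1:
            raise ConfigurationError("wavenumbers and absorbance must be equal-length 1-D")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ConfigurationError("wavenumber grid must be strictly increasing")


@dataclass
class IRDataset:
    """A stack of spectra sharing one grid; rows of the calibration matrix X."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray  # shape (n_samples, n_channels)
    sample_ids: list[str]
    ratios: np.ndarray
    replicates: np.ndarray

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=int)
        n, k = self.absorbance.shape
        if k != self.wavenumbers.size:
            raise ConfigurationError("absorbance columns must match grid length")
        if not (len(self.sample_ids) == self.ratios.size == self.replicates.size == n):
            raise ConfigurationError("metadata length must match number of spectra")
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ConfigurationError("wavenumber grid must be strictly increasing")

    def __len__(self):
        return self.absorbance.shape[0]

    def spectrum(self, i: int) -> IRSpectrum:
        return IRSpectrum(
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[i],
            sample_id=self.sample_ids[i],
            ratio=float(self.ratios[i]),
        )

    def spectra(self):
        return [self.spectrum(i) for i in range(len(self))]

    def with_absorbance(self, absorbance: np.ndarray) -> "IRDataset":
        return IRDataset(
            wavenumbers=self.wavenumbers,
            absorbance=absorbance,
            sample_ids=list(self.sample_ids),
            ratios=self.ratios.copy(),
            replicates=self.replicates.copy(),
        )


@dataclass(frozen=True)
class AslsParams:
    """AsLS settings: lam = smoothness penalty, p = asymmetry in (0, 1)."""

    lam: float = 1e4
    p: float = 0.001
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self):
        if not self.lam > 0:
            raise ConfigurationError("lam must be > 0")
        if not 0 < self.p < 1:
            raise ConfigurationError("p must lie in (0, 1)")


def normalise_mean(spectrum: IRSpectrum) -> IRSpectrum:
    """Divide a spectrum by its mean absorbance (output mean is exactly 1)."""
    m = float(spectrum.absorbance.mean())
    if abs(m) < 1e-300:
        raise ConfigurationError(
            f"cannot normalise spectrum {spectrum.sample_id!r}: mean absorbance is zero"
        )
    return replace(spectrum, absorbance=spectrum.absorbance / m)


def whittaker_asls(
    y: np.ndarray,
    lam: float,
    p: float,
    max_iter: int = 50,
    tol: float = 1e-6,
):
    """Asymmetric least squares baseline on a raw vector.

    Iterates z = argmin sum w_i (y_i - z_i)^2 + lam * sum (D2 z)^2 with
    w_i = p where y_i > z_i else 1 - p, until the weight vector changes by
    less than ``tol`` (sup norm) or ``max_iter`` passes.

    Returns
    -------
    (z, w)
        The baseline and the weight vector used in its final solve, so the
        frozen-weight system can be re-solved independently.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ConfigurationError("AsLS requires a 1-D signal of length >= 5")
    if not np.all(np.isfinite(y)):
        raise ConfigurationError("AsLS input contains non-finite values")
    n = y.size
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (d2.T @ d2)
    # the system (diag(w) + lam * D2'D2) is pentadiagonal SPD: solve banded
    ab = np.zeros((3, n))
    ab[0, 2:] = penalty.diagonal(2)
    ab[1, 1:] = penalty.diagonal(1)
    pen0 = penalty.diagonal(0)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        ab[2, :] = pen0 + w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.max(np.abs(w_new - w)) < tol:
            break
        w = w_new
    return z, w


def asls_baseline(spectrum: IRSpectrum, params: AslsParams | None = None):
    """AsLS baseline of one spectrum; returns (baseline, corrected spectrum)."""
    params = params or AslsParams()
    z, _ = whittaker_asls(
        spectrum.absorbance, params.lam, params.p, params.max_iter, params.tol
    )
    return z, replace(spectrum, absorbance=spectrum.absorbance - z)


def _negative_fraction(corrected: np.ndarray) -> float:
    """|most negative point| over max corrected height, pooled over spectra."""
    peak = float(corrected.max())
    if peak <= 0:
        return np.inf
    return max(0.0, -float(corrected.min())) / peak


def tune_asls(
    spectra,
    p_candidates,
    lam_candidates,
    y,
    max_lv: int = 10,
    n_splits: int | None = None,
    neg_tol_frac: float = 0.02,
    pairs=None,
):
    """Pick (p, lam) by PLS cross-validation over a candidate grid.

    Candidates are the cross product of ``p_candidates`` and
    ``lam_candidates`` (or the explicit ``pairs`` list when given).  Every
    (p, lam) pair is applied to all spectra; pairs whose corrected spectra
    dip below ``-neg_tol_frac * max height`` are flagged as over-corrected
    and excluded from selection.  Among the rest, the pair whose corrected
    matrix gives the lowest PLS RMSECV wins.

    Returns
    -------
    (AslsParams, pandas.DataFrame)
        Winning parameters and a diagnostics table with one row per
        candidate (p, lam, rmsecv, n_lv, neg_fraction, flagged).
    """
    if isinstance(spectra, IRDataset):
        spectra = spectra.spectra()
    spectra = list(spectra)
    y = np.asarray(y, dtype=float)
    if pairs is not None:
        candidates = sorted({(float(p), float(lam)) for p, lam in pairs})
    else:
        candidates = sorted(set(product((float(p) for p in p_candidates),
                                        (float(l) for l in lam_candidates))))
    if not candidates:
        raise ConfigurationError("no AsLS candidates given")
    rows = []
    for p, lam in candidates:
        params = AslsParams(lam=lam, p=p)
        corrected = np.vstack(
            [asls_baseline(s, params)[1].absorbance for s in spectra]
        )
        neg = max(_negative_fraction(row) for row in corrected)
        flagged = neg > neg_tol_frac
        model = fit_pls(corrected, y, max_lv=max_lv, n_splits=n_splits)
        rows.append(
            {"p": p, "lam": lam, "rmsecv": model.rmsecv, "n_lv": model.n_lv,
             "neg_fraction": neg, "flagged": flagged}
        )
    table = pd.DataFrame(rows)
    ok = table[~table["flagged"]]
    if ok.empty:
        raise ConfigurationError(
            "all AsLS candidates produce negative corrected intensities beyond "
            f"tolerance {neg_tol_frac:.2%}:\n{table.to_string(index=False)}"
        )
    best = ok.sort_values(["rmsecv", "lam", "p"]).iloc[0]
    return AslsParams(lam=float(best["lam"]), p=float(best["p"])), table


def band_area(spectrum: IRSpectrum, window=ALKYNE_WINDOW) -> float:
    """Trapezoidal integral of absorbance over a wavenumber window.

    The window edges are included by linear interpolation, so a unit
    absorbance over exactly the default window integrates to 130
    (absorbance * cm^-1).
    """
    lo, hi = float(window[0]), float(window[1])
    w, a = spectrum.wavenumbers, spectrum.absorbance
    if lo >= hi:
        raise ConfigurationError("window must satisfy low < high")
    if lo < w[0] or hi > w[-1]:
        raise ExtrapolationError(
            f"window [{lo}, {hi}] cm^-1 outside grid span [{w[0]}, {w[-1]}] cm^-1"
        )
    inside = (w > lo) & (w < hi)
    nodes = np.concatenate(([lo], w[inside], [hi]))
    values = np.concatenate(([np.interp(lo, w, a)], a[inside], [np.interp(hi, w, a)]))
    return float(np.trapezoid(values, nodes))


def band_maximum(spectrum: IRSpectrum, window=ALKYNE_WINDOW) -> float:
    """Maximum absorbance within a wavenumber window (window edges included
    by linear interpolation); an alternative univariate response to the
    integrated band area."""
    lo, hi = float(window[0]), float(window[1])
    w, a = spectrum.wavenumbers, spectrum.absorbance
    if lo >= hi:
        raise ConfigurationError("window must satisfy low < high")
    if lo < w[0] or hi > w[-1]:
        raise ExtrapolationError(
            f"window [{lo}, {hi}] cm^-1 outside grid span [{w[0]}, {w[-1]}] cm^-1"
        )
    inside = (w >= lo) & (w <= hi)
    candidates = np.concatenate((a[inside], [np.interp(lo, w, a), np.interp(hi, w, a)]))
    return float(candidates.max())


@dataclass
class PLSModel:
    """A fitted mean-centred PLS1 calibration with its CV figures of merit."""

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray
    x_loadings: np.ndarray
    x_scores: np.ndarray
    regression_vector: np.ndarray
    rmsec: float
    rmsecv: float
    bias: float
    r2_cal: float
    r2_cv: float
    rmsecv_by_lv: np.ndarray
    rmsec_by_lv: np.ndarray
    y_pred_cal: np.ndarray
    y_pred_cv: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.regression_vector + self.y_mean


def _block_slices(n: int, n_splits: int):
    if n % n_splits != 0:
        raise ConfigurationError(
            f"{n} rows cannot be divided into {n_splits} contiguous blocks of equal size"
        )
    size = n // n_splits
    return [slice(i * size, (i + 1) * size) for i in range(n_splits)]


def fit_pls(X, y, max_lv: int = 10, n_splits: int | None = None) -> PLSModel:
    """PLS1 calibration selected by contiguous-block cross-validation.

    Rows must be ordered so that each concentration level's replicates are
    contiguous; each CV block then holds one level's replicates, so no
    replicate of a left-out level leaks into training.  ``n_splits`` defaults
    to the number of distinct ``y`` values.  The latent-variable count is the
    RMSECV minimiser over 1..max_lv (ties go to fewer LVs); ``max_lv`` beyond
    the rank of centred X is capped with a warning.
    """
    if isinstance(X, IRDataset):
        X = X.absorbance
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.size != n:
        raise ConfigurationError("X rows and y length differ")
    if max_lv < 1:
        raise ConfigurationError("max_lv must be >= 1")
    if n_splits is None:
        n_splits = np.unique(y).size
    blocks = _block_slices(n, n_splits)

    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if max_lv > rank:
        warnings.warn(
            f"max_lv={max_lv} exceeds rank {rank} of centred X; capped", stacklevel=2
        )
        max_lv = rank

    # Cross-validated predictions for every candidate LV count.
    press = np.zeros(max_lv)
    y_cv = np.zeros((max_lv, n))
    for block in blocks:
        train = np.ones(n, dtype=bool)
        train[block] = False
        Xt, yt = X[train], y[train]
        fold_rank = int(np.linalg.matrix_rank(Xt - Xt.mean(axis=0)))
        for lv in range(1, max_lv + 1):
            m = PLSRegression(n_components=min(lv, fold_rank), scale=False)
            m.fit(Xt, yt)
            y_cv[lv - 1, block] = m.predict(X[block]).ravel()
    resid_cv = y_cv - y[None, :]
    press = (resid_cv**2).sum(axis=1)
    rmsecv_by_lv = np.sqrt(press / n)
    n_lv = int(np.argmin(rmsecv_by_lv)) + 1  # argmin takes the first (fewest LVs) tie

    rmsec_by_lv = np.empty(max_lv)
    for lv in range(1, max_lv + 1):
        m = PLSRegression(n_components=lv, scale=False)
        m.fit(X, y)
        rmsec_by_lv[lv - 1] = np.sqrt(((m.predict(X).ravel() - y) ** 2).mean())

    final = PLSRegression(n_components=n_lv, scale=False)
    final.fit(X, y)
    y_cal = final.predict(X).ravel()
    tss = float(((y - y.mean()) ** 2).sum())
    rmsec = float(np.sqrt(((y_cal - y) ** 2).mean()))
    rmsecv = float(rmsecv_by_lv[n_lv - 1])
    bias = float((y_cv[n_lv - 1] - y).mean())
    r2_cal = 1.0 - float(((y_cal - y) ** 2).sum()) / tss if tss > 0 else np.nan
    r2_cv = 1.0 - float(press[n_lv - 1]) / tss if tss > 0 else np.nan

    return PLSModel(
        n_lv=n_lv,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        x_weights=final.x_weights_,
        x_loadings=final.x_loadings_,
        x_scores=final.x_scores_,
        regression_vector=final.coef_.reshape(-1),
        rmsec=rmsec,
        rmsecv=rmsecv,
        bias=bias,
        r2_cal=r2_cal,
        r2_cv=r2_cv,
        rmsecv_by_lv=rmsecv_by_lv,
        rmsec_by_lv=rmsec_by_lv,
        y_pred_cal=y_cal,
        y_pred_cv=y_cv[n_lv - 1].copy(),
    )
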