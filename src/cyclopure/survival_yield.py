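"""Survival-yield computation from MS/MS peak lists.

The survival yield (SY) of a precursor ion at a given collisional excitation
voltage is the fraction of the total ion current carried by the surviving
precursor:

    SY = I_precursor / (I_precursor + sum(I_fragment))

Plotting SY against the excitation voltage yields a sigmoidal breakdown
curve; a four-parameter Boltzmann sigmoid

    SY(V) = A2 + (A1 - A2) / (1 + exp((V - V0) / dV))

describes it well, with ``V0`` the voltage of 50% fragmentation and ``dV``
the transition width.  Isomers that require different internal energies to
fragment (e.g. a cyclic peptide versus its linear precursor) separate by
their ``V0``, which is what makes SY curves usable for isomer quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    ConfigurationError,
    DegenerateFitError,
    ExtrapolationError,
    FitConvergenceError,
    GridMismatchError,
    PrecursorWindowWarning,
    UndefinedSurvivalYieldError,
)

__all__ = [
    "MsmsSpectrum",
    "SYCurve",
    "BoltzmannParams",
    "compute_sy",
    "build_sy_curve",
    "fit_boltzmann",
    "sy_at_voltage",
]


@dataclass(frozen=True)
class BoltzmannParams:
    """Parameters of the sigmoid SY(V) = a2 + (a1 - a2)/(1 + exp((V - v0)/dv)).

    ``a1`` is the upper (low-voltage) asymptote, ``a2`` the lower one, ``v0``
    the inflection voltage in volts and ``dv`` the transition width in volts.
    """

    a1: float
    a2: float
    v0: float
    dv: float

    def __post_init__(self):
        if not self.dv > 0:
            raise ConfigurationError(f"dv must be > 0, got {self.dv}")
        if not self.a1 > self.a2:
            raise ConfigurationError(f"a1 must exceed a2, got a1={self.a1}, a2={self.a2}")

    def __call__(self, voltage):
        v = np.asarray(voltage, dtype=float)
        out = self.a2 + (self.a1 - self.a2) / (1.0 + np.exp((v - self.v0) / self.dv))
        return float(out) if np.isscalar(voltage) else out


@dataclass(frozen=True)
class MsmsSpectrum:
    """A centroided MS/MS peak list acquired at one excitation voltage.

    ``precursor_window`` is the half-width (m/z) around ``precursor_mz``
    within which peaks count as surviving precursor; the default 0.5 mirrors
    a 1 m/z isolation window.
    """

    sample_id: str
    voltage: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    precursor_window: float = 0.5

    def __post_init__(self):
        mz = np.atleast_1d(np.asarray(self.mz, dtype=float))
        inten = np.atleast_1d(np.asarray(self.intensity, dtype=float))
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape:
            raise ConfigurationError("mz and intensity must have equal length")
        if mz.size == 0:
            raise ConfigurationError("spectrum must contain at least one peak")
        if np.any(inten < 0):
            raise ConfigurationError("peak intensities must be >= 0")
        if not self.precursor_window > 0:
            raise ConfigurationError("precursor_window must be > 0")


@dataclass(frozen=True)
class SYCurve:
    """Survival yield as a function of excitation voltage for one sample."""

    sample_id: str
    voltages: np.ndarray
    sy: np.ndarray

    def __post_init__(self):
        v = np.atleast_1d(np.asarray(self.voltages, dtype=float))
        s = np.atleast_1d(np.asarray(self.sy, dtype=float))
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "sy", s)
        if v.shape != s.shape:
            raise ConfigurationError("voltages and sy must have equal length")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ConfigurationError("voltages must be strictly increasing")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ConfigurationError("SY values must lie in [0, 1]")

    def __len__(self):
        return self.voltages.size


def compute_sy(spectrum: MsmsSpectrum) -> float:
    """Survival yield of one spectrum: precursor-window intensity over TIC.

    All peaks within ``precursor_mz +/- precursor_window`` are summed as
    precursor (centroiding may split the peak).  If no peak falls inside the
    window a :class:`PrecursorWindowWarning` is emitted and 0.0 returned.

    Raises
    ------
    UndefinedSurvivalYieldError
        If the total ion current is zero.
    """
    tic = float(spectrum.intensity.sum())
    if tic <= 0:
        raise UndefinedSurvivalYieldError(
            f"total ion current is zero for sample {spectrum.sample_id!r} "
            f"at {spectrum.voltage} V"
        )
    in_window = np.abs(spectrum.mz - spectrum.precursor_mz) <= spectrum.precursor_window
    if not in_window.any():
        warnings.warn(
            f"no peak within {spectrum.precursor_window} m/z of precursor "
            f"{spectrum.precursor_mz} for sample {spectrum.sample_id!r} at "
            f"{spectrum.voltage} V; SY = 0",
            PrecursorWindowWarning,
            stacklevel=2,
        )
        return 0.0
    return float(spectrum.intensity[in_window].sum() / tic)


def build_sy_curve(spectra) -> SYCurve:
    """Assemble the SY-vs-voltage curve of one sample from its spectra.

    Spectra may be given in any order; the curve is sorted by voltage.

    Raises
    ------
    ConfigurationError
        If spectra mix sample ids or share a voltage (the duplicate voltage
        is named in the message).
    """
    spectra = list(spectra)
    if not spectra:
        raise ConfigurationError("no spectra given")
    sample_id = spectra[0].sample_id
    if any(s.sample_id != sample_id for s in spectra):
        raise ConfigurationError("all spectra must share one sample_id")
    voltages = np.array([s.voltage for s in spectra], dtype=float)
    order = np.argsort(voltages)
    voltages = voltages[order]
    dupes = voltages[:-1][np.diff(voltages) == 0]
    if dupes.size:
        raise ConfigurationError(f"duplicate voltage {dupes[0]} V in sample {sample_id!r}")
    sy = np.array([compute_sy(spectra[i]) for i in order], dtype=float)
    return SYCurve(sample_id=sample_id, voltages=voltages, sy=sy)


def _boltzmann(theta, v):
    a1, a2, v0, dv = theta
    return a2 + (a1 - a2) / (1.0 + np.exp((v - v0) / dv))


def fit_boltzmann(
    curve: SYCurve,
    init: BoltzmannParams | None = None,
    max_nfev: int = 200,
    ftol: float = 1e-10,
):
    """Least-squares Boltzmann sigmoid fit of an SY curve.

    Initialisation (when ``init`` is not given): a1 = max(sy), a2 = min(sy),
    v0 = the voltage nearest the half-height crossing, dv = span/10.

    Returns
    -------
    (BoltzmannParams, float)
        Fitted parameters and the residual sum of squares.

    Raises
    ------
    DegenerateFitError
        Fewer than 4 points, or a flat curve with no inflection to locate.
    FitConvergenceError
        Iteration cap hit before the RSS tolerance; carries best-so-far
        parameters in ``.params``.
    """
    v = curve.voltages
    s = curve.sy
    if v.size < 4:
        raise DegenerateFitError("Boltzmann fit requires at least 4 points")
    if np.ptp(s) < 1e-9:
        raise DegenerateFitError("flat SY curve: inflection voltage is undetermined")

    if init is None:
        a1, a2 = float(s.max()), float(s.min())
        half = 0.5 * (a1 + a2)
        v0 = float(v[np.argmin(np.abs(s - half))])
        dv = float((v[-1] - v[0]) / 10.0)
        x0 = np.array([a1, a2, v0, dv])
    else:
        x0 = np.array([init.a1, init.a2, init.v0, init.dv])

    res = least_squares(
        lambda th: _boltzmann(th, v) - s,
        x0,
        bounds=([-np.inf, -np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf, np.inf]),
        ftol=ftol,
        xtol=1e-12,
        max_nfev=max_nfev,
    )
    rss = float(2.0 * res.cost)
    a1, a2, v0, dv = (float(x) for x in res.x)
    if res.status == 0:
        raise FitConvergenceError(
            f"Boltzmann fit did not converge within {max_nfev} evaluations",
            params=res.x,
            rss=rss,
        )
    if not a1 > a2:
        raise DegenerateFitError(
            f"fitted asymptotes are not ordered (a1={a1:.4g} <= a2={a2:.4g}); "
            "curve is not a decreasing sigmoid"
        )
    return BoltzmannParams(a1=a1, a2=a2, v0=v0, dv=dv), rss


def sy_at_voltage(
    curve: SYCurve,
    v: float,
    mode: str = "measured",
    fit: BoltzmannParams | None = None,
    atol: float = 1e-9,
) -> float:
    """SY of a curve at one voltage, either looked up or from the sigmoid fit.

    ``mode="measured"`` requires ``v`` to match a grid voltage within
    ``atol``; ``mode="fitted"`` evaluates the Boltzmann fit (fitted on the
    fly when ``fit`` is not supplied).
    """
    if v < curve.voltages[0] - atol or v > curve.voltages[-1] + atol:
        raise ExtrapolationError(
            f"{v} V outside curve span [{curve.voltages[0]}, {curve.voltages[-1]}] V"
        )
    if mode == "measured":
        i = int(np.argmin(np.abs(curve.voltages - v)))
        if abs(curve.voltages[i] - v) > atol:
            raise GridMismatchError(
                f"no grid voltage within {atol} of {v} V (nearest: {curve.voltages[i]} V)"
            )
        return float(curve.sy[i])
    if mode == "fitted":
        if fit is None:
            fit, _ = fit_boltzmann(curve)
        return float(fit(v))
    raise ConfigurationError(f"unknown mode {mode!r}; use 'measured' or 'fitted'")
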