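"""Calibration models relating ER-MS survival-yield responses to the molar
ratio x = n_lin / n_total of linear peptide.

Four models are provided:

* univariate — the response is the SY depression at one fixed voltage,
  ``SY_cyclic(v) - SY_mixture(v)``, regressed linearly on x;
* CLS — the whole mixture curve is decomposed as
  ``SY_mix = a * SY_lin + (1 - a) * SY_cyc + e`` (classical least squares on
  the two pure-component curves); the coefficient ``a`` is then regressed on
  x, again linearly;
* segmented — two independent lines on [0, breakpoint] and [breakpoint, 1]
  (the ion-suppression kink makes a single line inadequate over [0, 1]);
* quadratic — a single degree-2 polynomial over the full range.

The CLS coefficient is deliberately not clipped to [0, 1]: out-of-range
values diagnose noise or model failure and must reach the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DegenerateFitError, GridMismatchError, PredictionError
from .survival_yield import SYCurve, sy_at_voltage

__all__ = [
    "CalibrationStandard",
    "UnivariateModel",
    "CLSResult",
    "SegmentedModel",
    "QuadraticModel",
    "delta_sy_response",
    "cls_coefficient",
    "fit_univariate",
    "fit_segmented",
    "fit_quadratic",
    "predict_ratio",
    "average_curves",
]


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration observation: known ratio, replicate id and response."""

    ratio: float
    replicate: int
    response: float

    def __post_init__(self):
        if not 0.0 <= self.ratio <= 1.0:
            raise ConfigurationError(f"ratio {self.ratio} outside [0, 1]")


@dataclass(frozen=True)
class UnivariateModel:
    """OLS line response = b0 + b1 * ratio with residual sd and R^2."""

    b0: float
    b1: float
    se: float
    r2: float
    n: int

    def response(self, ratio):
        return self.b0 + self.b1 * np.asarray(ratio, dtype=float)


@dataclass(frozen=True)
class CLSResult:
    """CLS decomposition of one mixture curve onto the two pure curves."""

    a: float
    residuals: np.ndarray
    rss: float


@dataclass(frozen=True)
class SegmentedModel:
    """Two independent lines meeting the data on either side of a breakpoint."""

    breakpoint: float
    low_model: UnivariateModel
    high_model: UnivariateModel
    low_range: tuple = (0.0, 0.3)
    high_range: tuple = (0.3, 1.0)

    def __post_init__(self):
        if not 0.0 < self.breakpoint < 1.0:
            raise ConfigurationError("breakpoint must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class QuadraticModel:
    """Polynomial response = c0 + c1 * ratio + c2 * ratio^2."""

    c0: float
    c1: float
    c2: float
    se: float
    r2: float
    n: int

    def response(self, ratio):
        x = np.asarray(ratio, dtype=float)
        return self.c0 + self.c1 * x + self.c2 * x**2


def average_curves(curves) -> SYCurve:
    """Pointwise mean of replicate SY curves sharing one voltage grid."""
    curves = list(curves)
    if not curves:
        raise ConfigurationError("no curves to average")
    grid = curves[0].voltages
    for c in curves[1:]:
        if c.voltages.shape != grid.shape or not np.allclose(c.voltages, grid, atol=1e-9):
            raise GridMismatchError("replicate curves are not on a common voltage grid")
    sy = np.mean([c.sy for c in curves], axis=0)
    return SYCurve(sample_id=curves[0].sample_id, voltages=grid.copy(), sy=sy)


def delta_sy_response(curve_mix: SYCurve, curve_cyclic: SYCurve, v: float) -> float:
    """SY depression of a mixture at voltage v: SY_cyclic(v) - SY_mix(v).

    Positive (for well-behaved mixtures) and increasing with the linear
    content, since the linear isomer fragments earlier.
    """
    return sy_at_voltage(curve_cyclic, v) - sy_at_voltage(curve_mix, v)


def cls_coefficient(curve_mix: SYCurve, curve_lin: SYCurve, curve_cyc: SYCurve) -> CLSResult:
    """Closed-form CLS coefficient of one mixture curve.

    Minimises ||m - a*l - (1-a)*c||^2 over the scalar a, where m, l, c are
    the mixture and pure-component SY vectors on one common voltage grid:
    a = <m - c, l - c> / <l - c, l - c>.  ``a`` is not clipped.
    """
    grids = [curve_mix.voltages, curve_lin.voltages, curve_cyc.voltages]
    if not all(g.shape == grids[0].shape for g in grids) or not (
        np.allclose(grids[0], grids[1], atol=1e-9)
        and np.allclose(grids[0], grids[2], atol=1e-9)
    ):
        raise GridMismatchError("mixture and pure curves must share one voltage grid")
    m, l, c = curve_mix.sy, curve_lin.sy, curve_cyc.sy
    d = l - c
    denom = float(d @ d)
    if denom <= 0:
        raise DegenerateFitError(
            "pure linear and cyclic curves are identical; the coefficient is undetermined"
        )
    a = float((m - c) @ d / denom)
    residuals = m - a * l - (1.0 - a) * c
    return CLSResult(a=a, residuals=residuals, rss=float(residuals @ residuals))


def _responses(standards):
    standards = list(standards)
    x = np.array([s.ratio for s in standards], dtype=float)
    y = np.array([s.response for s in standards], dtype=float)
    return standards, x, y


def fit_univariate(standards) -> UnivariateModel:
    """Ordinary least squares of response on ratio.

    The residual sd uses n - 2 degrees of freedom; R^2 = 1 - RSS/TSS.
    """
    standards, x, y = _responses(standards)
    if np.unique(x).size < 3:
        raise DegenerateFitError("univariate fit requires >= 3 distinct ratios")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx <= 0:
        raise DegenerateFitError("all ratios identical: slope is undetermined")
    b1 = float((x - xm) @ (y - ym) / sxx)
    b0 = float(ym - b1 * xm)
    resid = y - (b0 + b1 * x)
    rss = float(resid @ resid)
    tss = float(((y - ym) ** 2).sum())
    n = x.size
    se = float(np.sqrt(rss / (n - 2))) if n > 2 else np.nan
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return UnivariateModel(b0=b0, b1=b1, se=se, r2=r2, n=n)


def fit_segmented(standards, breakpoint: float = 0.3) -> SegmentedModel:
    """Two independent OLS lines below and above a fixed breakpoint.

    Standards at the breakpoint itself belong to both segments.
    """
    standards, x, _ = _responses(standards)
    eps = 1e-12
    low = [s for s in standards if s.ratio <= breakpoint + eps]
    high = [s for s in standards if s.ratio >= breakpoint - eps]
    for side, subset in (("low", low), ("high", high)):
        if len({s.ratio for s in subset}) < 3:
            raise DegenerateFitError(
                f"{side} segment has fewer than 3 distinct ratios around breakpoint {breakpoint}"
            )
    low_model = fit_univariate(low)
    high_model = fit_univariate(high)
    return SegmentedModel(
        breakpoint=breakpoint,
        low_model=low_model,
        high_model=high_model,
        low_range=(min(s.ratio for s in low), breakpoint),
        high_range=(breakpoint, max(s.ratio for s in high)),
    )


def fit_quadratic(standards) -> QuadraticModel:
    """Degree-2 polynomial least squares of response on ratio.

    The residual sd uses n - 3 degrees of freedom.
    """
    standards, x, y = _responses(standards)
    if np.unique(x).size < 4:
        raise DegenerateFitError("quadratic fit requires >= 4 distinct ratios")
    design = np.vstack([np.ones_like(x), x, x**2]).T
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise DegenerateFitError("rank-deficient quadratic design")
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    n = x.size
    se = float(np.sqrt(rss / (n - 3))) if n > 3 else np.nan
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return QuadraticModel(
        c0=float(coef[0]), c1=float(coef[1]), c2=float(coef[2]), se=se, r2=r2, n=n
    )


def _invert_line(model: UnivariateModel, response: float) -> float:
    if abs(model.b1) <= 1e-12:
        raise PredictionError("slope too close to zero to invert")
    return (response - model.b0) / model.b1


def predict_ratio(model, response: float, atol: float = 1e-9) -> float:
    """Invert a fitted calibration model: response -> predicted molar ratio.

    Segmented models use the segment whose inverse lands in its own ratio
    range; if both segments claim the response and disagree beyond ``atol``
    the prediction is ambiguous.  Quadratic models take the real root inside
    [-0.1, 1.1]; two admissible roots are ambiguous.
    """
    if isinstance(model, UnivariateModel):
        return float(_invert_line(model, response))

    if isinstance(model, SegmentedModel):
        candidates = []
        for sub, (lo, hi) in (
            (model.low_model, model.low_range),
            (model.high_model, model.high_range),
        ):
            x = _invert_line(sub, response)
            if lo - atol <= x <= hi + atol:
                candidates.append(x)
        if not candidates:
            raise PredictionError(
                f"response {response} maps into neither segment's ratio range"
            )
        if len(candidates) == 2 and abs(candidates[0] - candidates[1]) > atol:
            raise PredictionError(
                f"response {response} is ambiguous between segments: "
                f"{candidates[0]:.6g} vs {candidates[1]:.6g}"
            )
        return float(np.mean(candidates))

    if isinstance(model, QuadraticModel):
        if abs(model.c2) <= 1e-12:
            return float(
                _invert_line(
                    UnivariateModel(b0=model.c0, b1=model.c1, se=0.0, r2=1.0, n=model.n),
                    response,
                )
            )
        roots = np.roots([model.c2, model.c1, model.c0 - response])
        real = roots[np.abs(roots.imag) < 1e-9].real
        admissible = np.unique(np.round(real[(real >= -0.1) & (real <= 1.1)], 12))
        if admissible.size == 0:
            raise PredictionError(f"no admissible root in [-0.1, 1.1] for response {response}")
        if admissible.size > 1 and np.ptp(admissible) > atol:
            raise PredictionError(
                f"two admissible roots for response {response}: {admissible.tolist()}"
            )
        return float(admissible[0])

    raise ConfigurationError(f"cannot invert model of type {type(model).__name__}")
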