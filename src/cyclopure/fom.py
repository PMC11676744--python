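"""Figures of merit for the calibration models: fit errors, RMSEC/RMSECV,
detection limits, pooled intermediate precision and the comparison report.

Definitions (molar-ratio units throughout):

* fit error_i = predicted_i - reference_i, per calibration standard;
* RMSEC = sqrt(sum(fit error_i^2) / n) with divisor exactly n;
* univariate LOD = 3.3 * se / |b1| (se = residual sd of the calibration
  line, b1 its slope; 3.3 corresponds to alpha = beta = 0.05);
* multivariate LOD = 3.3 * RMSEC;
* intermediate precision = dof-weighted pooled replicate sd of the
  predictions, sqrt(sum (n_g - 1) s_g^2 / sum (n_g - 1)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .erms_calibration import UnivariateModel
from .exceptions import ConfigurationError

__all__ = [
    "FomReport",
    "fit_errors",
    "rmsec",
    "lod_univariate",
    "lod_multivariate",
    "intermediate_precision",
    "make_fom_report",
    "build_comparison_report",
    "TABLE_COLUMNS",
    "reports_to_json",
    "reports_from_json",
    "reports_to_csv",
]

#: Column layout of the comparison table.
TABLE_COLUMNS = [
    "Analytical Technique",
    "Calibration Model",
    "Linearity Interval",
    "R2",
    "Fit Error (RMSEC)",
    "Intermediate Precision",
    "Detection Limit (LD)",
]


@dataclass
class FomReport:
    """Figures of merit of one (technique, model) pair."""

    technique: str  # "ERMS" | "IR"
    model: str  # "univariate" | "CLS" | "PLS" | "segmented" | "quadratic"
    linearity_interval: tuple
    r2: float
    rmsec: float
    intermediate_precision_sd: float
    lod: float
    n: int
    per_standard_fit_errors: list  # (ratio, replicate, fit_error)
    rmsecv: float | None = None
    lod_rule: str = "3.3*se/b1"
    lod_alt: float | None = None
    lod_alt_rule: str | None = None

    def __post_init__(self):
        if self.rmsec < 0 or self.lod < 0:
            raise ConfigurationError("rmsec and lod must be >= 0")
        if self.n != len(self.per_standard_fit_errors):
            raise ConfigurationError("n must equal the number of per-standard fit errors")


def fit_errors(predicted, reference):
    """Per-standard fit errors and percentage errors.

    Returns ``(errors, pct_errors)`` with ``errors = predicted - reference``
    elementwise; percentage errors are NaN where the reference is 0 (the
    ratio is undefined there and the absolute error stands alone).
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ConfigurationError("predicted and reference must have equal length")
    errors = predicted - reference
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(reference != 0, 100.0 * errors / reference, np.nan)
    return errors, pct


def rmsec(errors) -> float:
    """Root-mean-square error of calibration, sqrt(sum e_i^2 / n)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ConfigurationError("cannot compute RMSEC of an empty error list")
    return float(np.sqrt((errors**2).sum() / errors.size))


def lod_univariate(model: UnivariateModel, factor: float = 3.3) -> float:
    """Detection limit of a linear calibration: factor * se / |b1|."""
    if abs(model.b1) <= 1e-300:
        raise ConfigurationError("zero calibration slope: LOD is undefined")
    return float(factor * model.se / abs(model.b1))


def lod_multivariate(rmsec_value: float, factor: float = 3.3) -> float:
    """Detection limit of a multivariate calibration: factor * RMSEC."""
    if rmsec_value < 0:
        raise ConfigurationError("RMSEC must be >= 0")
    return float(factor * rmsec_value)


def intermediate_precision(groups) -> float:
    """Pooled replicate sd across standards.

    ``groups`` maps each standard (any hashable key) to its replicate
    predictions; every group needs >= 2 members.  Pooling is dof-weighted:
    sqrt( sum (n_g - 1) s_g^2 / sum (n_g - 1) ).
    """
    if not isinstance(groups, dict):
        groups = {i: g for i, g in enumerate(groups)}
    if not groups:
        raise ConfigurationError("no replicate groups given")
    num = 0.0
    dof = 0
    for key, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ConfigurationError(f"group {key!r} has fewer than 2 replicates")
        num += (v.size - 1) * float(np.var(v, ddof=1))
        dof += v.size - 1
    return float(np.sqrt(num / dof))


def make_fom_report(
    technique: str,
    model: str,
    ratios,
    replicates,
    predicted,
    linearity_interval,
    r2: float,
    lod: float,
    rmsecv: float | None = None,
    lod_rule: str = "3.3*se/b1",
    lod_alt: float | None = None,
    lod_alt_rule: str | None = None,
) -> FomReport:
    """Assemble a FomReport from per-standard predictions.

    RMSEC and the pooled intermediate precision are computed here from the
    (ratio, replicate, predicted) triples.
    """
    ratios = np.asarray(ratios, dtype=float)
    replicates = np.asarray(replicates, dtype=int)
    predicted = np.asarray(predicted, dtype=float)
    if not ratios.size:
        raise ConfigurationError(f"no predictions supplied for model {model!r}")
    errors, _ = fit_errors(predicted, ratios)
    groups = {}
    for r, pred in zip(ratios, predicted):
        groups.setdefault(float(r), []).append(float(pred))
    return FomReport(
        technique=technique,
        model=model,
        linearity_interval=(float(linearity_interval[0]), float(linearity_interval[1])),
        r2=float(r2),
        rmsec=rmsec(errors),
        intermediate_precision_sd=intermediate_precision(groups),
        lod=float(lod),
        n=int(ratios.size),
        per_standard_fit_errors=[
            (float(r), int(rep), float(e)) for r, rep, e in zip(ratios, replicates, errors)
        ],
        rmsecv=rmsecv,
        lod_rule=lod_rule,
        lod_alt=lod_alt,
        lod_alt_rule=lod_alt_rule,
    )


def build_comparison_report(reports) -> pd.DataFrame:
    """Render the comparison table, one row per (technique, model)."""
    reports = list(reports)
    if not reports:
        raise ConfigurationError("at least one fitted model is required")
    rows = []
    for r in reports:
        lo, hi = r.linearity_interval
        rows.append(
            {
                "Analytical Technique": r.technique,
                "Calibration Model": r.model,
                "Linearity Interval": f"{lo:g}-{hi:g}",
                "R2": r.r2,
                "Fit Error (RMSEC)": r.rmsec,
                "Intermediate Precision": r.intermediate_precision_sd,
                "Detection Limit (LD)": r.lod,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def reports_to_json(reports, path=None) -> str:
    """Serialise reports to JSON (full IEEE-double precision)."""
    payload = [asdict(r) for r in reports]
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def reports_from_json(source) -> list:
    """Read back reports written by :func:`reports_to_json` (path or text)."""
    try:
        with open(source, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, TypeError):
        payload = json.loads(source)
    out = []
    for d in payload:
        d["linearity_interval"] = tuple(d["linearity_interval"])
        d["per_standard_fit_errors"] = [tuple(t) for t in d["per_standard_fit_errors"]]
        out.append(FomReport(**d))
    return out


def reports_to_csv(reports, path) -> None:
    """Write the rendered comparison table as CSV."""
    build_comparison_report(reports).to_csv(path, index=False)
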