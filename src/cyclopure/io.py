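"""Reading and writing of the package's plain-text data dialects.

All CSVs are comma-separated UTF-8 with a mandatory header and "." decimals;
floats are written with 12 significant digits.  Malformed rows raise
:class:`~cyclopure.exceptions.FormatError` carrying the 1-based line number.

Dialects:

* peak lists — ``sample_id, replicate, voltage_V, mz, intensity,
  is_precursor`` (exactly one precursor row per spectrum);
* SY curves — ``sample_id, voltage_V, sy``;
* IR matrix — first column ``wavenumber_cm1``, one column per averaged
  spectrum, plus a sidecar JSON manifest (ratios, replicates, seed, config);
* predictions — ``sample_id, ratio_reference, replicate, response,
  ratio_predicted``;
* model JSON — a tagged dict per model type.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .erms_calibration import QuadraticModel, SegmentedModel, UnivariateModel
from .exceptions import ConfigurationError, FormatError
from .ir_pipeline import IRDataset, PLSModel
from .survival_yield import MsmsSpectrum, SYCurve
from .synthetic import ErmsSample

__all__ = [
    "write_peaklist_csv",
    "read_peaklist_csv",
    "write_sy_curves_csv",
    "read_sy_curves_csv",
    "write_ir_matrix_csv",
    "read_ir_matrix_csv",
    "write_manifest_json",
    "read_manifest_json",
    "write_predictions_csv",
    "read_predictions_csv",
    "model_to_dict",
    "model_from_dict",
    "write_model_json",
    "read_model_json",
]

FLOAT_FMT = "%.12g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def _require_header(df: pd.DataFrame, expected, path):
    if list(df.columns) != list(expected):
        raise FormatError(
            f"expected header {list(expected)}, found {list(df.columns)}", line=1, path=path
        )


def _numeric(df: pd.DataFrame, column: str, path):
    """Convert a string column to float, naming the first bad line."""
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(f"non-numeric value in column {column!r}", line=line, path=path)
    if converted.isna().any():
        line = int(converted.isna().idxmax()) + 2
        raise FormatError(f"missing value in column {column!r}", line=line, path=path)
    return converted.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# peak lists

PEAKLIST_HEADER = ["sample_id", "replicate", "voltage_V", "mz", "intensity", "is_precursor"]


def write_peaklist_csv(samples, path) -> None:
    rows = []
    for sample in samples:
        for spec in sample.spectra:
            for mz, inten in zip(spec.mz, spec.intensity):
                rows.append(
                    (
                        sample.sample_id,
                        sample.replicate,
                        _fmt(spec.voltage),
                        _fmt(mz),
                        _fmt(inten),
                        int(abs(mz - spec.precursor_mz) <= spec.precursor_window),
                    )
                )
    pd.DataFrame(rows, columns=PEAKLIST_HEADER).to_csv(path, index=False)


def read_peaklist_csv(path, precursor_window: float = 0.5, ratios: dict | None = None):
    """Read a peak-list CSV back into :class:`ErmsSample` objects.

    ``ratios`` optionally maps sample_id to the known molar ratio (e.g. from
    the run manifest); unknown ratios are NaN.
    """
    df = pd.read_csv(path, dtype=str)
    _require_header(df, PEAKLIST_HEADER, path)
    voltage = _numeric(df, "voltage_V", path)
    mz = _numeric(df, "mz", path)
    intensity = _numeric(df, "intensity", path)
    if (intensity < 0).any():
        line = int(np.argmax(intensity < 0)) + 2
        raise FormatError("negative intensity", line=line, path=path)
    is_prec = _numeric(df, "is_precursor", path).astype(int)
    replicate = _numeric(df, "replicate", path).astype(int)
    work = df.assign(_v=voltage, _mz=mz, _i=intensity, _p=is_prec, _rep=replicate)

    samples = []
    for sid, group in work.groupby("sample_id", sort=False):
        spectra = []
        for v, spec_rows in group.groupby("_v", sort=True):
            prec_rows = spec_rows[spec_rows["_p"] == 1]
            if prec_rows.empty:
                raise FormatError(
                    f"spectrum {sid!r} at {v} V has no precursor row",
                    line=int(spec_rows.index[0]) + 2,
                    path=path,
                )
            precursor_mz = float(prec_rows["_mz"].iloc[0])
            spectra.append(
                MsmsSpectrum(
                    sample_id=str(sid),
                    voltage=float(v),
                    mz=spec_rows["_mz"].to_numpy(dtype=float),
                    intensity=spec_rows["_i"].to_numpy(dtype=float),
                    precursor_mz=precursor_mz,
                    precursor_window=precursor_window,
                )
            )
        ratio = float((ratios or {}).get(str(sid), np.nan))
        samples.append(
            ErmsSample(
                sample_id=str(sid),
                ratio=ratio,
                replicate=int(group["_rep"].iloc[0]),
                spectra=tuple(spectra),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# SY curves

SY_HEADER = ["sample_id", "voltage_V", "sy"]


def write_sy_curves_csv(curves, path) -> None:
    rows = []
    for curve in curves:
        for v, s in zip(curve.voltages, curve.sy):
            rows.append((curve.sample_id, _fmt(v), _fmt(s)))
    pd.DataFrame(rows, columns=SY_HEADER).to_csv(path, index=False)


def read_sy_curves_csv(path):
    df = pd.read_csv(path, dtype=str)
    _require_header(df, SY_HEADER, path)
    voltage = _numeric(df, "voltage_V", path)
    sy = _numeric(df, "sy", path)
    work = df.assign(_v=voltage, _s=sy)
    curves = []
    for sid, group in work.groupby("sample_id", sort=False):
        order = np.argsort(group["_v"].to_numpy())
        curves.append(
            SYCurve(
                sample_id=str(sid),
                voltages=group["_v"].to_numpy(dtype=float)[order],
                sy=group["_s"].to_numpy(dtype=float)[order],
            )
        )
    return curves


# ---------------------------------------------------------------------------
# IR matrices

IR_INDEX_COLUMN = "wavenumber_cm1"


def write_ir_matrix_csv(dataset: IRDataset, path) -> None:
    data = {IR_INDEX_COLUMN: [_fmt(w) for w in dataset.wavenumbers]}
    for i, sid in enumerate(dataset.sample_ids):
        data[sid] = [_fmt(a) for a in dataset.absorbance[i]]
    pd.DataFrame(data).to_csv(path, index=False)


def read_ir_matrix_csv(path, manifest: dict | None = None) -> IRDataset:
    df = pd.read_csv(path, dtype=str)
    if not len(df.columns) or df.columns[0] != IR_INDEX_COLUMN:
        raise FormatError(
            f"first column must be {IR_INDEX_COLUMN!r}, found {df.columns[0]!r}",
            line=1,
            path=path,
        )
    wavenumbers = _numeric(df, IR_INDEX_COLUMN, path)
    diffs = np.diff(wavenumbers)
    if (diffs <= 0).any():
        line = int(np.argmax(diffs <= 0)) + 3  # offending (second) row of the pair
        raise FormatError("wavenumbers must be strictly increasing", line=line, path=path)
    sample_ids = [c for c in df.columns if c != IR_INDEX_COLUMN]
    absorbance = np.vstack([_numeric(df, c, path) for c in sample_ids])
    meta = manifest or {}
    ratios = np.array(
        [meta.get("ratios", {}).get(sid, np.nan) for sid in sample_ids], dtype=float
    )
    replicates = np.array(
        [meta.get("replicates", {}).get(sid, 0) for sid in sample_ids], dtype=int
    )
    return IRDataset(
        wavenumbers=wavenumbers,
        absorbance=absorbance,
        sample_ids=sample_ids,
        ratios=ratios,
        replicates=replicates,
    )


# ---------------------------------------------------------------------------
# manifests and predictions


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_manifest_json(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


PREDICTIONS_HEADER = [
    "sample_id",
    "ratio_reference",
    "replicate",
    "response",
    "ratio_predicted",
]


def write_predictions_csv(records, path) -> None:
    """``records``: iterable of (sample_id, ratio, replicate, response, predicted)."""
    rows = [
        (sid, _fmt(ratio), rep, _fmt(resp), _fmt(pred))
        for sid, ratio, rep, resp, pred in records
    ]
    pd.DataFrame(rows, columns=PREDICTIONS_HEADER).to_csv(path, index=False)


def read_predictions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require_header(df, PREDICTIONS_HEADER, path)
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "ratio_reference": _numeric(df, "ratio_reference", path),
            "replicate": _numeric(df, "replicate", path).astype(int),
            "response": _numeric(df, "response", path),
            "ratio_predicted": _numeric(df, "ratio_predicted", path),
        }
    )


# ---------------------------------------------------------------------------
# model JSON


def model_to_dict(model) -> dict:
    if isinstance(model, UnivariateModel):
        return {"type": "univariate", **dataclasses.asdict(model)}
    if isinstance(model, QuadraticModel):
        return {"type": "quadratic", **dataclasses.asdict(model)}
    if isinstance(model, SegmentedModel):
        return {
            "type": "segmented",
            "breakpoint": model.breakpoint,
            "low_model": dataclasses.asdict(model.low_model),
            "high_model": dataclasses.asdict(model.high_model),
            "low_range": list(model.low_range),
            "high_range": list(model.high_range),
        }
    if isinstance(model, PLSModel):
        return {
            "type": "pls",
            "n_lv": model.n_lv,
            "x_mean": model.x_mean.tolist(),
            "y_mean": model.y_mean,
            "regression_vector": model.regression_vector.tolist(),
            "rmsec": model.rmsec,
            "rmsecv": model.rmsecv,
            "bias": model.bias,
            "r2_cal": model.r2_cal,
            "r2_cv": model.r2_cv,
            "rmsecv_by_lv": model.rmsecv_by_lv.tolist(),
        }
    raise ConfigurationError(f"cannot serialise model of type {type(model).__name__}")


def model_from_dict(d: dict):
    kind = d.get("type")
    if kind == "univariate":
        return UnivariateModel(b0=d["b0"], b1=d["b1"], se=d["se"], r2=d["r2"], n=d["n"])
    if kind == "quadratic":
        return QuadraticModel(
            c0=d["c0"], c1=d["c1"], c2=d["c2"], se=d["se"], r2=d["r2"], n=d["n"]
        )
    if kind == "segmented":
        return SegmentedModel(
            breakpoint=d["breakpoint"],
            low_model=model_from_dict({"type": "univariate", **d["low_model"]}),
            high_model=model_from_dict({"type": "univariate", **d["high_model"]}),
            low_range=tuple(d["low_range"]),
            high_range=tuple(d["high_range"]),
        )
    if kind == "pls":
        empty = np.empty((0, 0))
        return PLSModel(
            n_lv=d["n_lv"],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=d["y_mean"],
            x_weights=empty,
            x_loadings=empty,
            x_scores=empty,
            regression_vector=np.asarray(d["regression_vector"], dtype=float),
            rmsec=d["rmsec"],
            rmsecv=d["rmsecv"],
            bias=d["bias"],
            r2_cal=d["r2_cal"],
            r2_cv=d["r2_cv"],
            rmsecv_by_lv=np.asarray(d["rmsecv_by_lv"], dtype=float),
            rmsec_by_lv=np.empty(0),
            y_pred_cal=np.empty(0),
            y_pred_cv=np.empty(0),
        )
    raise FormatError(f"unknown model type {kind!r}")


def write_model_json(model, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def read_model_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
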