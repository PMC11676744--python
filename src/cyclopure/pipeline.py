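"""End-to-end orchestration of the two analytical branches.

``run_pipeline`` executes (optionally) simulate -> SY extraction /
IR preprocessing -> calibration -> prediction -> figures of merit, writes
every artefact as CSV/JSON next to a manifest listing each output with its
SHA-256 checksum, and returns the manifest.  With a fixed seed the whole
artefact tree is bit-reproducible; nothing time-dependent is written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .erms_calibration import (
    CalibrationStandard,
    QuadraticModel,
    SegmentedModel,
    UnivariateModel,
    average_curves,
    cls_coefficient,
    delta_sy_response,
    fit_quadratic,
    fit_segmented,
    fit_univariate,
    predict_ratio,
)
from .exceptions import ConfigurationError, CycloPureError, PredictionError
from .fom import lod_multivariate, lod_univariate, make_fom_report, reports_to_csv, reports_to_json
from .ir_pipeline import AslsParams, asls_baseline, band_area, fit_pls, normalise_mean, tune_asls
from .survival_yield import build_sy_curve
from .synthetic import (
    ERMS_CALIBRATION_RATIOS,
    ERMS_DESIGN,
    IR_DESIGN,
    ErmsSimConfig,
    IrSimConfig,
    MixtureDesign,
    simulate_erms_dataset,
    simulate_ir_dataset,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("cyclopure")


@dataclass
class RunConfig:
    """Fully resolved settings of one pipeline run."""

    branch: str = "both"  # "erms" | "ir" | "both"
    outdir: str = "cyclopure_out"
    seed: int = 0
    simulate: bool = True
    peaklist_path: str | None = None
    peaklist_manifest_path: str | None = None
    ir_matrix_path: str | None = None
    ir_manifest_path: str | None = None
    erms_sim: ErmsSimConfig | None = None
    ir_sim: IrSimConfig | None = None
    erms_design: MixtureDesign = ERMS_DESIGN
    ir_design: MixtureDesign = IR_DESIGN
    univariate_voltage: float = 2.2
    calibration_max_ratio: float = 0.3
    segmented_breakpoint: float = 0.3
    asls: AslsParams = field(default_factory=AslsParams)
    tune_p: tuple | None = None
    tune_lam: tuple | None = None
    max_lv: int = 10

    def __post_init__(self):
        if self.branch not in ("erms", "ir", "both"):
            raise ConfigurationError(f"unknown branch {self.branch!r}")
        # coerce nested dicts from a JSON config file back into dataclasses
        if isinstance(self.erms_sim, dict):
            d = dict(self.erms_sim)
            for key in ("boltzmann_linear", "boltzmann_cyclic"):
                if isinstance(d.get(key), dict):
                    from .survival_yield import BoltzmannParams

                    d[key] = BoltzmannParams(**d[key])
            self.erms_sim = ErmsSimConfig(**d)
        if isinstance(self.ir_sim, dict):
            self.ir_sim = IrSimConfig(**self.ir_sim)
        if isinstance(self.asls, dict):
            self.asls = AslsParams(**self.asls)
        if isinstance(self.erms_design, dict):
            self.erms_design = MixtureDesign(**self.erms_design)
        if isinstance(self.ir_design, dict):
            self.ir_design = MixtureDesign(**self.ir_design)
        if self.erms_sim is None:
            self.erms_sim = ErmsSimConfig(seed=self.seed)
        if self.ir_sim is None:
            self.ir_sim = IrSimConfig(seed=self.seed)
        if self.simulate:
            grid = self.erms_sim.voltage_grid
            if not grid[0] <= self.univariate_voltage <= grid[-1]:
                raise ConfigurationError(
                    f"univariate voltage {self.univariate_voltage} V outside grid span"
                )
        else:
            for label, p in (
                ("peak list", self.peaklist_path),
                ("IR matrix", self.ir_matrix_path),
            ):
                needed = (self.branch in ("erms", "both")) if label == "peak list" else (
                    self.branch in ("ir", "both")
                )
                if needed and (p is None or not Path(p).exists()):
                    raise ConfigurationError(f"{label} input path missing or absent: {p}")


@contextmanager
def _stage(name: str, path=None):
    """Attach the stage name (and input path) to any error escaping it."""
    try:
        yield
    except CycloPureError as err:
        raise type(err)(f"[stage {name}] {err}") from err
    except Exception as err:  # noqa: BLE001 - deliberate context wrapper
        suffix = f" (input: {path})" if path else ""
        raise CycloPureError(f"[stage {name}] {err}{suffix}") from err


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _predict_for_standard(model, response: float, reference: float) -> float:
    """Inverse prediction in the calibration context, where the reference is
    known: segmented models use the segment containing the reference, and a
    quadratic ambiguity resolves to the root nearest the reference."""
    if isinstance(model, SegmentedModel):
        sub = model.low_model if reference <= model.breakpoint else model.high_model
        return float((response - sub.b0) / sub.b1)
    if isinstance(model, QuadraticModel):
        try:
            return predict_ratio(model, response)
        except PredictionError:
            roots = np.roots([model.c2, model.c1, model.c0 - response])
            real = roots[np.abs(roots.imag) < 1e-9].real
            if real.size == 0:
                # response below the parabola: nearest attainable point
                return float(-model.c1 / (2.0 * model.c2))
            return float(real[np.argmin(np.abs(real - reference))])
    return predict_ratio(model, response)


def _fom_row_from_standards(
    technique, model_name, standards, model, predictions, **kwargs
):
    return make_fom_report(
        technique=technique,
        model=model_name,
        ratios=[s.ratio for s in standards],
        replicates=[s.replicate for s in standards],
        predicted=predictions,
        **kwargs,
    )


def _run_erms(config: RunConfig, outdir: Path):
    artefacts = {}

    with _stage("erms-input", config.peaklist_path):
        if config.simulate:
            samples = simulate_erms_dataset(config.erms_sim, config.erms_design)
        else:
            manifest = (
                cio.read_manifest_json(config.peaklist_manifest_path)
                if config.peaklist_manifest_path
                else {}
            )
            samples = cio.read_peaklist_csv(
                config.peaklist_path, ratios=manifest.get("ratios", {})
            )
        peaklist_path = outdir / "erms_peaklists.csv"
        cio.write_peaklist_csv(samples, peaklist_path)
        cio.write_manifest_json(
            {
                "ratios": {s.sample_id: s.ratio for s in samples},
                "replicates": {s.sample_id: s.replicate for s in samples},
                "seed": config.seed,
                "config": dataclasses.asdict(config.erms_sim) if config.simulate else None,
            },
            outdir / "erms_manifest.json",
        )
        artefacts["erms_peaklists"] = peaklist_path
        artefacts["erms_manifest"] = outdir / "erms_manifest.json"

    with _stage("erms-sy"):
        curves = {s.sample_id: build_sy_curve(s.spectra) for s in samples}
        sy_path = outdir / "erms_sy_curves.csv"
        cio.write_sy_curves_csv(curves.values(), sy_path)
        artefacts["erms_sy_curves"] = sy_path

    with _stage("erms-calibrate"):
        pure_cyc = [curves[s.sample_id] for s in samples if s.ratio == 0.0]
        pure_lin = [curves[s.sample_id] for s in samples if s.ratio == 1.0]
        if not pure_cyc or not pure_lin:
            raise ConfigurationError(
                "ER-MS calibration needs pure standards at x = 0 and x = 1 "
                "for the reference curves"
            )
        cyc_ref = average_curves(pure_cyc)
        lin_ref = average_curves(pure_lin)
        log.info(
            "ER-MS references: %d cyclic and %d linear replicate curves averaged",
            len(pure_cyc), len(pure_lin),
        )

        v22 = config.univariate_voltage
        delta_all, cls_all = [], []
        for s in samples:
            curve = curves[s.sample_id]
            delta_all.append(
                CalibrationStandard(
                    ratio=s.ratio,
                    replicate=s.replicate,
                    response=delta_sy_response(curve, cyc_ref, v22),
                )
            )
            cls_all.append(
                CalibrationStandard(
                    ratio=s.ratio,
                    replicate=s.replicate,
                    response=cls_coefficient(curve, lin_ref, cyc_ref).a,
                )
            )
        low = lambda st: [s for s in st if s.ratio <= config.calibration_max_ratio + 1e-12]
        delta_low, cls_low = low(delta_all), low(cls_all)
        log.info(
            "ER-MS univariate calibration at %.2f V on %d standards (x <= %g)",
            v22, len(delta_low), config.calibration_max_ratio,
        )

        uni = fit_univariate(delta_low)
        cls_reg = fit_univariate(cls_low)
        seg = fit_segmented(delta_all, breakpoint=config.segmented_breakpoint)
        quad = fit_quadratic(delta_all)
        for name, model in (
            ("erms_univariate", uni),
            ("erms_cls", cls_reg),
            ("erms_segmented", seg),
            ("erms_quadratic", quad),
        ):
            path = outdir / f"model_{name}.json"
            cio.write_model_json(model, path)
            artefacts[f"model_{name}"] = path

    with _stage("erms-predict"):
        def predictions(model, standards):
            return [
                _predict_for_standard(model, s.response, s.ratio) for s in standards
            ]

        pred_sets = {
            "univariate": (uni, delta_low),
            "CLS": (cls_reg, cls_low),
            "segmented": (seg, delta_all),
            "quadratic": (quad, delta_all),
        }
        records = []
        preds = {}
        for name, (model, standards) in pred_sets.items():
            p = predictions(model, standards)
            preds[name] = p
            for s, yhat in zip(standards, p):
                records.append(
                    (f"erms_x{s.ratio:.3f}_rep{s.replicate}:{name}",
                     s.ratio, s.replicate, s.response, yhat)
                )
        pred_path = outdir / "erms_predictions.csv"
        cio.write_predictions_csv(records, pred_path)
        artefacts["erms_predictions"] = pred_path

    with _stage("erms-fom"):
        low_iv = (0.0, config.calibration_max_ratio)
        cls_rmsec = float(
            np.sqrt(np.mean((np.array(preds["CLS"]) - np.array([s.ratio for s in cls_low])) ** 2))
        )
        reports = [
            _fom_row_from_standards(
                "ERMS", "univariate", delta_low, uni, preds["univariate"],
                linearity_interval=low_iv, r2=uni.r2, lod=lod_univariate(uni),
            ),
            _fom_row_from_standards(
                "ERMS", "CLS", cls_low, cls_reg, preds["CLS"],
                linearity_interval=low_iv, r2=cls_reg.r2,
                lod=lod_univariate(cls_reg),
                lod_alt=lod_multivariate(cls_rmsec), lod_alt_rule="3.3*RMSEC",
            ),
            _fom_row_from_standards(
                "ERMS", "segmented", delta_all, seg, preds["segmented"],
                linearity_interval=(0.0, 1.0),
                r2=min(seg.low_model.r2, seg.high_model.r2),
                lod=lod_univariate(seg.low_model),
            ),
            _fom_row_from_standards(
                "ERMS", "quadratic", delta_all, quad, preds["quadratic"],
                linearity_interval=(0.0, 1.0), r2=quad.r2,
                lod=lod_univariate(
                    UnivariateModel(b0=quad.c0, b1=quad.c1, se=quad.se, r2=quad.r2, n=quad.n)
                ),
            ),
        ]
    return reports, artefacts


def _run_ir(config: RunConfig, outdir: Path):
    artefacts = {}

    with _stage("ir-input", config.ir_matrix_path):
        if config.simulate:
            dataset = simulate_ir_dataset(config.ir_sim, config.ir_design)
        else:
            manifest = (
                cio.read_manifest_json(config.ir_manifest_path)
                if config.ir_manifest_path
                else None
            )
            dataset = cio.read_ir_matrix_csv(config.ir_matrix_path, manifest=manifest)
        raw_path = outdir / "ir_matrix_raw.csv"
        cio.write_ir_matrix_csv(dataset, raw_path)
        cio.write_manifest_json(
            {
                "ratios": {sid: r for sid, r in zip(dataset.sample_ids, dataset.ratios)},
                "replicates": {
                    sid: int(r) for sid, r in zip(dataset.sample_ids, dataset.replicates)
                },
                "seed": config.seed,
                "config": dataclasses.asdict(config.ir_sim) if config.simulate else None,
            },
            outdir / "ir_manifest.json",
        )
        artefacts["ir_matrix_raw"] = raw_path
        artefacts["ir_manifest"] = outdir / "ir_manifest.json"

    with _stage("ir-preprocess"):
        # Order: normalise to mean absorbance, then AsLS-correct each spectrum.
        normalised = [normalise_mean(s) for s in dataset.spectra()]
        asls_params = config.asls
        if config.tune_p and config.tune_lam:
            asls_params, table = tune_asls(
                normalised, config.tune_p, config.tune_lam, dataset.ratios,
                max_lv=config.max_lv,
            )
            log.info("AsLS tuning table:\n%s", table.to_string(index=False))
        log.info("AsLS parameters: lam=%g p=%g", asls_params.lam, asls_params.p)
        corrected = dataset.with_absorbance(
            np.vstack([asls_baseline(s, asls_params)[1].absorbance for s in normalised])
        )
        corr_path = outdir / "ir_matrix_corrected.csv"
        cio.write_ir_matrix_csv(corrected, corr_path)
        artefacts["ir_matrix_corrected"] = corr_path

    with _stage("ir-calibrate"):
        standards = [
            CalibrationStandard(
                ratio=float(corrected.ratios[i]),
                replicate=int(corrected.replicates[i]),
                response=band_area(corrected.spectrum(i)),
            )
            for i in range(len(corrected))
        ]
        uni = fit_univariate(standards)
        n_levels = np.unique(corrected.ratios).size
        pls = fit_pls(corrected.absorbance, corrected.ratios,
                      max_lv=config.max_lv, n_splits=n_levels)
        log.info("IR PLS: %d latent variables, RMSEC=%.4f, RMSECV=%.4f",
                 pls.n_lv, pls.rmsec, pls.rmsecv)
        for name, model in (("ir_univariate", uni), ("ir_pls", pls)):
            path = outdir / f"model_{name}.json"
            cio.write_model_json(model, path)
            artefacts[f"model_{name}"] = path

    with _stage("ir-predict"):
        uni_pred = [predict_ratio(uni, s.response) for s in standards]
        pls_pred = pls.y_pred_cal
        records = [
            (f"{sid}:univariate", s.ratio, s.replicate, s.response, yhat)
            for sid, s, yhat in zip(corrected.sample_ids, standards, uni_pred)
        ] + [
            (f"{sid}:PLS", float(r), int(rep), np.nan, float(yhat))
            for sid, r, rep, yhat in zip(
                corrected.sample_ids, corrected.ratios, corrected.replicates, pls_pred
            )
        ]
        pred_path = outdir / "ir_predictions.csv"
        cio.write_predictions_csv(records, pred_path)
        artefacts["ir_predictions"] = pred_path

    with _stage("ir-fom"):
        reports = [
            _fom_row_from_standards(
                "IR", "univariate", standards, uni, uni_pred,
                linearity_interval=(0.0, 1.0), r2=uni.r2, lod=lod_univariate(uni),
            ),
            make_fom_report(
                technique="IR",
                model="PLS",
                ratios=corrected.ratios,
                replicates=corrected.replicates,
                predicted=pls_pred,
                linearity_interval=(0.0, 1.0),
                r2=pls.r2_cal,
                lod=lod_multivariate(pls.rmsec),
                rmsecv=pls.rmsecv,
                lod_rule="3.3*RMSEC",
            ),
        ]
    return reports, artefacts


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured branches and return the artefact manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run: branch=%s seed=%d simulate=%s outdir=%s",
             config.branch, config.seed, config.simulate, outdir)

    reports = []
    artefacts = {}
    if config.branch in ("erms", "both"):
        r, a = _run_erms(config, outdir)
        reports += r
        artefacts.update(a)
    if config.branch in ("ir", "both"):
        r, a = _run_ir(config, outdir)
        reports += r
        artefacts.update(a)

    with _stage("report"):
        report_csv = outdir / "fom_report.csv"
        report_json = outdir / "fom_report.json"
        reports_to_csv(reports, report_csv)
        reports_to_json(reports, report_json)
        artefacts["fom_report_csv"] = report_csv
        artefacts["fom_report_json"] = report_json

        config_path = outdir / "resolved_config.json"
        resolved = dataclasses.asdict(config)
        resolved.pop("outdir")  # implied by location; keeps reruns byte-identical
        cio.write_manifest_json(resolved, config_path)
        artefacts["resolved_config"] = config_path

        manifest = {
            "branch": config.branch,
            "seed": config.seed,
            "n_report_rows": len(reports),
            "files": {
                name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                for name, p in sorted(artefacts.items())
            },
        }
        cio.write_manifest_json(manifest, outdir / "manifest.json")
    return manifest
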