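"""End-to-end experiment orchestration.

``run_pipeline`` chains generate -> preprocess -> screen -> split ->
train (SMLR, PLS, iPLS, SA-PLS) -> compare and writes every intermediate
artifact as CSV plus a machine-readable run manifest.
``compare_preprocessing`` benchmarks the five preprocessing treatments
under a full-spectrum PLS model.

Every stochastic stage derives its own seed from the global seed and the
stage name, so stage results do not depend on execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import make_grid
from .metrics import ModelReport, build_report
from .pls import cross_validate, fit_pls
from .preprocessing import TREATMENTS, PreprocessSpec, apply_preprocessing
from .screening import cohort_stats, kennard_stone, random_split, screen_outliers
from .selection import AnnealConfig, anneal, ipls, smlr
from .spectra_io import SpectrumSet, join_reference, write_reference, write_spectra, ReferenceTable
from .synthetic import GeneratorConfig, simulate

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "compare_preprocessing", "derive_seed"]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "label", "n_lv", "n_variables", "rc", "rmsec", "rp", "rmsep", "rmsecv",
    "sec", "sep", "offset", "rpd", "rc_pearson", "rp_pearson",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, independent of stage order."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessSpec = field(default_factory=lambda: PreprocessSpec(2, "norris"))
    screening_enabled: bool = True
    screening_alpha: float = 0.05
    n_cal: int = 118
    split_method: str = "kennard_stone"  # or "random"
    smlr_window: tuple[float, float] = (9503.48, 7347.46)
    smlr_p_enter: float = 0.05
    smlr_p_remove: float = 0.10
    smlr_max_vars: int = 15
    ipls_intervals: int = 9
    max_lv: int = 10
    n_folds: int = 10
    sa: AnnealConfig = field(default_factory=AnnealConfig)
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_raw = raw.pop("generator", {})
        if "grid" in gen_raw:
            g = gen_raw.pop("grid")
            gen_raw["grid"] = make_grid(g["start"], g["end"], g["n_points"])
        pre_raw = raw.pop("preprocess", {})
        sa_raw = raw.pop("sa", {})
        cfg = cls(
            generator=GeneratorConfig(**gen_raw),
            preprocess=(
                PreprocessSpec.from_label(pre_raw)
                if isinstance(pre_raw, str)
                else PreprocessSpec(**pre_raw)
            ),
            sa=AnnealConfig(**sa_raw),
            **{k: tuple(v) if k == "smlr_window" else v for k, v in raw.items()},
        )
        return cfg

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if hasattr(obj, "values") and not isinstance(obj, (dict, str)):
                return np.asarray(obj.values).tolist()
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        blob = json.dumps(encode(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    comparison: pd.DataFrame
    reports: dict[str, ModelReport]
    split: "object"
    outliers: "object | None"
    sa_trace: "object"
    sa_mask: "object"
    cohorts: pd.DataFrame
    manifest: dict


def _reports_frame(reports: dict[str, ModelReport]) -> pd.DataFrame:
    rows = [r.as_dict() for r in reports.values()]
    return pd.DataFrame(rows)[REPORT_COLUMNS]


def _write_csv(df: pd.DataFrame, outdir: Path | None, name: str, manifest: dict) -> None:
    if outdir is None:
        return
    path = outdir / name
    df.to_csv(path, index=False)
    manifest["outputs"][name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full four-model comparison experiment."""
    cfg.generator.validate()
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "global_seed": cfg.seed,
        "stage_seeds": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # -- generate ----------------------------------------------------------
    gen_cfg = dataclasses.replace(cfg.generator, seed=derive_seed(cfg.seed, "generate"))
    manifest["stage_seeds"]["generate"] = gen_cfg.seed
    spectra, truth = simulate(gen_cfg)
    reference = ReferenceTable(dict(zip(spectra.sample_ids, truth.reference_concentrations)))
    if outdir is not None:
        write_spectra(spectra, outdir / "spectra.csv")
        write_reference(reference, outdir / "reference.csv")

    # -- preprocess --------------------------------------------------------
    processed = apply_preprocessing(cfg.preprocess, spectra)
    if outdir is not None:
        write_spectra(processed, outdir / "preprocessed.csv")

    # -- screen ------------------------------------------------------------
    outliers = None
    retained = processed
    if cfg.screening_enabled:
        outliers = screen_outliers(processed, alpha=cfg.screening_alpha)
        keep = [sid for sid in processed.sample_ids if sid not in outliers.excluded_ids]
        retained = processed.subset(keep)
        _write_csv(pd.DataFrame(outliers.to_rows()), outdir, "outliers.csv", manifest)
        if outliers.excluded_ids:
            logger.info("screening excluded %d sample(s): %s", len(outliers.excluded_ids), outliers.excluded_ids)

    # -- split -------------------------------------------------------------
    n_cal = min(cfg.n_cal, retained.n_samples - 2)
    if cfg.split_method == "kennard_stone":
        split = kennard_stone(retained, n_cal)
    elif cfg.split_method == "random":
        split = random_split(retained, n_cal, derive_seed(cfg.seed, "split"))
        manifest["stage_seeds"]["split"] = derive_seed(cfg.seed, "split")
    else:
        raise ValueError(f"unknown split_method {cfg.split_method!r}")
    cal_set = retained.subset(split.calibration_ids)
    val_set = retained.subset(split.validation_ids)
    y_cal = join_reference(cal_set, reference)
    y_val = join_reference(val_set, reference)
    X_cal, X_val = cal_set.absorbance, val_set.absorbance

    cohorts = pd.DataFrame(
        [
            {"cohort": "calibration", **dataclasses.asdict(cohort_stats(y_cal))},
            {"cohort": "validation", **dataclasses.asdict(cohort_stats(y_val))},
        ]
    )
    split_df = pd.DataFrame(
        [{"sample_id": s, "subset": "calibration"} for s in split.calibration_ids]
        + [{"sample_id": s, "subset": "validation"} for s in split.validation_ids]
    )
    _write_csv(split_df, outdir, "split.csv", manifest)
    _write_csv(cohorts, outdir, "cohorts.csv", manifest)

    grid = retained.grid
    reports: dict[str, ModelReport] = {}

    # -- SMLR --------------------------------------------------------------
    smlr_model = smlr(
        X_cal, y_cal, grid,
        window=cfg.smlr_window,
        p_enter=cfg.smlr_p_enter,
        p_remove=cfg.smlr_p_remove,
        max_vars=cfg.smlr_max_vars,
    )
    reports["SMLR"] = build_report(
        smlr_model, (X_cal, y_cal), (X_val, y_val), label="SMLR",
        n_variables=int(smlr_model.selected.size),
    )

    # -- full-spectrum PLS -------------------------------------------------
    cv_seed = derive_seed(cfg.seed, "pls_cv")
    manifest["stage_seeds"]["pls_cv"] = cv_seed
    pls_cv = cross_validate(X_cal, y_cal, max_lv=cfg.max_lv, n_folds=cfg.n_folds, seed=cv_seed)
    pls_model = fit_pls(X_cal, y_cal, pls_cv.chosen_n_lv)
    reports["PLS"] = build_report(
        pls_model, (X_cal, y_cal), (X_val, y_val), cv_curve=pls_cv, label="PLS",
        n_variables=X_cal.shape[1],
    )

    # -- iPLS --------------------------------------------------------------
    interval_set = ipls(
        X_cal, y_cal, grid,
        n_intervals=cfg.ipls_intervals, max_lv=cfg.max_lv, n_folds=cfg.n_folds, cv_seed=cv_seed,
    )
    best = interval_set.best_model
    cols = interval_set.best_model.variable_subset
    reports["iPLS"] = build_report(
        _SubsetPredictor(best, cols), (X_cal, y_cal), (X_val, y_val),
        cv_curve=interval_set.cv_curves[interval_set.best_index], label="iPLS",
        n_variables=int(cols.size),
    )
    interval_df = pd.DataFrame(
        {
            "interval": np.arange(1, len(interval_set.boundaries) + 1),
            "low_cm1": [b[0] for b in interval_set.boundaries],
            "high_cm1": [b[1] for b in interval_set.boundaries],
            "rmsecv": interval_set.rmsecv,
            "best": [i == interval_set.best_index for i in range(len(interval_set.boundaries))],
        }
    )
    _write_csv(interval_df, outdir, "ipls_intervals.csv", manifest)

    # -- simulated annealing ----------------------------------------------
    sa_cfg = dataclasses.replace(cfg.sa, seed=derive_seed(cfg.seed, "anneal"))
    manifest["stage_seeds"]["anneal"] = sa_cfg.seed
    sa_mask, sa_model, sa_trace = anneal(X_cal, y_cal, X_val, y_val, sa_cfg)
    # the SA objective is scored on the validation set, so its Rp is
    # selection-biased; the label makes that explicit in the comparison
    reports["SA"] = build_report(
        _SubsetPredictor(sa_model, sa_mask.indices), (X_cal, y_cal), (X_val, y_val),
        label="SA", n_variables=sa_mask.m,
    )
    trace_df = pd.DataFrame(
        {
            "iteration": sa_trace.iteration,
            "delta_e": sa_trace.delta_e,
            "temperature": sa_trace.temperature,
            "accepted": sa_trace.accepted,
            "m": sa_trace.m,
            "objective": sa_trace.objective,
            "best_objective": sa_trace.best_objective,
        }
    )
    retention_df = pd.DataFrame(
        {"wavenumber_cm1": grid.values, "retained": sa_mask.V.astype(int)}
    )
    _write_csv(trace_df, outdir, "sa_trace.csv", manifest)
    _write_csv(retention_df, outdir, "sa_retention.csv", manifest)

    comparison = _reports_frame(reports)
    _write_csv(comparison, outdir, "comparison.csv", manifest)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if outdir is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        comparison=comparison,
        reports=reports,
        split=split,
        outliers=outliers,
        sa_trace=sa_trace,
        sa_mask=sa_mask,
        cohorts=cohorts,
        manifest=manifest,
    )


class _SubsetPredictor:
    """Adapter exposing a column-subset model on full-width matrices."""

    def __init__(self, model, columns: np.ndarray):
        self._model = model
        self._columns = np.asarray(columns, dtype=int)
        self.n_lv = getattr(model, "n_lv", 0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict(np.asarray(X)[:, self._columns])


def compare_preprocessing(cfg: PipelineConfig) -> pd.DataFrame:
    """Full-spectrum PLS under each of the five preprocessing treatments.

    Emits one row per treatment with Rc, Rp, SEC, SEP, Offset, RPD, RMSEC
    and RMSEP, mirroring the usual preprocessing-comparison table.
    """
    cfg.generator.validate()
    gen_cfg = dataclasses.replace(cfg.generator, seed=derive_seed(cfg.seed, "generate"))
    spectra, truth = simulate(gen_cfg)
    reference = ReferenceTable(dict(zip(spectra.sample_ids, truth.reference_concentrations)))
    cv_seed = derive_seed(cfg.seed, "pls_cv")

    rows = []
    for label in TREATMENTS:
        spec = PreprocessSpec.from_label(label)
        processed = apply_preprocessing(spec, spectra)
        n_cal = min(cfg.n_cal, processed.n_samples - 2)
        split = kennard_stone(processed, n_cal)
        cal_set = processed.subset(split.calibration_ids)
        val_set = processed.subset(split.validation_ids)
        y_cal = join_reference(cal_set, reference)
        y_val = join_reference(val_set, reference)
        cv = cross_validate(cal_set.absorbance, y_cal, max_lv=cfg.max_lv, n_folds=cfg.n_folds, seed=cv_seed)
        model = fit_pls(cal_set.absorbance, y_cal, cv.chosen_n_lv)
        report = build_report(
            model, (cal_set.absorbance, y_cal), (val_set.absorbance, y_val),
            cv_curve=cv, label=label,
        )
        rows.append(report.as_dict())
    df = pd.DataFrame(rows)[["label", "n_lv", "rc", "rp", "sec", "sep", "offset", "rpd", "rmsec", "rmsep", "rmsecv"]]
    if cfg.outdir:
        outpath = Path(cfg.outdir)
        outpath.mkdir(parents=True, exist_ok=True)
        df.to_csv(outpath / "preprocessing_comparison.csv", index=False)
    return df
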