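"""End-to-end study orchestration.

Reproduces the full study design on simulated or on-disk data:

1. simulate (or load) replicate spectra + reference IgG;
2. per-sample preprocessing (filter/normalize/region-select, Dixon screen,
   replicate averaging);
3. exclusion of samples whose reference IgG falls outside the working range
   of their RID kit (standard 196–2748 mg/dL, ultra-low 10–100 mg/dL);
4. every-third prediction split: samples sorted by reference IgG, 1-based
   ranks 1, 4, 7, ... become the prediction set (67 of 200), the rest the
   calibration set (133);
5. Monte Carlo CV factor selection on the calibration set and final refit;
6. evaluation on the held-out prediction set (agreement, precision,
   FTPI diagnostics), with artifacts written to disk.

Everything is reproducible from the seeds in the RunConfig.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate, evaluate, preprocess, simulate, spectra_io
from .calibrate import MCCVResult, PLS1Model
from .evaluate import AgreementReport, DiagnosticTable, PrecisionRecord
from .preprocess import PreprocessSpec
from .simulate import SimulationConfig, SyntheticDataset
from .spectra_io import SampleRecord, WavenumberGrid

__all__ = [
    "KIT_RANGES",
    "VARIANTS",
    "SplitPlan",
    "RunConfig",
    "RunResult",
    "variant_spec",
    "exclude_out_of_range",
    "split_every_third",
    "preprocess_dataset",
    "compare_preprocessing",
    "run_full",
]

logger = logging.getLogger("atrigg")

KIT_RANGES: dict[str, tuple[float, float]] = {
    "standard": (196.0, 2748.0),
    "ultra_low": (10.0, 100.0),
}

# the nine preprocessing variants compared in the study, as named presets
VARIANTS: dict[str, PreprocessSpec] = {
    "smooth": PreprocessSpec(smoothing="savitzky_golay"),
    "smooth+snv": PreprocessSpec(smoothing="savitzky_golay", normalization="snv"),
    "smooth+vector": PreprocessSpec(smoothing="savitzky_golay", normalization="vector"),
    "d1": PreprocessSpec(derivative="first"),
    "d1+snv": PreprocessSpec(derivative="first", normalization="snv"),
    "d1+vector": PreprocessSpec(derivative="first", normalization="vector"),
    "d2": PreprocessSpec(derivative="second"),
    "d2+snv": PreprocessSpec(derivative="second", normalization="snv"),
    "d2+vector": PreprocessSpec(derivative="second", normalization="vector"),
}


def variant_spec(name_or_spec) -> PreprocessSpec:
    if isinstance(name_or_spec, PreprocessSpec):
        return name_or_spec
    try:
        return VARIANTS[str(name_or_spec)]
    except KeyError:
        raise ValueError(
            f"unknown preprocessing variant {name_or_spec!r}; known: {sorted(VARIANTS)}"
        ) from None


# ---------------------------------------------------------------------------
# Exclusion and splitting
# ---------------------------------------------------------------------------

def exclude_out_of_range(
    samples, ranges: dict[str, tuple[float, float]] | None = None
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Partition samples by whether the reference IgG lies inside the closed
    working range of the sample's RID kit."""
    ranges = dict(KIT_RANGES if ranges is None else ranges)
    retained: list[SampleRecord] = []
    excluded: list[SampleRecord] = []
    for rec in samples:
        if rec.kit not in ranges:
            raise ValueError(f"sample {rec.sample_id}: unknown kit {rec.kit!r}")
        low, high = ranges[rec.kit]
        ok = low <= rec.igg_reference <= high
        (retained if ok else excluded).append(rec.with_in_range(ok))
    logger.info("exclusion: %d retained, %d out of range", len(retained), len(excluded))
    return retained, excluded


@dataclass(frozen=True)
class SplitPlan:
    """Every-third prediction split over the retained samples."""

    prediction_ids: tuple[str, ...]
    calibration_ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.prediction_ids) + list(self.calibration_ids),
                "set": ["prediction"] * len(self.prediction_ids)
                + ["calibration"] * len(self.calibration_ids),
            }
        )


def split_every_third(samples) -> SplitPlan:
    """Sort ascending by reference IgG (ties by sample_id) and send 1-based
    ranks 1, 4, 7, ... to the prediction set.

    This offset makes the prediction set span the full IgG range and yields
    67 prediction / 133 calibration samples from 200 retained.
    """
    records = list(samples)
    if len(records) < 3:
        raise ValueError("need at least 3 samples to split")
    ordered = sorted(records, key=lambda r: (r.igg_reference, r.sample_id))
    prediction = tuple(r.sample_id for r in ordered[0::3])
    calibration = tuple(r.sample_id for i, r in enumerate(ordered) if i % 3 != 0)
    logger.info("split: %d prediction, %d calibration", len(prediction), len(calibration))
    return SplitPlan(prediction_ids=prediction, calibration_ids=calibration)


# ---------------------------------------------------------------------------
# Dataset-level preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessedDataset:
    """Per-sample averaged spectra on the selected subgrid, plus audit data."""

    grid: WavenumberGrid
    sample_ids: tuple[str, ...]
    X: np.ndarray                         # (n_samples, n_selected_points)
    reports: dict[str, preprocess.OutlierReport]
    replicates: dict[str, np.ndarray]     # surviving preprocessed replicates

    def rows_for(self, ids) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return self.X[[index[s] for s in ids]]


def preprocess_dataset(
    grid: WavenumberGrid,
    spectra: dict[str, np.ndarray],
    spec: PreprocessSpec,
) -> PreprocessedDataset:
    """Run the per-sample preprocessing chain over a whole dataset."""
    sample_ids = tuple(spectra)
    rows = []
    reports = {}
    survivors = {}
    subgrid = None
    for sid in sample_ids:
        result = preprocess.apply_pipeline(spectra[sid], grid, spec)
        rows.append(result.values)
        reports[sid] = result.report
        survivors[sid] = result.replicates
        subgrid = result.grid
    return PreprocessedDataset(
        grid=subgrid,
        sample_ids=sample_ids,
        X=np.vstack(rows),
        reports=reports,
        replicates=survivors,
    )


def _dataset_spectra(dataset: SyntheticDataset) -> dict[str, np.ndarray]:
    return {rec.sample_id: mat for rec, mat in zip(dataset.samples, dataset.spectra)}


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    Input is either a simulation config or a manifest path.  ``variant``
    names the preprocessing preset used for the final model; ``variants``
    lists the presets swept by ``compare_preprocessing``.
    """

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    manifest: str | None = None
    variant: str = "smooth+snv"
    variants: tuple[str, ...] = tuple(VARIANTS)
    kit_ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(KIT_RANGES))
    cutoff: float = evaluate.FTPI_CUTOFF
    k_max: int = 30
    mccv_repeats: int = 10_000
    mccv_train_size: int | None = None
    seed: int = 0
    write_spectra: bool = False

    def __post_init__(self) -> None:
        if self.simulation is None and self.manifest is None:
            raise ValueError("either a simulation config or a manifest is required")
        if not self.variants:
            raise ValueError("at least one preprocessing variant is required")
        for name, (low, high) in self.kit_ranges.items():
            if not low < high:
                raise ValueError(f"invalid working range for kit {name!r}")

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        doc = yaml.safe_load(Path(source).read_text()) or {}
        sim = doc.pop("simulation", None)
        config = cls(
            simulation=SimulationConfig(**sim) if isinstance(sim, dict) else None,
            manifest=doc.pop("manifest", None),
            **{
                k: tuple(v) if k == "variants" else v
                for k, v in doc.items()
                if k in cls.__dataclass_fields__
            },
        )
        return config

    def to_yaml(self, destination) -> None:
        doc = {
            "variant": self.variant,
            "variants": list(self.variants),
            "kit_ranges": {k: list(v) for k, v in self.kit_ranges.items()},
            "cutoff": self.cutoff,
            "k_max": self.k_max,
            "mccv_repeats": self.mccv_repeats,
            "mccv_train_size": self.mccv_train_size,
            "seed": self.seed,
        }
        if self.manifest is not None:
            doc["manifest"] = self.manifest
        if self.simulation is not None:
            sim = self.simulation
            doc["simulation"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in sim.__dict__.items()
            }
        Path(destination).write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# Comparison of preprocessing variants
# ---------------------------------------------------------------------------

def _calibrate_and_evaluate(
    pp: PreprocessedDataset,
    records: list[SampleRecord],
    plan: SplitPlan,
    k_max: int,
    mccv_repeats: int,
    mccv_train_size: int | None,
    seed: int,
):
    """Shared core: MCCV, final fit, predictions, agreement metrics."""
    igg = {r.sample_id: r.igg_reference for r in records}
    X_cal = pp.rows_for(plan.calibration_ids)
    y_cal = np.array([igg[s] for s in plan.calibration_ids])
    X_pred = pp.rows_for(plan.prediction_ids)
    y_pred = np.array([igg[s] for s in plan.prediction_ids])

    k_cap = min(k_max, (mccv_train_size or -(-len(y_cal) // 2)) - 1, X_cal.shape[1])
    mccv = calibrate.mccv_select_factors(
        X_cal,
        y_cal,
        k_max=k_cap,
        n_repeats=mccv_repeats,
        train_size=mccv_train_size,
        seed=seed,
    )
    model = calibrate.fit_final_model(X_cal, y_cal, mccv.chosen_k)
    yhat_cal = calibrate.predict(model, X_cal)
    yhat_pred = calibrate.predict(model, X_pred)
    report = evaluate.evaluate_agreement(y_cal, yhat_cal, y_pred, yhat_pred)
    return mccv, model, (y_cal, yhat_cal), (y_pred, yhat_pred), report


def compare_preprocessing(
    grid: WavenumberGrid,
    spectra: dict[str, np.ndarray],
    records: list[SampleRecord],
    variants=None,
    k_max: int = 30,
    mccv_repeats: int = 500,
    mccv_train_size: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep preprocessing variants and report one row per variant.

    Columns follow the study's comparison table: chosen factor count,
    RMMCCV at that count, calibration r and RMSEC, prediction r, RMSEP,
    RPD and RER.  The winner (lowest RMMCCV) is reported in the log, not
    silently selected.
    """
    names = list(variants or VARIANTS)
    if not names:
        raise ValueError("need at least one variant")
    retained, _ = exclude_out_of_range(records)
    rows = []
    for name in names:
        spec = variant_spec(name)
        pp = preprocess_dataset(grid, {r.sample_id: spectra[r.sample_id] for r in retained}, spec)
        plan = split_every_third(retained)
        mccv, model, _, _, rep = _calibrate_and_evaluate(
            pp, retained, plan, k_max, mccv_repeats, mccv_train_size, seed
        )
        rows.append(
            {
                "variant": name,
                "pls_factors": mccv.chosen_k,
                "rmmccv": mccv.rmmccv[mccv.chosen_k - 1],
                "r_calibration": rep.pearson_r_calibration,
                "rmsec": rep.rmsec,
                "r_prediction": rep.pearson_r,
                "rmsep": rep.rmsep,
                "rpd": rep.rpd,
                "rer": rep.rer,
            }
        )
    frame = pd.DataFrame(rows)
    best = frame.loc[frame["rmmccv"].idxmin(), "variant"]
    logger.info("lowest RMMCCV variant: %s", best)
    return frame


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunResult:
    """Everything a full run produces."""

    agreement: AgreementReport
    diagnostics_prediction: DiagnosticTable
    diagnostics_all: DiagnosticTable
    mccv: MCCVResult
    model: PLS1Model
    split: SplitPlan
    precision: tuple[PrecisionRecord, ...]
    n_retained: int
    n_excluded: int
    y_prediction: np.ndarray
    yhat_prediction: np.ndarray
    y_calibration: np.ndarray
    yhat_calibration: np.ndarray

    @property
    def mean_cv_star(self) -> float:
        return float(np.mean([p.cv_star for p in self.precision]))

    def metrics_dict(self) -> dict:
        return {
            "agreement": self.agreement.to_dict(),
            "diagnostics_prediction": self.diagnostics_prediction.to_dict(),
            "diagnostics_all": self.diagnostics_all.to_dict(),
            "chosen_k": self.mccv.chosen_k,
            "rmmccv_at_chosen_k": float(self.mccv.rmmccv[self.mccv.chosen_k - 1]),
            "mean_cv_star_atr": self.mean_cv_star,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "n_prediction": len(self.split.prediction_ids),
            "n_calibration": len(self.split.calibration_ids),
        }


def _replicate_precision(
    pp: PreprocessedDataset, model: PLS1Model, ids
) -> tuple[PrecisionRecord, ...]:
    """CV* of the assay from per-replicate predictions of the final model."""
    records = []
    for sid in ids:
        preds = calibrate.predict(model, pp.replicates[sid])
        if np.mean(preds) == 0:
            continue
        records.append(evaluate.cv_star(preds, sample_id=sid))
    return tuple(records)


def run_full(config: RunConfig, outdir=None) -> RunResult:
    """Execute the whole study design; optionally write artifacts to outdir."""
    if config.manifest is not None:
        logger.info("loading manifest %s", config.manifest)
        records, grid, spectra = spectra_io.read_manifest(config.manifest)
        dataset = None
    else:
        logger.info("simulating dataset (seed %d)", config.simulation.seed)
        dataset = simulate.simulate_dataset(config.simulation)
        records = list(dataset.samples)
        grid, spectra = dataset.grid, _dataset_spectra(dataset)

    retained, excluded = exclude_out_of_range(records, config.kit_ranges)
    if len(retained) < 3:
        raise RuntimeError("exclusion left fewer than 3 samples")
    plan = split_every_third(retained)

    spec = variant_spec(config.variant)
    pp = preprocess_dataset(grid, {r.sample_id: spectra[r.sample_id] for r in retained}, spec)

    mccv, model, (y_cal, yhat_cal), (y_pred, yhat_pred), agreement = _calibrate_and_evaluate(
        pp, retained, plan, config.k_max, config.mccv_repeats, config.mccv_train_size, config.seed
    )
    logger.info("chosen k = %d, RMMCCV = %.1f mg/dL", mccv.chosen_k, mccv.rmmccv[mccv.chosen_k - 1])

    diag_pred = evaluate.diagnostic_table(y_pred, yhat_pred, config.cutoff)
    y_all = np.concatenate([y_pred, y_cal])
    yhat_all = np.concatenate([yhat_pred, yhat_cal])
    diag_all = evaluate.diagnostic_table(y_all, yhat_all, config.cutoff)
    precision = _replicate_precision(pp, model, plan.prediction_ids)

    result = RunResult(
        agreement=agreement,
        diagnostics_prediction=diag_pred,
        diagnostics_all=diag_all,
        mccv=mccv,
        model=model,
        split=plan,
        precision=precision,
        n_retained=len(retained),
        n_excluded=len(excluded),
        y_prediction=y_pred,
        yhat_prediction=yhat_pred,
        y_calibration=y_cal,
        yhat_calibration=yhat_cal,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        plan.to_frame().to_csv(outdir / "split_plan.csv", index=False)
        pd.concat(
            [rep.to_frame(sid) for sid, rep in pp.reports.items()], ignore_index=True
        ).to_csv(outdir / "outlier_report.csv", index=False)
        mccv.to_frame().to_csv(outdir / "mccv.csv", index=False)
        model.to_json(outdir / "model.json")
        (outdir / "metrics.json").write_text(
            json.dumps(result.metrics_dict(), sort_keys=True, indent=2, allow_nan=True)
        )
        pd.DataFrame([p.__dict__ for p in precision]).to_csv(
            outdir / "precision_cv_star.csv", index=False
        )
        if dataset is not None and config.write_spectra:
            spectra_io.write_dataset(dataset, outdir / "dataset")
    return result


def configure_logging(level: int = logging.INFO, logfile=None) -> None:
    """Stage-level structured logging to stderr and an optional run log."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
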