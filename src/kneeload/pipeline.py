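"""Schema-validated run configuration and the end-to-end pipeline driver.

``run_pipeline`` executes simulate -> ground truth + preprocessing ->
train/evaluate [-> robustness -> summarize] into a run directory, with a
manifest capturing the configuration, seeds and a content hash per stage so
that deterministic stages can be verified to reproduce exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigurationError
from .evaluation import render_results_table, run_experiment
from .msk import Muscle, PlanarLimbModel, default_model
from .preprocess import FeatureTensor, build_tensor
from .regression import ANNConfig, SVRConfig
from .robustness import ContaminationSpec, fit_trend_slope, robustness_curve
from .storage import write_cohort
from .summary import collect_cycles, peak_table
from .synthetic import CohortConfig, make_cohort, synthesize_cohort_trials

log = logging.getLogger("kneeload")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Section):
    n_subjects: int = 8
    speed_grid: list[int] = [3, 4, 5]
    seconds_per_speed: float = 10.0
    noise_sd_angles: float = 0.5
    noise_sd_grf: float = 5.0
    master_seed: int = 0
    sides: list[str] = ["right", "left"]


class MuscleSection(_Section):
    name: str
    f_max: float
    sagittal_moment_arm: float
    compressive_fraction: float


class ModelSection(_Section):
    contact_spacing: float = 0.045
    frontal_alignment: float = 0.0
    reserve_weight: float = 1000.0
    cop_frac: float = 0.25
    muscles: list[MuscleSection] | None = None


class PreprocessSection(_Section):
    cutoff_hz: float = 6.0
    stance_threshold_bw: float = 0.05
    variance_threshold: float = 1e-6
    use_grf: bool = True


class AnnSection(_Section):
    hidden_layers: list[int] = [400, 400]
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    max_epochs: int = 500
    batch_size: int = 256
    validation_fraction: float = 0.1


class SvrSection(_Section):
    kernel_scale: float = 0.6
    epsilon: float = 0.01
    box_constraint: float = 1.0
    max_train_rows: int = 20000


class EvaluationSection(_Section):
    k: int = 3
    schemes: list[str] = ["LeaveTrialsOut", "LeaveSubjectsOut"]
    model_kinds: list[str] = ["svr"]
    fold_seed: int = 0
    delta_y: str = "dataset"  # or "reference"


class RobustnessSection(_Section):
    enabled: bool = False
    proportions: list[float] = [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
    df: float = 2.0
    targets_of_corruption: str = "both"
    model_kind: str = "ann"
    scheme: str = "LeaveTrialsOut"
    seed: int = 0
    targets: list[str] = ["med_y"]


class SummarySection(_Section):
    enabled: bool = True


class RunConfig(_Section):
    """Whole-pipeline configuration; unknown keys are rejected up front."""

    schema_version: int = 1
    cohort: CohortSection = Field(default_factory=CohortSection)
    model: ModelSection = Field(default_factory=ModelSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    ann: AnnSection = Field(default_factory=AnnSection)
    svr: SvrSection = Field(default_factory=SvrSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    robustness: RobustnessSection = Field(default_factory=RobustnessSection)
    summary: SummarySection = Field(default_factory=SummarySection)


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**raw)
    except Exception as exc:
        raise ConfigurationError(f"invalid run configuration: {exc}") from exc


def _cohort_config(section: CohortSection, seed=None) -> CohortConfig:
    return CohortConfig(
        n_subjects=section.n_subjects,
        speed_grid=tuple(section.speed_grid),
        seconds_per_speed=section.seconds_per_speed,
        noise_sd_angles=section.noise_sd_angles,
        noise_sd_grf=section.noise_sd_grf,
        master_seed=section.master_seed if seed is None else seed,
        sides=tuple(section.sides),
    )


def _limb_model(section: ModelSection) -> PlanarLimbModel:
    muscles = (
        default_model().muscles
        if section.muscles is None
        else tuple(Muscle(**m.model_dump()) for m in section.muscles)
    )
    return PlanarLimbModel(
        muscles=muscles,
        contact_spacing=section.contact_spacing,
        frontal_alignment=section.frontal_alignment,
        reserve_weight=section.reserve_weight,
        cop_frac=section.cop_frac,
    )


def save_tensor(tensor: FeatureTensor, directory) -> Path:
    """Persist a tensor: manifest JSON plus per-trial arrays (npz)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for m, (x, y) in enumerate(zip(tensor.X, tensor.Y)):
        arrays[f"X{m}"] = x
        arrays[f"Y{m}"] = y
    np.savez(directory / "tensor.npz", **arrays)
    manifest = {
        "n_trials": tensor.n_trials,
        "feature_names": list(tensor.feature_names),
        "target_names": list(tensor.target_names),
        "meta": tensor.meta.to_dict(orient="records"),
    }
    path = directory / "tensor.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_tensor(directory) -> FeatureTensor:
    import pandas as pd

    directory = Path(directory)
    manifest = json.loads((directory / "tensor.json").read_text())
    with np.load(directory / "tensor.npz") as arrays:
        xs = [arrays[f"X{m}"] for m in range(manifest["n_trials"])]
        ys = [arrays[f"Y{m}"] for m in range(manifest["n_trials"])]
    return FeatureTensor(
        X=xs, Y=ys,
        feature_names=manifest["feature_names"],
        target_names=manifest["target_names"],
        meta=pd.DataFrame(manifest["meta"]),
    )


def _digest(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> Path:
    """Execute all configured stages into ``out_dir``; returns the run dir.

    The manifest records a content hash per stage; a rerun with the same
    configuration and seed reproduces identical hashes for every
    deterministic stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"schema_version": config.schema_version,
                "config": config.model_dump(), "seed": seed, "stages": {}}

    # -- simulate ---------------------------------------------------------
    log.info("stage simulate: generating synthetic cohort")
    cohort_cfg = _cohort_config(config.cohort, seed)
    profiles = make_cohort(cohort_cfg)
    trials = synthesize_cohort_trials(profiles, cohort_cfg)
    write_cohort(trials, out / "trials")
    manifest["stages"]["simulate"] = {
        "n_trials": len(trials),
        "hash": _digest([np.asarray(t.angles).sum() for t in trials]),
    }

    # -- ground truth + preprocess ---------------------------------------
    log.info("stage preprocess: ground truth and tensor assembly")
    limb = _limb_model(config.model)
    tensor, report = build_tensor(
        trials,
        model=limb,
        use_grf=config.preprocess.use_grf,
        variance_threshold=config.preprocess.variance_threshold,
        stance_threshold_bw=config.preprocess.stance_threshold_bw,
    )
    save_tensor(tensor, out / "processed")
    manifest["stages"]["preprocess"] = {
        "n_stances": tensor.n_trials,
        "n_inputs": len(tensor.feature_names),
        "n_outputs": len(tensor.target_names),
        "dropped": report,
        "hash": _digest([float(np.concatenate(tensor.Y, axis=1).sum())]),
    }

    # -- train + evaluate -------------------------------------------------
    ann_cfg = ANNConfig(
        hidden_layers=tuple(config.ann.hidden_layers),
        learning_rate=config.ann.learning_rate,
        early_stop_patience=config.ann.early_stop_patience,
        max_epochs=config.ann.max_epochs,
        batch_size=config.ann.batch_size,
        validation_fraction=config.ann.validation_fraction,
        seed=0 if seed is None else seed,
    )
    svr_cfg = SVRConfig(
        kernel_scale=config.svr.kernel_scale,
        epsilon=config.svr.epsilon,
        box_constraint=config.svr.box_constraint,
        max_train_rows=config.svr.max_train_rows,
    )
    reports = []
    for kind in config.evaluation.model_kinds:
        for scheme in config.evaluation.schemes:
            log.info("stage evaluate: %s / %s", kind, scheme)
            reports.append(
                run_experiment(
                    tensor, kind, scheme,
                    use_grf=config.preprocess.use_grf,
                    ann_cfg=ann_cfg, svr_cfg=svr_cfg,
                    k=config.evaluation.k,
                    seed=config.evaluation.fold_seed if seed is None else seed,
                    delta_y=config.evaluation.delta_y,
                )
            )
    (out / "reports").mkdir(exist_ok=True)
    payload = [r.to_dict() for r in reports]
    (out / "reports" / "evaluation.json").write_text(
        json.dumps(payload, indent=1)
    )
    render_results_table(reports, "nrmse").to_csv(out / "reports" / "nrmse.csv", index=False)
    render_results_table(reports, "r").to_csv(out / "reports" / "pearson_r.csv", index=False)
    manifest["stages"]["evaluate"] = {"hash": _digest(payload)}

    # -- robustness (optional) -------------------------------------------
    if config.robustness.enabled:
        log.info("stage robustness: contamination study")
        spec = ContaminationSpec(
            proportions=tuple(config.robustness.proportions),
            df=config.robustness.df,
            targets_of_corruption=config.robustness.targets_of_corruption,
            seed=config.robustness.seed if seed is None else seed,
        )
        curve = robustness_curve(
            tensor, config.robustness.model_kind, config.robustness.scheme,
            spec=spec, ann_cfg=ann_cfg, svr_cfg=svr_cfg,
            k=config.evaluation.k,
            seed=config.evaluation.fold_seed if seed is None else seed,
            targets=list(config.robustness.targets),
        )
        curve.to_csv(out / "reports" / "robustness.csv")
        slopes = {t: fit_trend_slope(curve, t) for t in curve.columns}
        manifest["stages"]["robustness"] = {
            "slopes": slopes, "hash": _digest(curve.to_dict()),
        }

    # -- summarize (optional) --------------------------------------------
    if config.summary.enabled:
        log.info("stage summarize: ensemble curves and peak table")
        from .msk import compute_kcf
        from .preprocess import detect_stance, preprocess_trial

        processed, stances = [], []
        for trial in trials:
            kcf = compute_kcf(trial, limb)
            pt = preprocess_trial(trial, kcf)
            processed.append(pt)
            stances.append(detect_stance(pt, config.preprocess.stance_threshold_bw))
        cycles = collect_cycles(processed, stances)
        table = peak_table(cycles)
        table.to_csv(out / "reports" / "peak_table.csv")
        manifest["stages"]["summarize"] = {"hash": _digest(table.to_dict())}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
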