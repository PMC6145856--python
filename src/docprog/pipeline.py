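"""End-to-end orchestration: simulate -> preprocess -> features -> train ->
predict -> validate, driven by a single YAML config with a master seed.

Every stage writes its artifacts plus a manifest (config snapshot, seed,
input checksums, package version) so any stage can be re-run from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import spawn_seed
from .exceptions import ConfigurationError, PipelineError
from .features import (
    assemble_feature_table,
    build_network_templates,
    compute_profile,
    network_seed_series,
    save_templates,
    seed_zmap,
)
from .model import ModelConfig, PrognosticPLSModel, PrognosticPLSResults
from .preprocess import (
    BoldRun,
    ExclusionSignal,
    PreprocessConfig,
    load_run,
    preprocess_run,
    save_run,
)
from .roi import RoiSet, example_roiset
from .synthetic import (
    CohortSpec,
    SubjectRecord,
    gen_bold_nifti,
    gen_cohort,
    gen_motion_trace,
    gen_roi_timeseries,
)
from .validation import (
    bland_altman,
    optimism_bootstrap,
    permutation_test,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single human-editable configuration for all pipeline stages."""

    output_dir: str = "docprog_output"
    roi_config: str | None = None  # path; None -> shipped example set
    seed: int = 0
    # simulate
    n_patients: int = 63
    n_controls: int = 30
    roi_count: int = 22
    noise_sd: float = 2.0
    write_volumes: bool = False
    n_volumes: int = 210
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (40, 44, 34)
    voxel_size_mm: float = 4.0
    volume_noise_sd: float = 0.5
    motion_spike_rate: float = 0.02
    # preprocess
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    # model / selection
    model: ModelConfig = field(default_factory=ModelConfig)
    # validation
    optimism_B: int = 200
    permutation_B: int = 99

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pp = PreprocessConfig(**raw.pop("preprocess", {}))
        mc = ModelConfig(**raw.pop("model", {}))
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(preprocess=pp, model=mc, **raw)

    def roiset(self) -> RoiSet:
        if self.roi_config is None:
            return example_roiset()
        path = Path(self.roi_config)
        if not path.exists():
            raise ConfigurationError(f"ROI config not found: {path}")
        return RoiSet.load(path)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, config: RunConfig, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "inputs": {str(p): _checksum(p) for p in inputs if p.exists()},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> Path:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        roi_count=config.roi_count,
        noise_sd=config.noise_sd,
        motion_spike_rate=config.motion_spike_rate,
        seed=config.seed,
    )
    subjects, table, truth = gen_cohort(spec)
    table.to_csv(outdir / "cohort.csv")
    truth_json = {
        "effect_weights": truth["effect_weights"].tolist(),
        "intercept": truth["intercept"],
        "feature_names": truth["feature_names"],
        "seed": truth["seed"],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))

    if config.write_volumes:
        roiset = config.roiset()
        if len(roiset) != spec.roi_count:
            raise ConfigurationError("roi_config size must match roi_count")
        vol_dir = outdir / "volumes"
        vol_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(config.seed)
        for subj in subjects:
            sub_seed = spawn_seed(rng)
            ts = gen_roi_timeseries(
                subj, spec, config.n_volumes, tr=config.tr, seed=sub_seed
            )
            motion = gen_motion_trace(
                config.n_volumes,
                spike_rate=config.motion_spike_rate,
                seed=sub_seed,
            )
            run = gen_bold_nifti(
                ts,
                roiset,
                grid_shape=config.grid_shape,
                voxel_size_mm=config.voxel_size_mm,
                noise_sd=config.volume_noise_sd,
                tr=config.tr,
                seed=sub_seed,
                motion=motion,
            )
            save_run(
                run,
                vol_dir / f"{subj.id}_bold.nii.gz",
                vol_dir / f"{subj.id}_mask.nii.gz",
                vol_dir / f"{subj.id}_motion.tsv",
            )
    _write_manifest(outdir, "simulate", config, [])
    return outdir


def stage_preprocess(config: RunConfig) -> Path:
    outdir = Path(config.output_dir)
    vol_dir = outdir / "volumes"
    if not vol_dir.exists():
        raise ConfigurationError(f"no volumes directory at {vol_dir}")
    prep_dir = outdir / "preprocessed"
    prep_dir.mkdir(exist_ok=True)
    qc: dict = {}
    for bold in sorted(vol_dir.glob("*_bold.nii.gz")):
        sid = bold.name.replace("_bold.nii.gz", "")
        run = load_run(
            bold, vol_dir / f"{sid}_mask.nii.gz", vol_dir / f"{sid}_motion.tsv"
        )
        result = preprocess_run(run, config.preprocess)
        if isinstance(result, ExclusionSignal):
            qc[sid] = {
                "excluded": True,
                "n_remaining": result.n_remaining,
                "reason": result.reason,
            }
            continue
        qc[sid] = {"excluded": False, "volumes_retained": result.n_volumes}
        save_run(
            result,
            prep_dir / f"{sid}_bold.nii.gz",
            prep_dir / f"{sid}_mask.nii.gz",
            prep_dir / f"{sid}_motion.tsv",
        )
        np.savetxt(prep_dir / f"{sid}_kept.tsv", result.kept_volumes, fmt="%d")
    (outdir / "qc_report.json").write_text(json.dumps(qc, indent=2))
    _write_manifest(outdir, "preprocess", config, sorted(vol_dir.glob("*.tsv")))
    return outdir


def _load_cohort_subjects(outdir: Path) -> tuple[pd.DataFrame, list[SubjectRecord]]:
    cohort = pd.read_csv(outdir / "cohort.csv", index_col="id")
    subjects = []
    for sid, row in cohort.iterrows():
        subjects.append(
            SubjectRecord(
                id=sid,
                group=row["group"],
                age=float(row["age"]),
                duration=float(row["duration"]) if row["group"] == "patient" else None,
                etiology=(
                    "stroke"
                    if row["etiology_stroke"] == 1
                    else "anoxia" if row["etiology_anoxia"] == 1 else "trauma"
                )
                if row["group"] == "patient"
                else None,
                crsr_t0=23,
                crsr_t1=int(row["crsr_t1"]) if pd.notna(row["crsr_t1"]) else None,
                gos_t1=int(row["gos_t1"]) if pd.notna(row["gos_t1"]) else None,
            )
        )
    return cohort, subjects


def stage_features(config: RunConfig) -> Path:
    outdir = Path(config.output_dir)
    prep_dir = outdir / "preprocessed"
    if not prep_dir.exists():
        raise ConfigurationError(f"no preprocessed directory at {prep_dir}")
    roiset = config.roiset()
    cohort, subjects = _load_cohort_subjects(outdir)
    runs: dict[str, BoldRun] = {}
    for bold in sorted(prep_dir.glob("*_bold.nii.gz")):
        sid = bold.name.replace("_bold.nii.gz", "")
        runs[sid] = load_run(
            bold, prep_dir / f"{sid}_mask.nii.gz", prep_dir / f"{sid}_motion.tsv"
        )
    controls = [s for s in subjects if s.group == "control" and s.id in runs]
    if len(controls) < 3:
        raise PipelineError("need at least 3 preprocessed controls for templates")
    control_zmaps: dict[str, list[np.ndarray]] = {}
    for ctl in controls:
        run = runs[ctl.id]
        for net, series in network_seed_series(run, roiset).items():
            control_zmaps.setdefault(net, []).append(seed_zmap(run, series))
    templates = build_network_templates(control_zmaps)
    save_templates(templates, outdir / "templates", affine=runs[controls[0].id].affine)

    patients = [s for s in subjects if s.group == "patient" and s.id in runs]
    profiles = [
        compute_profile(runs[s.id], roiset, templates, subject_id=s.id)
        for s in patients
    ]
    feats = assemble_feature_table(profiles, patients, roiset)
    # carry outcomes alongside the features
    feats["crsr_t1"] = [cohort.loc[s.id, "crsr_t1"] for s in patients]
    feats["gos_t1"] = [cohort.loc[s.id, "gos_t1"] for s in patients]
    feats["group"] = "patient"
    feats.to_csv(outdir / "features.csv")
    _write_manifest(outdir, "features", config, [outdir / "cohort.csv"])
    return outdir


def _training_table(config: RunConfig) -> pd.DataFrame:
    outdir = Path(config.output_dir)
    for name in ("features.csv", "cohort.csv"):
        path = outdir / name
        if path.exists():
            return pd.read_csv(path, index_col="id")
    raise ConfigurationError(f"no feature table found in {outdir}")


def stage_train(config: RunConfig) -> PrognosticPLSResults:
    outdir = Path(config.output_dir)
    table = _training_table(config)
    model = PrognosticPLSModel.from_dataframe(table, config=config.model)
    results = model.fit(seed=config.seed)
    results.to_json(outdir / "model.json")
    patients = table[table["group"] == "patient"] if "group" in table else table
    preds = results.predict(patients)
    preds.to_csv(outdir / "training_predictions.csv")
    if results.roc is not None:
        results.roc.curve.to_csv(outdir / "roc_curve.csv", index=False)
    _write_manifest(outdir, "train", config, [outdir / "cohort.csv"])
    return results


def stage_predict(config: RunConfig, table_path: str | Path | None = None) -> pd.DataFrame:
    outdir = Path(config.output_dir)
    model_path = outdir / "model.json"
    if not model_path.exists():
        raise ConfigurationError(f"no trained model at {model_path}")
    results = PrognosticPLSResults.from_json(model_path)
    table = (
        pd.read_csv(table_path, index_col="id")
        if table_path is not None
        else _training_table(config)
    )
    preds = results.predict(table)
    preds.to_csv(outdir / "predictions.csv")
    return preds


def stage_validate(config: RunConfig) -> dict:
    outdir = Path(config.output_dir)
    table = _training_table(config)
    patients = table[table["group"] == "patient"] if "group" in table else table

    report: dict = {}
    opt = optimism_bootstrap(
        patients, config.model, B=config.optimism_B, seed=config.seed
    )
    report["optimism"] = opt.as_dict()

    def _stat(tab: pd.DataFrame, y: np.ndarray) -> float:
        t = tab.copy()
        t["crsr_t1"] = y
        model = PrognosticPLSModel.from_dataframe(t, config=config.model)
        res = model.fit(seed=config.seed)
        return res.rsquared

    perm = permutation_test(
        _stat,
        patients,
        patients["crsr_t1"].to_numpy(dtype=float),
        B=config.permutation_B,
        seed=config.seed,
    )
    report["permutation"] = {"observed_r2": perm["observed"], "p": perm["p"]}

    fit = PrognosticPLSModel.from_dataframe(patients, config=config.model).fit(
        seed=config.seed
    )
    preds = fit.predict(patients)["predicted_score"].to_numpy()
    report["bland_altman"] = {
        k: v
        for k, v in bland_altman(
            preds, patients["crsr_t1"].to_numpy(dtype=float)
        ).items()
    }
    (outdir / "validation_report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(outdir, "validate", config, [outdir / "cohort.csv"])
    return report


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "features": stage_features,
    "train": stage_train,
    "predict": stage_predict,
    "validate": stage_validate,
}


def run_pipeline(config: RunConfig, command: str):
    if command not in STAGES:
        raise ConfigurationError(
            f"unknown command {command!r}; choose from {sorted(STAGES)}"
        )
    return STAGES[command](config)
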