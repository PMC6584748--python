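"""End-to-end orchestration: simulate -> preprocess -> reho -> univariate -> mvpa.

One global seed deterministically derives per-stage sub-seeds, so a full run
is reproducible (hash-identical outputs) and each stage can also be re-run
standalone.  Every run writes a manifest recording parameters, seeds, the
package version and a SHA-256 per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import write_bold, write_cohort, write_map, write_motion
from .mvpa import (build_features, discriminative_map, discriminative_peaks,
                   permutation_test, svm_loocv)
from .preprocess import preprocess_bold, qc_screen
from .reho import subject_reho
from .synth import SyntheticConfig, make_cohort
from .univariate import (cluster_fwe, clinical_correlations,
                         clusters_to_table, demographics, roi_mean)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "reho", "univariate", "mvpa")


@dataclass
class QcParams:
    trans_limit_mm: float = 1.5
    rot_limit_deg: float = 1.5
    mean_fd_limit: float = 0.2
    fd_sphere_radius_mm: float = 50.0


@dataclass
class PreprocessParams:
    low_hz: float = 0.01
    high_hz: float = 0.08
    global_signal: bool = True
    qc: QcParams = field(default_factory=QcParams)


@dataclass
class RehoParams:
    neighborhood: int = 27
    fwhm_mm: float = 8.0
    standardize: bool = True
    require_full_neighborhood: bool = False


@dataclass
class UnivariateParams:
    voxel_p: float = 0.001
    min_extent: int = 100
    cluster_alpha: float = 0.05
    n_perm: int = 1000
    connectivity: int = 18


@dataclass
class MvpaParams:
    svm_c: float = 1.0
    n_perm: int = 1000
    top_fraction: float = 0.30
    threshold_mode: str = "rank-fraction"


@dataclass
class PipelineConfig:
    out_dir: str = "rehopipe_out"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    reho: RehoParams = field(default_factory=RehoParams)
    univariate: UnivariateParams = field(default_factory=UnivariateParams)
    mvpa: MvpaParams = field(default_factory=MvpaParams)
    subset_column: str | None = None
    subset_value: object = None


def _build_dataclass(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if f.name in _NESTED and isinstance(val, dict):
            val = _build_dataclass(_NESTED[f.name], val)
        kwargs[f.name] = val
    return cls(**kwargs)


_NESTED = {
    "synthetic": SyntheticConfig,
    "preprocess": PreprocessParams,
    "reho": RehoParams,
    "univariate": UnivariateParams,
    "mvpa": MvpaParams,
    "qc": QcParams,
}


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from YAML (missing keys fall back to defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "synthetic" in data:
        syn = dict(data["synthetic"])
        if "rois" in syn:
            from .synth import RoiSpec
            syn["rois"] = tuple(
                RoiSpec(**{**r, "center_voxel": tuple(r["center_voxel"])})
                for r in syn["rois"]
            )
        if "clinical_link" in syn:
            from .synth import ClinicalLink
            syn["clinical_link"] = ClinicalLink(**syn["clinical_link"])
        for key in ("shape", "band_hz"):
            if key in syn:
                syn[key] = tuple(syn[key])
        data["synthetic"] = syn
    cfg = _build_dataclass(PipelineConfig, data)
    if not isinstance(cfg.synthetic, SyntheticConfig):
        cfg = dataclasses.replace(cfg, synthetic=SyntheticConfig(**data["synthetic"]))
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the global seed."""
    k = STAGES.index(stage)
    return int(np.random.SeedSequence(entropy=global_seed, spawn_key=(k,))
               .generate_state(1, dtype=np.uint32)[0])


def subset_filter(table: pd.DataFrame, column: str, value) -> pd.DataFrame:
    """Retain patients matching ``column == value`` plus all controls."""
    if column not in table.columns:
        raise KeyError(f"no column {column!r} in cohort table")
    is_patient = table["group"] == "patient"
    keep = ~is_patient | (table[column] == value)
    out = table[keep].reset_index(drop=True)
    if not (out["group"] == "patient").any():
        raise ValueError(f"subset {column}=={value!r} removes all patients")
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order on QC-passing subjects; returns the manifest."""
    out_root = Path(config.out_dir)
    outputs: dict[str, str] = {}

    def register(path: Path):
        outputs[str(path.relative_to(out_root))] = _sha256(path)

    # ----- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        syn_cfg = dataclasses.replace(config.synthetic,
                                      seed=stage_seed(config.seed, stage))
        bolds, motions, cohort, brain, tissue = make_cohort(syn_cfg)
        sim_dir = out_root / stage
        sim_dir.mkdir(parents=True, exist_ok=True)
        write_map(brain.data, brain.affine, sim_dir / "brain_mask.nii.gz")
        for name, m in tissue.items():
            write_map(m.data, m.affine, sim_dir / f"{name}_mask.nii.gz")
        for bold, motion in zip(bolds, motions):
            write_bold(bold, sim_dir / f"{bold.subject_id}_bold.nii.gz")
            write_motion(motion, sim_dir / f"rp_{motion.subject_id}.txt")
        write_cohort(cohort, sim_dir / "cohort.csv")
        for p in sorted(sim_dir.iterdir()):
            register(p)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # optional medication-naive-style subgroup filter
    if config.subset_column:
        cohort = subset_filter(cohort, config.subset_column, config.subset_value)
        keep_ids = set(cohort["id"])
        pairs = [(b, m) for b, m in zip(bolds, motions) if b.subject_id in keep_ids]
        bolds, motions = [list(t) for t in zip(*pairs)]
        logger.info("subset filter retained %d subjects", len(bolds))

    # ----- preprocess -------------------------------------------------------
    stage = "preprocess"
    try:
        pp = config.preprocess
        pre_dir = out_root / stage
        pre_dir.mkdir(parents=True, exist_ok=True)
        reports = [qc_screen(m, pp.qc.trans_limit_mm, pp.qc.rot_limit_deg,
                             pp.qc.mean_fd_limit, pp.qc.fd_sphere_radius_mm)
                   for m in motions]
        qc_df = pd.DataFrame([{
            "id": r.subject_id, "max_abs_translation_mm": r.max_abs_translation_mm,
            "max_abs_rotation_deg": r.max_abs_rotation_deg, "mean_fd": r.mean_fd,
            "passed": r.passed, "reasons": "; ".join(r.reasons),
        } for r in reports])
        qc_df.to_csv(pre_dir / "qc_report.csv", index=False)
        register(pre_dir / "qc_report.csv")
        passed = {r.subject_id for r in reports if r.passed}
        for r in reports:
            if not r.passed:
                logger.info("excluded %s: %s", r.subject_id, "; ".join(r.reasons))
        cohort["qc_pass"] = cohort["id"].isin(passed)
        kept = [(b, m) for b, m in zip(bolds, motions) if b.subject_id in passed]
        clean = [
            preprocess_bold(b, m, brain, csf=tissue["csf"], wm=tissue["wm"],
                            low_hz=pp.low_hz, high_hz=pp.high_hz,
                            global_signal=pp.global_signal)
            for b, m in kept
        ]
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # ----- reho -------------------------------------------------------------
    stage = "reho"
    try:
        rp = config.reho
        reho_dir = out_root / stage
        reho_dir.mkdir(parents=True, exist_ok=True)
        maps = []
        for bold in clean:
            rmap = subject_reho(bold, brain, neighborhood=rp.neighborhood,
                                fwhm_mm=rp.fwhm_mm, standardize=rp.standardize,
                                require_full_neighborhood=rp.require_full_neighborhood)
            maps.append(rmap)
            suffix = "szreho" if rp.standardize else "reho"
            path = reho_dir / f"{bold.subject_id}_{suffix}.nii.gz"
            write_map(rmap.data, rmap.affine, path)
            register(path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    kept_ids = [b.subject_id for b in clean]
    kept_table = cohort.set_index("id").loc[kept_ids].reset_index()
    is_patient = (kept_table["group"] == "patient").to_numpy()

    # ----- univariate -------------------------------------------------------
    stage = "univariate"
    try:
        if is_patient.all() or (~is_patient).all():
            raise ValueError("need both groups after QC/subsetting for the "
                             "group comparison")
        uv = config.univariate
        uni_dir = out_root / stage
        uni_dir.mkdir(parents=True, exist_ok=True)
        maps_A = [m for m, p in zip(maps, is_patient) if p]
        maps_B = [m for m, p in zip(maps, is_patient) if not p]
        clusters = cluster_fwe(maps_A, maps_B, brain, voxel_p=uv.voxel_p,
                               min_extent=uv.min_extent, connectivity=uv.connectivity,
                               n_perm=uv.n_perm,
                               seed=stage_seed(config.seed, stage))
        ctable = clusters_to_table(clusters)
        ctable.insert(0, "method", "permutation max-cluster-extent FWE")
        ctable.to_csv(uni_dir / "clusters.csv", index=False)
        register(uni_dir / "clusters.csv")

        demo = demographics(kept_table)
        pd.DataFrame([{
            "gender_chi2": demo.gender_chi2, "gender_p": demo.gender_p,
            "age_t": demo.age_t, "age_p": demo.age_p,
        }]).to_csv(uni_dir / "demographics.csv", index=False)
        register(uni_dir / "demographics.csv")

        sig = [c for c in clusters if c.fwe_p < uv.cluster_alpha]
        corr_frames = []
        pat_maps = [m for m, p in zip(maps, is_patient) if p]
        pat_table = kept_table[is_patient]
        for j, c in enumerate(sig):
            vals = np.array([roi_mean(m, c.voxel_members) for m in pat_maps])
            corr_frames.append(clinical_correlations(
                vals, kept_table, roi_name=f"cluster{j}_{c.sign}"))
        corr = (pd.concat(corr_frames, ignore_index=True) if corr_frames
                else pd.DataFrame(columns=["roi", "score", "r", "n", "p"]))
        corr.to_csv(uni_dir / "clinical_correlations.csv", index=False)
        register(uni_dir / "clinical_correlations.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # ----- mvpa -------------------------------------------------------------
    stage = "mvpa"
    try:
        mp = config.mvpa
        mvpa_dir = out_root / stage
        mvpa_dir.mkdir(parents=True, exist_ok=True)
        labels = np.where(is_patient, 1, -1)
        feats = build_features(maps, brain, labels, subject_ids=kept_ids)
        seed = stage_seed(config.seed, stage)
        report = svm_loocv(feats, C=mp.svm_c, seed=seed)
        report.permutation_p = permutation_test(
            feats, n_perm=mp.n_perm, seed=seed, C=mp.svm_c,
            observed_accuracy=report.accuracy)
        summary = {
            "accuracy_percent": report.accuracy,
            "sensitivity_percent": report.sensitivity,
            "specificity_percent": report.specificity,
            "auc": report.auc,
            "permutation_p": report.permutation_p,
            "n_permutations": mp.n_perm,
            "svm_c": mp.svm_c,
        }
        with open(mvpa_dir / "svm_report.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        register(mvpa_dir / "svm_report.json")
        pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
            mvpa_dir / "roc_points.csv", index=False)
        register(mvpa_dir / "roc_points.csv")
        pd.DataFrame({"id": kept_ids, "label": labels,
                      "decision_value": report.decision_values,
                      "predicted": report.fold_predictions}).to_csv(
            mvpa_dir / "decision_values.csv", index=False)
        register(mvpa_dir / "decision_values.csv")
        write_map(report.weight_map, brain.affine, mvpa_dir / "weight_map.nii.gz")
        register(mvpa_dir / "weight_map.nii.gz")
        w_flat = report.weight_map[brain.data]
        dmap = discriminative_map(w_flat, feats.voxel_index, feats.shape3d,
                                  fraction=mp.top_fraction, mode=mp.threshold_mode)
        write_map(dmap.weights, brain.affine, mvpa_dir / "discriminative_map.nii.gz")
        register(mvpa_dir / "discriminative_map.nii.gz")
        discriminative_peaks(dmap, brain.affine).to_csv(
            mvpa_dir / "discriminative_peaks.csv", index=False)
        register(mvpa_dir / "discriminative_peaks.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "parameters": {
            "synthetic": dataclasses.asdict(config.synthetic),
            "preprocess": dataclasses.asdict(config.preprocess),
            "reho": dataclasses.asdict(config.reho),
            "univariate": dataclasses.asdict(config.univariate),
            "mvpa": dataclasses.asdict(config.mvpa),
        },
        "stages": list(STAGES),
        "outputs": dict(sorted(outputs.items())),
    }
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
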