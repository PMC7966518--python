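"""End-to-end orchestration: simulate -> preprocess -> extract -> cluster -> slz -> correlate.

Every stage writes its artifact (CSV/JSON) under the run directory, and a
manifest records the configuration hash, the master seed, and a SHA-256
checksum for each artifact, so that a re-run with an identical configuration
can be verified byte-for-byte.  Stages communicate through plain in-memory
objects but their file artifacts are complete, so each stage can also be
re-run standalone from the written outputs.
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

from bhtyper import clinical as clin
from bhtyper import clustering, distance, features, phantom, preprocess

logger = logging.getLogger("bhtyper")

__all__ = ["RunConfig", "RunResult", "StageError", "run_all", "verify_manifest", "load_config"]

STAGES = ("simulate", "preprocess", "extract", "cluster", "slz", "correlate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    cohort: phantom.CohortSpec = field(default_factory=phantom.CohortSpec)
    preprocess: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)
    null: distance.NullConfig = field(default_factory=distance.NullConfig)
    max_iterations: int = 10
    out_dir: str | Path | None = None
    persist_volumes: bool = False
    log_level: str = "INFO"

    @property
    def master_seed(self) -> int:
        return self.cohort.master_seed


@dataclass
class RunResult:
    feature_table: pd.DataFrame
    cluster_summary: dict
    feature_F: dict
    exceedance: dict
    tests: list
    correlations: list
    burden: pd.DataFrame
    clinical_table: pd.DataFrame
    manifest: dict


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"cohort", "preprocess", "null", "max_iterations", "out_dir",
             "persist_volumes", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "cohort" in raw:
        cohort = dict(raw["cohort"])
        for key in ("grid_shape", "voxel_size", "lesion_size_range"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        kwargs["cohort"] = phantom.CohortSpec(**cohort)
    if "preprocess" in raw:
        pp = dict(raw["preprocess"])
        if "landmark_percentiles" in pp:
            pp["landmark_percentiles"] = tuple(pp["landmark_percentiles"])
        kwargs["preprocess"] = preprocess.PreprocessConfig(**pp)
    if "null" in raw:
        kwargs["null"] = distance.NullConfig(**raw["null"])
    for key in ("max_iterations", "out_dir", "persist_volumes", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _config_hash(config: RunConfig) -> str:
    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        raise TypeError(type(obj))

    payload = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _null_seed(config: RunConfig, subject_index: int, seq_index: int) -> np.random.SeedSequence:
    # counter scheme: spawn key (1000, subject, sequence) off the master seed
    return np.random.SeedSequence(
        config.master_seed, spawn_key=(1000, subject_index, seq_index)
    )


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage in order and return the assembled results.

    With ``config.out_dir`` set, each stage persists its artifact and the
    manifest is written last; a failure raises :class:`StageError` naming the
    stage, with the partial manifest retained and marked incomplete.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "stages": {},
    }

    def persist(stage: str, artifacts: dict[str, object]) -> None:
        entry: dict = {"outputs": {}}
        if out_dir is not None:
            for name, obj in artifacts.items():
                path = out_dir / name
                if isinstance(obj, pd.DataFrame):
                    obj.to_csv(path, index=False)
                else:
                    _write_json(obj, path)
                entry["outputs"][name] = _sha256_file(path)
        manifest["stages"][stage] = entry

    def fail(stage: str, exc: BaseException):
        manifest["incomplete_at"] = stage
        if out_dir is not None:
            _write_json(manifest, out_dir / "manifest.json")
        raise StageError(stage, exc) from exc

    # -- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        logger.info("simulate: %d subjects, seed %d", config.cohort.n_subjects,
                     config.master_seed)
        subjects, clinical_table = phantom.generate_cohort(config.cohort)
        if config.persist_volumes and out_dir is not None:
            phantom.write_fixtures(subjects, clinical_table, out_dir / "cohort")
        persist(stage, {"clinical.csv": clinical_table})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail(stage, exc)

    # -- preprocess -------------------------------------------------------
    stage = "preprocess"
    try:
        pp = config.preprocess
        landmarks: dict[str, np.ndarray] = {}
        if pp.standardization_enabled:
            for seq in phantom.SEQUENCES:
                landmarks[seq] = preprocess.learn_landmarks(
                    (s.volumes[seq] for s in subjects), pp.landmark_percentiles
                )
        report: dict = {}
        per_subject_tissue: dict[str, dict[str, preprocess.TissueMedians]] = {}
        per_subject_labels: dict[str, np.ndarray] = {}
        for subj in subjects:
            if pp.standardization_enabled:
                subj.volumes = {
                    seq: preprocess.standardize_intensities(
                        vol, landmarks[seq], pp.landmark_percentiles
                    )
                    for seq, vol in subj.volumes.items()
                }
            raw_n = int(np.max(subj.lesion_labels)) if subj.lesion_labels.size else 0
            filtered = preprocess.label_and_filter_lesions(
                subj.lesion_labels, pp.min_lesion_voxels
            )
            per_subject_labels[subj.subject_id] = filtered
            tissue = {
                seq: preprocess.tissue_medians(
                    subj.volumes[seq], subj.tissue_maps, subj.lesion_labels
                )
                for seq in phantom.SEQUENCES
            }
            per_subject_tissue[subj.subject_id] = tissue
            report[subj.subject_id] = {
                "lesions_before_filter": raw_n,
                "lesions_after_filter": int(filtered.max()) if filtered.size else 0,
                "tissue_medians": {
                    seq: {t: tissue[seq].median_for(t) for t in ("wm", "gm", "csf")}
                    for seq in phantom.SEQUENCES
                },
            }
        persist(stage, {"preprocess_report.json": report})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- extract ----------------------------------------------------------
    stage = "extract"
    try:
        vox_mm3 = float(np.prod(config.cohort.voxel_size))
        per_subject_feats: dict[str, pd.DataFrame] = {}
        for subj in subjects:
            labels = per_subject_labels[subj.subject_id]
            if labels.max() == 0:
                continue
            meds = features.lesion_medians(subj.volumes, labels)
            meds["volume_mm3"] = meds["voxel_count"] * vox_mm3
            per_subject_feats[subj.subject_id] = features.standardized_intensities(
                meds, per_subject_tissue[subj.subject_id]
            )
        table = features.build_feature_table(per_subject_feats)
        persist(stage, {"features.csv": table})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- cluster ----------------------------------------------------------
    stage = "cluster"
    try:
        model = clustering.fit_kmeans2(table, config.max_iterations)
        summary = clustering.canonicalize_and_summarize(model, table)
        table["cluster_label"] = model.labels
        feature_F = clustering.feature_influence_F(table, model.labels)
        summary["feature_F"] = feature_F
        summary["iterations_used"] = model.iterations_used
        persist(stage, {"cluster_summary.json": summary, "features_labeled.csv": table})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- slz --------------------------------------------------------------
    stage = "slz"
    try:
        for seq in phantom.SEQUENCES:
            table[f"z_{seq}"] = np.nan
        for s_idx, subj in enumerate(subjects):
            sel = table["subject_id"] == subj.subject_id
            if not sel.any():
                continue
            for q_idx, seq in enumerate(phantom.SEQUENCES):
                cfg = dataclasses.replace(
                    config.null,
                    rng_seed=_null_seed(config, s_idx, q_idx).generate_state(1)[0] % (2**31),
                )
                null = distance.build_null(
                    per_subject_tissue[subj.subject_id][seq].wm_voxel_intensities,
                    cfg,
                    subject_id=subj.subject_id,
                    sequence=seq,
                )
                zs = distance.z_scores(table.loc[sel, f"median_{seq}"].to_numpy(), null)
                table.loc[sel, f"z_{seq}"] = zs["z"].to_numpy()
        exceedance = distance.exceedance_percentages(
            table, table["cluster_label"].to_numpy(), config.null.z_threshold,
            sequences=("fspgr", "se"),
        )
        persist(stage, {"exceedance.json": exceedance, "features_z.csv": table})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- correlate --------------------------------------------------------
    stage = "correlate"
    try:
        tests: list[clin.TestResult] = []
        for seq in ("fspgr", "se"):
            for tissue in ("wm", "gm", "csf"):
                tests.append(
                    clin.wilcoxon_vs_unity(
                        table[f"ratio_{tissue}_{seq}"].to_numpy(),
                        name=f"wilcoxon_{seq}_{tissue}_vs_1",
                    )
                )
        tests.append(
            clin.mann_whitney_u(
                table["ratio_wm_se"].to_numpy(),
                table["ratio_wm_fspgr"].to_numpy(),
                name="mwu_ratio_wm_se_vs_fspgr",
            )
        )
        for t in tests:  # Bonferroni over the intensity-test family
            t.p_adjusted = min(1.0, len(tests) * t.p_raw)
        burden = clin.burden_summary(table, [s.subject_id for s in subjects])
        correlations = clin.spearman_with_correction(clinical_table, burden)
        persist(
            stage,
            {
                "burden.csv": burden,
                "tests.json": [dataclasses.asdict(t) for t in tests],
                "correlations.csv": pd.DataFrame(
                    [dataclasses.asdict(c) for c in correlations]
                ),
            },
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    if out_dir is not None:
        _write_json(manifest, out_dir / "manifest.json")
    return RunResult(
        feature_table=table,
        cluster_summary=summary,
        feature_F=feature_F,
        exceedance=exceedance,
        tests=tests,
        correlations=correlations,
        burden=burden,
        clinical_table=clinical_table,
        manifest=manifest,
    )


def verify_manifest(out_dir: str | Path) -> list[str]:
    """Re-hash every artifact listed in a run manifest; return mismatched files."""
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    mismatched = []
    for stage in manifest["stages"].values():
        for name, digest in stage.get("outputs", {}).items():
            path = out_dir / name
            if not path.exists() or _sha256_file(path) != digest:
                mismatched.append(name)
    return mismatched
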