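"""Synthetic multi-contrast cohort generator.

Builds phantom subjects that carry the statistical structure the downstream
analysis assumes: three co-registered intensity volumes (FSPGR, SE, FLAIR),
ground-truth tissue partial-volume maps (WM/GM/CSF), an integer lesion label
map, and a clinical covariate table.  Lesions belong to one of two intensity
classes.  On T1-weighted sequences (FSPGR, SE) lesion medians fall strictly
between the gray-matter and white-matter intensity locations (hypointense
relative to WM, hyperintense relative to GM/CSF); on FLAIR both classes sit
above WM and are nearly coincident, so FLAIR carries almost no class signal.

Clinical covariates are coupled to class-2 lesion burden through a Gaussian
copula so that a target population Spearman correlation can be injected
exactly (up to tie attenuation from discrete marginals).
"""

from __future__ import annotations

import gzip
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSpec",
    "LesionTruth",
    "SubjectPhantom",
    "SpecValidationError",
    "PlacementError",
    "generate_subject",
    "generate_truth",
    "generate_cohort",
    "generate_clinical_table",
    "write_fixtures",
]

SEQUENCES = ("fspgr", "se", "flair")
TISSUES = ("wm", "gm", "csf")

#: Tissue intensity locations per sequence (arbitrary scanner units).  Chosen
#: to satisfy the qualitative contrasts of the sequences: on T1-weighted
#: FSPGR/SE, CSF < GM < WM; on FLAIR, CSF is suppressed and GM > WM.
DEFAULT_TISSUE_PARAMS: dict[str, dict[str, float]] = {
    "fspgr": {"wm": 4800.0, "gm": 3000.0, "csf": 800.0},
    "se": {"wm": 2000.0, "gm": 1400.0, "csf": 600.0},
    "flair": {"wm": 2200.0, "gm": 2400.0, "csf": 300.0},
}

#: Per-class lesion-median location and spread per sequence.  Locations are
#: the two final cluster centers the typing analysis should recover; spreads
#: are set so the class ranges are essentially disjoint on FSPGR, overlap on
#: SE, and coincide on FLAIR.
DEFAULT_LESION_CLASS_PARAMS: dict[int, dict[str, tuple[float, float]]] = {
    1: {"fspgr": (3525.20, 140.0), "se": (1701.23, 140.0), "flair": (2575.23, 210.0)},
    2: {"fspgr": (4280.42, 120.0), "se": (1887.77, 80.0), "flair": (2555.67, 210.0)},
}

#: Target rank correlations between class-2 lesion burden and clinical
#: covariates: clinical variable -> (burden statistic, Spearman rho).
DEFAULT_EFFECT_SIZES: dict[str, tuple[str, float]] = {
    "edss": ("cl2_count", 0.30),
    "disease_duration": ("cl2_count", 0.33),
    "nbv": ("cl2_volume", -0.51),
}


class SpecValidationError(ValueError):
    """A CohortSpec field is invalid; the message names the field."""


class PlacementError(RuntimeError):
    """A lesion could not be placed inside white matter after bounded retries."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a 79-subject relapsing-remitting MS cohort with on
    average ~8.78 lesions per subject (≈694 lesions in expectation), a
    470/694 class-2 fraction, lesion voxel counts log-uniform on [60, 2000]
    (straddling the 100-voxel detectability filter), and clinical effects
    coupling class-2 burden to EDSS, disease duration and normalized brain
    volume.
    """

    n_subjects: int = 79
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_intensity_params: dict = field(
        default_factory=lambda: {s: dict(t) for s, t in DEFAULT_TISSUE_PARAMS.items()}
    )
    lesion_class_params: dict = field(
        default_factory=lambda: {c: dict(p) for c, p in DEFAULT_LESION_CLASS_PARAMS.items()}
    )
    mean_lesions_per_subject: float = 694.0 / 79.0
    lesion_size_range: tuple[int, int] = (60, 2000)
    class2_fraction: float = 470.0 / 694.0
    #: fractional voxel-noise level: per-tissue sd = noise_level * location
    noise_level: float = 0.03
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SpecValidationError("n_subjects must be >= 1")
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise SpecValidationError("grid_shape must be three axes of >= 8 voxels")
        if any(v <= 0 for v in self.voxel_size):
            raise SpecValidationError("voxel_size entries must be > 0")
        if not 0.0 <= self.class2_fraction <= 1.0:
            raise SpecValidationError("class2_fraction must lie in [0, 1]")
        if self.mean_lesions_per_subject < 0:
            raise SpecValidationError("mean_lesions_per_subject must be >= 0")
        lo, hi = self.lesion_size_range
        if not (0 < lo < hi):
            raise SpecValidationError("lesion_size_range must satisfy 0 < lo < hi")
        if self.noise_level <= 0:
            raise SpecValidationError("noise_level must be > 0")
        for seq in SEQUENCES:
            tis = self.tissue_intensity_params.get(seq)
            if tis is None or any(t not in tis for t in TISSUES):
                raise SpecValidationError(
                    f"tissue_intensity_params must define wm/gm/csf for {seq}"
                )
        for cls in (1, 2):
            params = self.lesion_class_params.get(cls)
            if params is None or any(s not in params for s in SEQUENCES):
                raise SpecValidationError(
                    f"lesion_class_params must define all sequences for class {cls}"
                )
            for seq in SEQUENCES:
                loc, sd = params[seq]
                if sd <= 0:
                    raise SpecValidationError(
                        f"lesion_class_params spread must be > 0 for class {cls}, {seq}"
                    )
                tis = self.tissue_intensity_params[seq]
                if seq in ("fspgr", "se"):
                    if not tis["gm"] < loc < tis["wm"]:
                        raise SpecValidationError(
                            f"lesion_class_params location for class {cls}, {seq} "
                            "must lie strictly between the GM and WM locations"
                        )
                elif loc <= tis["wm"]:
                    raise SpecValidationError(
                        f"lesion_class_params location for class {cls}, flair "
                        "must lie above the WM location"
                    )

    def subject_seed(self, index: int) -> np.random.SeedSequence:
        """Per-subject seed: SeedSequence(master_seed) with spawn key = index."""
        return np.random.SeedSequence(self.master_seed, spawn_key=(index,))


@dataclass
class LesionTruth:
    """Ground truth for one subject's lesions (before any voxel rendering)."""

    subject_id: str
    lesion_class: np.ndarray  # (n_lesions,) in {1, 2}
    target_voxels: np.ndarray  # (n_lesions,) intended voxel counts
    medians: dict[str, np.ndarray]  # sequence -> (n_lesions,) sampled medians

    @property
    def n_lesions(self) -> int:
        return int(self.lesion_class.size)


@dataclass
class SubjectPhantom:
    """One synthetic subject: aligned volumes, lesion labels, tissue maps."""

    subject_id: str
    volumes: dict[str, np.ndarray]  # sequence -> 3D float32 grid
    lesion_labels: np.ndarray  # 3D int32 grid, 0 = background
    tissue_maps: dict[str, np.ndarray]  # tissue -> 3D float32 partial volume
    voxel_size: tuple[float, float, float]
    truth: LesionTruth

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])


def _anatomy(grid_shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Concentric-ellipsoid head model: GM shell, WM core, CSF rim + ventricle."""
    axes = [np.arange(s, dtype=np.float64) - (s - 1) / 2.0 for s in grid_shape]
    semi = [0.45 * s for s in grid_shape]
    xn = [ax / sa for ax, sa in zip(axes, semi)]
    r = np.sqrt(
        xn[0][:, None, None] ** 2 + xn[1][None, :, None] ** 2 + xn[2][None, None, :] ** 2
    )
    brain = r <= 1.0
    ventricle = r <= 0.10
    csf = (brain & (r > 0.92)) | ventricle
    gm = brain & (r <= 0.92) & (r > 0.78)
    wm = brain & (r <= 0.78) & ~ventricle
    return {
        "wm": wm.astype(np.float32),
        "gm": gm.astype(np.float32),
        "csf": csf.astype(np.float32),
    }


def _sample_truth(spec: CohortSpec, rng: np.random.Generator, subject_id: str) -> LesionTruth:
    n_lesions = int(rng.poisson(spec.mean_lesions_per_subject))
    lo, hi = spec.lesion_size_range
    sizes = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_lesions))
    sizes = np.maximum(1, np.round(sizes)).astype(np.int64)
    classes = np.where(rng.random(n_lesions) < spec.class2_fraction, 2, 1).astype(np.int64)
    medians: dict[str, np.ndarray] = {}
    for seq in SEQUENCES:
        vals = np.empty(n_lesions)
        tis = spec.tissue_intensity_params[seq]
        for cls in (1, 2):
            sel = classes == cls
            if not sel.any():
                continue
            loc, sd = spec.lesion_class_params[cls][seq]
            if seq in ("fspgr", "se"):
                lob, hib = tis["gm"], tis["wm"]
            else:
                lob, hib = tis["wm"], np.inf
            a, b = (lob - loc) / sd, (hib - loc) / sd
            vals[sel] = stats.truncnorm.rvs(
                a, b, loc=loc, scale=sd, size=int(sel.sum()), random_state=rng
            )
        medians[seq] = vals
    return LesionTruth(subject_id, classes, sizes, medians)


def _ellipsoid_offsets(
    target_voxels: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer offsets of a random axis-aligned ellipsoid of ~target_voxels voxels."""
    shape_factors = rng.uniform(0.8, 1.2, size=3)
    shape_factors /= np.prod(shape_factors) ** (1.0 / 3.0)
    r0 = (3.0 * target_voxels / (4.0 * math.pi)) ** (1.0 / 3.0)
    radii = np.maximum(r0 * shape_factors, 0.5)
    bounds = np.floor(radii).astype(int)
    grids = np.meshgrid(*[np.arange(-b, b + 1) for b in bounds], indexing="ij")
    inside = sum((g / rad) ** 2 for g, rad in zip(grids, radii)) <= 1.0
    return np.stack([g[inside] for g in grids], axis=1)


def _place_lesions(
    spec: CohortSpec,
    truth: LesionTruth,
    wm_mask: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 500,
) -> np.ndarray:
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    wm_idx = np.argwhere(wm_mask)
    if truth.n_lesions and wm_idx.size == 0:
        raise PlacementError("no white-matter voxels available for lesion placement")
    shape = np.asarray(spec.grid_shape)
    actual_counts = np.zeros(truth.n_lesions, dtype=np.int64)
    # biggest first: large ellipsoids have the fewest viable centers
    order = np.argsort(-truth.target_voxels, kind="stable")
    for k in order:
        offsets = _ellipsoid_offsets(int(truth.target_voxels[k]), rng)
        placed = False
        for _ in range(max_attempts):
            center = wm_idx[rng.integers(len(wm_idx))]
            vox = center[None, :] + offsets
            if (vox < 0).any() or (vox >= shape[None, :]).any():
                continue
            ix, iy, iz = vox[:, 0], vox[:, 1], vox[:, 2]
            if not wm_mask[ix, iy, iz].all():
                continue
            if labels[ix, iy, iz].any():
                continue
            labels[ix, iy, iz] = k + 1
            actual_counts[k] = len(vox)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place lesion {k + 1} ({truth.target_voxels[k]} voxels) "
                f"after {max_attempts} attempts; grid too small"
            )
    truth.target_voxels = actual_counts  # replace intended with rendered counts
    return labels


def generate_truth(spec: CohortSpec, subject_index: int) -> LesionTruth:
    """Sample one subject's lesion ground truth without rendering any voxels.

    Uses the same random stream prefix as :func:`generate_subject`, so the
    truth is identical to the one a fully rendered subject would carry (up to
    ellipsoid-discretization of voxel counts).
    """
    rng = np.random.default_rng(spec.subject_seed(subject_index))
    return _sample_truth(spec, rng, f"sub-{subject_index + 1:03d}")


def generate_subject(spec: CohortSpec, subject_index: int) -> SubjectPhantom:
    """Render one subject: tissue maps, lesion labels, noisy intensity volumes."""
    rng = np.random.default_rng(spec.subject_seed(subject_index))
    subject_id = f"sub-{subject_index + 1:03d}"
    truth = _sample_truth(spec, rng, subject_id)
    tissue_maps = _anatomy(spec.grid_shape)
    wm_mask = tissue_maps["wm"] > 0.5
    labels = _place_lesions(spec, truth, wm_mask, rng)

    volumes: dict[str, np.ndarray] = {}
    for seq in SEQUENCES:
        vol = np.zeros(spec.grid_shape, dtype=np.float64)
        for tissue in TISSUES:
            loc = spec.tissue_intensity_params[seq][tissue]
            mask = tissue_maps[tissue] > 0.5
            n = int(mask.sum())
            vol[mask] = loc + rng.normal(0.0, spec.noise_level * loc, size=n)
        for k in range(truth.n_lesions):
            mask = labels == (k + 1)
            med = truth.medians[seq][k]
            vol[mask] = med + rng.normal(
                0.0, spec.noise_level * med, size=int(mask.sum())
            )
        vol = np.clip(vol, 1e-3, None)
        brain = (tissue_maps["wm"] + tissue_maps["gm"] + tissue_maps["csf"]) > 0.5
        vol[~brain] = 0.0  # background stays exactly zero
        volumes[seq] = vol.astype(np.float32)
    return SubjectPhantom(subject_id, volumes, labels, tissue_maps, spec.voxel_size, truth)


def _burden_table(truths: list[LesionTruth], spec: CohortSpec) -> pd.DataFrame:
    vox_mm3 = float(np.prod(spec.voxel_size))
    rows = []
    for t in truths:
        cl2 = t.lesion_class == 2
        rows.append(
            {
                "subject_id": t.subject_id,
                "cl1_count": int((~cl2).sum()),
                "cl2_count": int(cl2.sum()),
                "cl1_volume": float(t.target_voxels[~cl2].sum() * vox_mm3),
                "cl2_volume": float(t.target_voxels[cl2].sum() * vox_mm3),
            }
        )
    return pd.DataFrame(rows)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Van der Waerden scores with average ranks for ties."""
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (len(x) + 1.0))


def generate_clinical_table(
    truths: list[LesionTruth], spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical covariates coupled to class-2 lesion burden via Gaussian copula.

    For each clinical variable with target Spearman rho against a burden
    statistic, a latent normal is built as ``r * score(burden) + sqrt(1-r^2) *
    noise`` with ``r = 2 sin(pi * rho / 6)`` (the Pearson correlation of a
    bivariate Gaussian whose population Spearman equals rho), then pushed
    through the variable's marginal quantile function.  Relapse counts are
    drawn independently of burden.
    """
    if not truths:
        return pd.DataFrame(
            columns=[
                "subject_id",
                "edss",
                "disease_duration",
                "n_relapses",
                "n_relapses_since_treatment",
                "nbv",
            ]
        )
    burdens = _burden_table(truths, spec)
    n = len(burdens)
    scores = {
        stat: _normal_scores(burdens[stat].to_numpy())
        for stat in ("cl1_count", "cl2_count", "cl1_volume", "cl2_volume")
    }

    def latent_for(var: str) -> np.ndarray:
        noise = rng.standard_normal(n)
        if var in spec.effect_sizes:
            stat, rho = spec.effect_sizes[var]
            r = 2.0 * math.sin(math.pi * rho / 6.0)
            return r * scores[stat] + math.sqrt(1.0 - r * r) * noise
        return noise

    u = stats.norm.cdf
    # EDSS: ordinal 0..10 in 0.5 steps; marginal ~ truncated normal on [0, 6]
    # with median 2, matching a stable RRMS cohort.
    edss_latent = latent_for("edss")
    a, b = (0.0 - 2.0) / 1.7, (6.0 - 2.0) / 1.7
    edss = stats.truncnorm.ppf(u(edss_latent), a, b, loc=2.0, scale=1.7)
    edss = np.clip(np.round(edss * 2.0) / 2.0, 0.0, 10.0)

    # Disease duration: truncated normal, mean 12.34 y, sd 7.44 y, support >= 0.
    dur_latent = latent_for("disease_duration")
    a_d = (0.0 - 12.34) / 7.44
    duration = stats.truncnorm.ppf(u(dur_latent), a_d, np.inf, loc=12.34, scale=7.44)

    # Normalized brain volume (arbitrary units ~ cm^3): Normal(1500, 75).
    nbv_latent = latent_for("nbv")
    nbv = stats.norm.ppf(u(nbv_latent), loc=1500.0, scale=75.0)

    n_relapses = rng.poisson(2.0, size=n)
    n_relapses_tx = np.minimum(rng.poisson(0.6, size=n), n_relapses)

    return pd.DataFrame(
        {
            "subject_id": burdens["subject_id"],
            "edss": edss,
            "disease_duration": duration,
            "n_relapses": n_relapses,
            "n_relapses_since_treatment": n_relapses_tx,
            "nbv": nbv,
        }
    )


def generate_cohort(
    spec: CohortSpec, render_volumes: bool = True
) -> tuple[list, pd.DataFrame]:
    """Generate the full cohort: subjects (or truth only) plus clinical table.

    With ``render_volumes=False`` only the lesion ground truth is sampled —
    the clinical coupling depends on nothing else, which makes replicate
    studies of the correlation machinery cheap.
    Fully reproducible from ``spec.master_seed``.
    """
    if render_volumes:
        subjects = [generate_subject(spec, i) for i in range(spec.n_subjects)]
        truths = [s.truth for s in subjects]
    else:
        subjects = [generate_truth(spec, i) for i in range(spec.n_subjects)]
        truths = subjects
    clin_rng = np.random.default_rng(
        np.random.SeedSequence(spec.master_seed, spawn_key=(spec.n_subjects,))
    )
    clinical = generate_clinical_table(truths, spec, clin_rng)
    return subjects, clinical


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_nifti(arr: np.ndarray, affine: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(arr), affine)
    # deterministic gzip (no mtime) so identical cohorts give identical bytes
    with gzip.GzipFile(str(path), "wb", mtime=0) as fh:
        fh.write(img.to_bytes())


def write_fixtures(
    subjects: list[SubjectPhantom], clinical: pd.DataFrame, directory: str | Path
) -> dict:
    """Write a cohort to disk as NIfTI + CSV and return a checksum manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": {}, "files": {}}
    for subj in subjects:
        sdir = directory / subj.subject_id
        sdir.mkdir(exist_ok=True)
        files = {}
        for seq, vol in subj.volumes.items():
            p = sdir / f"{seq}.nii.gz"
            _write_nifti(vol, subj.affine, p)
            files[seq] = str(p.relative_to(directory))
        p = sdir / "lesion_labels.nii.gz"
        _write_nifti(subj.lesion_labels, subj.affine, p)
        files["lesion_labels"] = str(p.relative_to(directory))
        for tissue, pv in subj.tissue_maps.items():
            p = sdir / f"pv_{tissue}.nii.gz"
            _write_nifti(pv, subj.affine, p)
            files[f"pv_{tissue}"] = str(p.relative_to(directory))
        manifest["subjects"][subj.subject_id] = files
    clin_path = directory / "clinical.csv"
    clinical.to_csv(clin_path, index=False)
    manifest["files"]["clinical"] = clin_path.name
    for files in manifest["subjects"].values():
        for rel in files.values():
            manifest["files"][rel] = _sha256(directory / rel)
    manifest["files"][clin_path.name] = _sha256(clin_path)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_subject(directory: str | Path, subject_id: str) -> SubjectPhantom:
    """Read a written subject back into memory (truth is not round-tripped)."""
    sdir = Path(directory) / subject_id
    volumes = {
        seq: np.asarray(nib.load(sdir / f"{seq}.nii.gz").dataobj) for seq in SEQUENCES
    }
    labels_img = nib.load(sdir / "lesion_labels.nii.gz")
    labels = np.asarray(labels_img.dataobj).astype(np.int32)
    tissue_maps = {
        t: np.asarray(nib.load(sdir / f"pv_{t}.nii.gz").dataobj) for t in TISSUES
    }
    voxel_size = tuple(float(z) for z in labels_img.header.get_zooms()[:3])
    truth = LesionTruth(
        subject_id,
        np.zeros(0, dtype=np.int64),
        np.zeros(0, dtype=np.int64),
        {s: np.zeros(0) for s in SEQUENCES},
    )
    return SubjectPhantom(subject_id, volumes, labels, tissue_maps, voxel_size, truth)
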