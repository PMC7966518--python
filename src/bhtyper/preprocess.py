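"""Image preprocessing: intensity standardization, mask conditioning, tissue medians.

Three steps of the image-analysis chain are kept here: (i) cohort-landmark
piecewise-linear intensity standardization (decile landmarks averaged over the
cohort define a standard scale per sequence; each volume's own landmarks are
mapped onto it), (ii) lesion-mask conditioning — trilinear resampling followed
by thresholding at 0.5 ("binarize to avoid enlargement due to interpolation")
and a strict 100-voxel minimum-size filter, and (iii) per-sequence tissue
medians with lesion voxels excluded from white matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "TissueMedians",
    "DegenerateLandmarkError",
    "EmptyTissueError",
    "GeometryError",
    "learn_landmarks",
    "standardize_intensities",
    "resample_and_binarize_mask",
    "label_and_filter_lesions",
    "tissue_medians",
]

DEFAULT_PERCENTILES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)


class DegenerateLandmarkError(ValueError):
    """A volume has (near-)constant foreground intensity; landmarks collapse."""


class EmptyTissueError(ValueError):
    """A tissue class has no member voxels; the message names the class."""


class GeometryError(ValueError):
    """Source and target grids are geometrically incompatible."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing stage.

    mask_threshold: fraction at/above which a resampled mask voxel is kept.
    min_lesion_voxels: components must be strictly larger than this to survive.
    landmark_percentiles: percentile grid of the standardization landmarks.
    standardization_enabled: passthrough mode when False.
    """

    mask_threshold: float = 0.5
    min_lesion_voxels: int = 100
    landmark_percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    standardization_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_threshold < 1.0:
            raise ValueError("mask_threshold must lie in (0, 1)")
        if self.min_lesion_voxels < 0:
            raise ValueError("min_lesion_voxels must be >= 0")
        pcts = np.asarray(self.landmark_percentiles, dtype=float)
        if pcts.size < 2 or (np.diff(pcts) <= 0).any() or pcts[0] <= 0 or pcts[-1] >= 100:
            raise ValueError(
                "landmark_percentiles must be strictly increasing within (0, 100)"
            )


@dataclass
class TissueMedians:
    """Per-sequence tissue medians plus the retained WM intensity multiset."""

    wm_median: float
    gm_median: float
    csf_median: float
    wm_voxel_intensities: np.ndarray = field(repr=False)

    def median_for(self, tissue: str) -> float:
        return {"wm": self.wm_median, "gm": self.gm_median, "csf": self.csf_median}[tissue]


def _foreground(volume: np.ndarray) -> np.ndarray:
    vals = np.asarray(volume, dtype=np.float64).ravel()
    vals = vals[vals > 0]
    if vals.size == 0:
        raise DegenerateLandmarkError("volume has no positive foreground voxels")
    return vals


def _volume_landmarks(volume: np.ndarray, percentiles) -> np.ndarray:
    vals = _foreground(volume)
    if np.ptp(vals) <= 0:
        raise DegenerateLandmarkError("constant-intensity volume: landmarks collapse")
    return np.percentile(vals, percentiles)


def learn_landmarks(volumes, percentiles=DEFAULT_PERCENTILES) -> np.ndarray:
    """Standard-scale landmarks for one sequence: cohort mean of per-volume percentiles.

    Foreground is defined as strictly positive voxels (the background of a
    brain-extracted volume is zero and would otherwise dominate low
    percentiles).
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume to learn landmarks")
    pcts = np.atleast_1d(np.asarray(percentiles, dtype=float))
    if pcts.size < 1 or (np.diff(pcts) <= 0).any() or pcts[0] <= 0 or pcts[-1] >= 100:
        raise ValueError("percentiles must be strictly increasing within (0, 100)")
    per_volume = np.stack([_volume_landmarks(v, pcts) for v in volumes])
    return per_volume.mean(axis=0)


def _piecewise_linear(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation beyond the landmark range."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + slope * (x[lo] - xp[0])
    hi = x > xp[-1]
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + slope * (x[hi] - xp[-1])
    return y


def standardize_intensities(
    volume: np.ndarray,
    standard_landmarks: np.ndarray,
    percentiles=DEFAULT_PERCENTILES,
) -> np.ndarray:
    """Map a volume onto the standard scale by piecewise-linear landmark matching.

    The volume's own foreground percentiles are matched to the standard
    landmarks; in between, intensities are interpolated linearly, and beyond
    the outermost landmarks the edge segments are extended (linear
    extrapolation).  The mapping is monotone, so within-volume voxel rank
    order is preserved.  Background (non-positive) voxels stay untouched.
    """
    standard_landmarks = np.asarray(standard_landmarks, dtype=float)
    if (np.diff(standard_landmarks) <= 0).any():
        raise ValueError("standard landmarks must be strictly increasing")
    own = _volume_landmarks(volume, percentiles)
    if (np.diff(own) <= 0).any():
        # percentile ties (heavily quantized data): jitter-free repair by
        # collapsing duplicated landmarks is ambiguous -> refuse.
        raise DegenerateLandmarkError("volume landmarks are not strictly increasing")
    out = np.array(volume, dtype=np.float64, copy=True)
    fg = out > 0
    out[fg] = _piecewise_linear(out[fg], own, standard_landmarks)
    return out


def resample_and_binarize_mask(
    mask: np.ndarray,
    source_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    threshold: float = 0.5,
) -> np.ndarray:
    """Trilinear resampling onto the target grid, then threshold-and-binarize.

    Voxels whose interpolated value is >= threshold become 1, the rest 0 —
    thresholding at 0.5 avoids the apparent lesion enlargement a plain
    interpolated mask would show.
    """
    mask = np.asarray(mask, dtype=np.float64)
    if mask.min() < 0 or mask.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    source_affine = np.asarray(source_affine, dtype=float)
    target_affine = np.asarray(target_affine, dtype=float)
    if source_affine.shape != (4, 4) or target_affine.shape != (4, 4):
        raise GeometryError("affines must be 4x4")
    try:
        src_from_tgt = np.linalg.inv(source_affine) @ target_affine
    except np.linalg.LinAlgError as exc:  # pragma: no cover - singular affine
        raise GeometryError("source affine is singular") from exc
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in target_shape], indexing="ij")
    tgt_vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src_vox = (src_from_tgt @ tgt_vox)[:3]
    vals = ndimage.map_coordinates(mask, src_vox, order=1, mode="grid-constant", cval=0.0)
    return (vals >= threshold).astype(np.uint8).reshape(target_shape)


_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def label_and_filter_lesions(grid: np.ndarray, min_lesion_voxels: int = 100) -> np.ndarray:
    """Connected-component labelling (26-connectivity) plus strict size filter.

    Binary inputs are labelled first; integer-labelled inputs keep their
    component structure.  Components with voxel count strictly greater than
    ``min_lesion_voxels`` survive and are relabelled compactly (1..k) in the
    order of their original labels.
    """
    grid = np.asarray(grid)
    if grid.min() < 0:
        raise ValueError("lesion grid must be non-negative")
    if not np.issubdtype(grid.dtype, np.integer):
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("non-integer lesion grids must be binary")
        grid = grid.astype(np.int32)
    if grid.max() <= 1:
        labeled, _ = ndimage.label(grid, structure=_STRUCTURE_26)
    else:
        labeled = grid.astype(np.int32)
    out = np.zeros_like(labeled, dtype=np.int32)
    counts = np.bincount(labeled.ravel())
    next_label = 1
    for lab in range(1, counts.size):
        if counts[lab] > min_lesion_voxels:
            out[labeled == lab] = next_label
            next_label += 1
    return out


def tissue_medians(
    volume: np.ndarray,
    tissue_maps: dict[str, np.ndarray],
    lesion_mask: np.ndarray | None = None,
) -> TissueMedians:
    """Median WM/GM/CSF intensity on one sequence, lesions excluded from WM.

    Tissue membership is the majority-tissue rule (partial volume > 0.5).
    White-matter membership additionally excludes every lesion voxel, and the
    surviving WM intensity multiset is retained for the bootstrap null.
    """
    volume = np.asarray(volume)
    members: dict[str, np.ndarray] = {}
    for tissue in ("wm", "gm", "csf"):
        mask = np.asarray(tissue_maps[tissue]) > 0.5
        if tissue == "wm" and lesion_mask is not None:
            mask = mask & ~(np.asarray(lesion_mask) > 0)
        if not mask.any():
            raise EmptyTissueError(f"tissue class '{tissue}' has no member voxels")
        members[tissue] = volume[mask].astype(np.float64)
    return TissueMedians(
        wm_median=float(np.median(members["wm"])),
        gm_median=float(np.median(members["gm"])),
        csf_median=float(np.median(members["csf"])),
        wm_voxel_intensities=members["wm"],
    )
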