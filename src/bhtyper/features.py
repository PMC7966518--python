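"""Per-lesion feature assembly: median intensities and tissue-standardized ratios.

One row per surviving lesion.  ``median_<seq>`` is the median voxel intensity
under the lesion mask on that sequence; ``ratio_<tissue>_<seq>`` is the lesion
median divided by the subject's tissue median on the same sequence (a value of
1 means the lesion is indistinguishable from that tissue).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bhtyper.preprocess import TissueMedians

__all__ = [
    "lesion_medians",
    "standardized_intensities",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

SEQUENCES = ("fspgr", "se", "flair")
TISSUES = ("wm", "gm", "csf")

FEATURE_COLUMNS = (
    ["subject_id", "lesion_id", "voxel_count", "volume_mm3"]
    + [f"median_{s}" for s in SEQUENCES]
    + [f"ratio_{t}_{s}" for t in TISSUES for s in SEQUENCES]
)


def lesion_medians(
    volumes: dict[str, np.ndarray], lesion_labels: np.ndarray
) -> pd.DataFrame:
    """Median intensity of each labelled lesion on each sequence.

    Returns one row per lesion id (ascending) with columns ``lesion_id``,
    ``voxel_count`` and ``median_<seq>``.
    """
    labels = np.asarray(lesion_labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    for lid in ids:
        mask = labels == lid
        n = int(mask.sum())
        if n == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"lesion {lid} has zero voxels")
        row = {"lesion_id": int(lid), "voxel_count": n}
        for seq, vol in volumes.items():
            vals = np.asarray(vol)[mask].astype(np.float64)
            row[f"median_{seq}"] = float(np.median(vals))
        rows.append(row)
    cols = ["lesion_id", "voxel_count"] + [f"median_{s}" for s in volumes]
    return pd.DataFrame(rows, columns=cols)


def standardized_intensities(
    medians: pd.DataFrame, tissue: dict[str, TissueMedians]
) -> pd.DataFrame:
    """Append ``ratio_<tissue>_<seq>`` columns: lesion median / tissue median."""
    out = medians.copy()
    for seq, tm in tissue.items():
        for t in TISSUES:
            ref = tm.median_for(t)
            if ref <= 0:
                raise ValueError(f"non-positive {t} median on {seq}")
            out[f"ratio_{t}_{seq}"] = out[f"median_{seq}"] / ref
    return out


def build_feature_table(per_subject: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject lesion records into one cohort feature table.

    Rows are ordered by (subject_id, lesion_id); duplicate keys are an error.
    An empty cohort yields an empty table with the full header.
    """
    frames = []
    for subject_id in sorted(per_subject):
        df = per_subject[subject_id]
        if len(df) == 0:
            continue
        df = df.copy()
        df.insert(0, "subject_id", subject_id)
        frames.append(df.sort_values("lesion_id"))
    if not frames:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    dup = table.duplicated(subset=["subject_id", "lesion_id"])
    if dup.any():
        keys = table.loc[dup, ["subject_id", "lesion_id"]].to_records(index=False)
        raise ValueError(f"duplicate (subject, lesion) keys: {list(keys)[:5]}")
    ordered = [c for c in FEATURE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    return table[ordered + extra]
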