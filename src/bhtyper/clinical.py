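"""Cohort statistics: Wilcoxon vs unity, Mann-Whitney U, Spearman with Bonferroni.

All tests work on the lesion feature table and the clinical covariate table.
Standardized (tissue-relative) intensities are tested against 1 with a
one-sample Wilcoxon signed-rank test (a ratio of 1 means the lesion does not
stand out from the reference tissue); FSPGR and SE WM-ratios are compared
with a Mann-Whitney U test; and cluster-wise lesion burden is related to
clinical covariates with Spearman rank correlations, Bonferroni-corrected
over the whole grid of correlations produced in one run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "CorrelationResult",
    "wilcoxon_vs_unity",
    "mann_whitney_u",
    "spearman_with_correction",
    "burden_summary",
    "BURDEN_MEASURES",
    "CLINICAL_VARS",
]

BURDEN_MEASURES = (
    "cl1_count",
    "cl1_volume",
    "cl2_count",
    "cl2_volume",
    "total_count",
    "total_volume",
)
CLINICAL_VARS = (
    "edss",
    "disease_duration",
    "n_relapses",
    "n_relapses_since_treatment",
    "nbv",
)


@dataclass
class TestResult:
    name: str
    statistic: float  # Z for Wilcoxon, U for Mann-Whitney
    p_raw: float
    n: int
    p_adjusted: float | None = None
    note: str = ""


@dataclass
class CorrelationResult:
    burden: str
    clinical: str
    rho: float
    p_raw: float
    p_adjusted: float
    n: int
    valid: bool = True


def wilcoxon_vs_unity(ratios: np.ndarray, name: str = "wilcoxon_vs_1") -> TestResult:
    """One-sample Wilcoxon signed-rank test of standardized intensities against 1.

    Differences of exactly zero are dropped.  The reported statistic is the
    normal-approximation Z with the sign of the rank sum: ratios
    predominantly below unity give Z < 0.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    diffs = ratios - 1.0
    diffs = diffs[diffs != 0.0]
    if diffs.size < 5:
        raise ValueError("need >= 5 non-unity ratios for the signed-rank test")
    res = stats.wilcoxon(diffs, correction=True, method="approx")
    # two-sided zstatistic is built from min(T+, T-), so it carries no
    # direction; restore the sign from the positive rank sum.
    n = diffs.size
    t_plus = stats.rankdata(np.abs(diffs))[diffs > 0].sum()
    sign = 1.0 if t_plus >= n * (n + 1) / 4 else -1.0
    return TestResult(
        name=name,
        statistic=float(sign * abs(res.zstatistic)),
        p_raw=float(res.pvalue),
        n=int(n),
    )


def mann_whitney_u(
    group_a: np.ndarray, group_b: np.ndarray, name: str = "mann_whitney_u"
) -> TestResult:
    """Mann-Whitney U with tie-corrected normal approximation, two-sided.

    The reported U is the statistic of the first group (number of (a, b)
    pairs with a > b, counting ties as 1/2).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(
        name=name,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        n=int(a.size + b.size),
        note="U convention: statistic of the first group",
    )


def spearman_with_correction(
    clinical: pd.DataFrame,
    burden: pd.DataFrame,
    burden_measures=BURDEN_MEASURES,
    clinical_vars=CLINICAL_VARS,
) -> list[CorrelationResult]:
    """Spearman rho for every burden x clinical pair, Bonferroni-adjusted.

    Tables are joined on ``subject_id``.  Rho uses average ranks for ties and
    a two-sided t-approximation p-value.  The family for the Bonferroni
    correction is the set of valid cells computed in this run (constant
    variables are flagged invalid and excluded from the family size);
    p_adjusted = min(1, m * p_raw).
    """
    merged = pd.merge(clinical, burden, on="subject_id", validate="one_to_one")
    if len(merged) < 3:
        raise ValueError("need >= 3 subjects for rank correlation")
    results: list[CorrelationResult] = []
    for bm in burden_measures:
        for cv in clinical_vars:
            x = merged[bm].to_numpy(dtype=float)
            y = merged[cv].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                results.append(
                    CorrelationResult(bm, cv, float("nan"), float("nan"), float("nan"),
                                      len(merged), valid=False)
                )
                continue
            rho, p = stats.spearmanr(x, y)
            results.append(
                CorrelationResult(bm, cv, float(rho), float(p), float("nan"), len(merged))
            )
    m = sum(r.valid for r in results)
    for r in results:
        if r.valid:
            r.p_adjusted = min(1.0, m * r.p_raw)
    return results


def correlation_grid(results: list[CorrelationResult]) -> pd.DataFrame:
    """Long results reshaped into the burden x clinical grid (rho / p_adj cells)."""
    rows = []
    for r in results:
        rows.append(
            {
                "burden": r.burden,
                "clinical": r.clinical,
                "rho": r.rho,
                "p_adjusted": r.p_adjusted,
            }
        )
    long = pd.DataFrame(rows)
    return long.pivot(index="burden", columns="clinical", values=["rho", "p_adjusted"])


def burden_summary(
    labeled_features: pd.DataFrame, subject_ids=None
) -> pd.DataFrame:
    """Per-subject lesion count and volume per cluster, plus totals.

    ``labeled_features`` needs ``subject_id``, ``volume_mm3`` and
    ``cluster_label`` columns.  Subjects listed in ``subject_ids`` but absent
    from the table (no surviving lesions) receive all-zero rows.
    """
    if subject_ids is None:
        subject_ids = sorted(labeled_features["subject_id"].unique())
    rows = []
    for sid in subject_ids:
        sub = labeled_features[labeled_features["subject_id"] == sid]
        row = {"subject_id": sid}
        for cluster in (1, 2):
            members = sub[sub["cluster_label"] == cluster]
            row[f"cl{cluster}_count"] = int(len(members))
            row[f"cl{cluster}_volume"] = float(members["volume_mm3"].sum())
        row["total_count"] = int(len(sub))
        row["total_volume"] = float(sub["volume_mm3"].sum())
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["subject_id", "cl1_count", "cl1_volume", "cl2_count", "cl2_volume",
                 "total_count", "total_volume"],
    )
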