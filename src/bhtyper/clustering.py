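"""Two-cluster K-means lesion typing on raw (FSPGR, SE, FLAIR) median intensities.

The fit mirrors an "iterate and classify" K-means with K = 2 and at most 10
Lloyd iterations: deterministic farthest-pair initialization, batch Lloyd
updates on unscaled Euclidean distance, then a final classification pass
against the last centers.  Features are deliberately not rescaled — on raw
intensities the FSPGR median dominates cluster formation, which is exactly
the behaviour the per-feature one-way ANOVA F statistics quantify.

Cluster labels are canonicalized so that cluster 1 is the one with the lower
FSPGR center (the darker, classic black-hole type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterModel",
    "fit_kmeans2",
    "feature_influence_F",
    "canonicalize_and_summarize",
]

FEATURES = ("median_fspgr", "median_se", "median_flair")


@dataclass
class ClusterModel:
    centers: np.ndarray  # (2, n_features), row 0 = cluster 1
    labels: np.ndarray  # (n,) in {1, 2}
    n_per_cluster: tuple[int, int]
    feature_names: tuple[str, ...]
    iterations_used: int
    wcss_path: tuple[float, ...]  # within-cluster sum of squares per iteration

    @property
    def wcss(self) -> float:
        return self.wcss_path[-1]


def _as_matrix(table) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(table, pd.DataFrame):
        names = tuple(c for c in FEATURES if c in table.columns)
        if not names:
            names = tuple(table.columns)
        return table[list(names)].to_numpy(dtype=float), names
    X = np.asarray(table, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, tuple(f"f{i}" for i in range(X.shape[1]))


def _farthest_pair(X: np.ndarray) -> tuple[int, int]:
    """Indices of the two points at maximal Euclidean distance.

    Ties are broken by the lexicographically smallest (i, j) index pair.
    """
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    iu = np.triu_indices(len(X), k=1)
    flat = d2[iu]
    best = int(np.argmax(flat))  # argmax returns the first (lowest-index) max
    return int(iu[0][best]), int(iu[1][best])


def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # ties -> lower center index


#: below this table size every observation pair is tried as initial centers
MULTISTART_MAX_N = 64


def _lloyd(
    X: np.ndarray, init: tuple[int, int], max_iterations: int, center_tol: float
) -> tuple[np.ndarray, np.ndarray, list[float], int]:
    centers = X[list(init)].astype(float).copy()
    labels = _assign(X, centers)
    wcss_path = [float(((X - centers[labels]) ** 2).sum())]
    iterations = 0
    for _ in range(max_iterations):
        new_centers = centers.copy()
        for k in (0, 1):
            members = X[labels == k]
            if len(members):  # empty cluster keeps its previous center
                new_centers[k] = members.mean(axis=0)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        new_labels = _assign(X, centers)
        iterations += 1
        wcss_path.append(float(((X - centers[new_labels]) ** 2).sum()))
        converged = (new_labels == labels).all() or shift < center_tol
        labels = new_labels
        if converged:
            break
    labels = _assign(X, centers)  # final classify pass
    return centers, labels, wcss_path, iterations


def fit_kmeans2(table, max_iterations: int = 10, center_tol: float = 1e-9) -> ClusterModel:
    """K = 2 Lloyd iterations with deterministic initialization.

    Small tables (n <= 64) run one Lloyd pass from every observation pair as
    initial centers and keep the solution with the lowest final
    within-cluster sum of squares (ties: first pair in row order) — on such
    sizes this reliably attains the global 2-means optimum.  Larger tables
    use the pair of observations at maximal Euclidean distance, which for
    well-separated cluster structure converges to the same solution.  Each
    pass stops when no label changes (or the center shift falls below
    ``center_tol``) or after ``max_iterations`` Lloyd updates, then assigns
    every point to its nearest final center (the final classification pass).
    The recorded within-cluster sum of squares is non-increasing over
    iterations.
    """
    X, names = _as_matrix(table)
    if len(X) < 2 or len(np.unique(X, axis=0)) < 2:
        raise ValueError("need at least 2 distinct feature vectors to fit 2 clusters")
    if len(X) <= MULTISTART_MAX_N:
        inits = [
            (i, j)
            for i in range(len(X))
            for j in range(i + 1, len(X))
            if (X[i] != X[j]).any()
        ]
    else:
        inits = [_farthest_pair(X)]
    best = None
    for init in inits:
        fit = _lloyd(X, init, max_iterations, center_tol)
        if best is None or fit[2][-1] < best[2][-1] - 1e-12:
            best = fit
    centers, labels, wcss_path, iterations = best
    n1, n2 = int((labels == 0).sum()), int((labels == 1).sum())
    return ClusterModel(
        centers=centers,
        labels=labels + 1,
        n_per_cluster=(n1, n2),
        feature_names=names,
        iterations_used=iterations,
        wcss_path=tuple(wcss_path),
    )


def feature_influence_F(table, labels: np.ndarray) -> dict[str, float]:
    """One-way ANOVA F per feature across the two final clusters.

    F = between-cluster mean square / within-cluster mean square with
    df = (1, n - 2); large F means the feature drove cluster formation.
    """
    X, names = _as_matrix(table)
    labels = np.asarray(labels)
    groups = [X[labels == lab] for lab in (1, 2)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each cluster needs >= 2 members for a within-cluster variance")
    out: dict[str, float] = {}
    for idx, name in enumerate(names):
        a, b = groups[0][:, idx], groups[1][:, idx]
        if np.ptp(np.concatenate([a, b])) == 0:
            out[name] = 0.0
            continue
        out[name] = float(stats.f_oneway(a, b).statistic)
    return out


def canonicalize_and_summarize(model: ClusterModel, table) -> dict:
    """Relabel so cluster 1 has the lower FSPGR center; emit the cluster summary.

    The summary carries, per cluster: number of cases, final center per
    sequence, and median (range) of the member lesions' medians per sequence.
    The input ``model`` is modified in place when a swap is needed.
    """
    X, names = _as_matrix(table)
    fspgr_idx = names.index("median_fspgr") if "median_fspgr" in names else 0
    if model.centers[0, fspgr_idx] > model.centers[1, fspgr_idx]:
        model.centers = model.centers[::-1].copy()
        model.labels = np.where(model.labels == 1, 2, 1)
        model.n_per_cluster = model.n_per_cluster[::-1]
    summary: dict = {"n_per_cluster": {1: model.n_per_cluster[0], 2: model.n_per_cluster[1]}}
    for k, cluster in enumerate((1, 2)):
        members = X[model.labels == cluster]
        entry: dict = {"n": int(len(members))}
        for idx, name in enumerate(names):
            vals = members[:, idx]
            entry[name] = {
                "center": float(model.centers[k, idx]),
                "median": float(np.median(vals)) if len(vals) else float("nan"),
                "range": (
                    (float(vals.min()), float(vals.max())) if len(vals) else (float("nan"),) * 2
                ),
            }
        summary[f"cluster_{cluster}"] = entry
    return summary
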