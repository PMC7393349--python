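"""Per-TF regulatory shift between case and control networks, module-level
median summaries, and TF community discovery.

The regulatory shift of a TF on a target is the difference of its
fitted edge weight (z-score scale) between the asthma and control
networks; its shift on a module is the median over its targets in that
module, where "target" means a gene with a nonzero motif-prior hit
count for the TF. TFs lacking a target in any module are excluded.
Eligible TFs are then clustered by k-means on their module shift
vectors, k chosen over 2..10 by maximum mean silhouette.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, ward
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.cluster import KMeans

from .expression import bh_adjust
from .wgcna import ModuleAssignment


def edge_shift(net_case: pd.DataFrame, net_control: pd.DataFrame) -> pd.DataFrame:
    """Elementwise case-minus-control edge-weight differences."""
    if (set(net_case.index) != set(net_control.index)
            or set(net_case.columns) != set(net_control.columns)):
        d_tf = set(net_case.index) ^ set(net_control.index)
        d_g = set(net_case.columns) ^ set(net_control.columns)
        raise ValueError(
            f"networks cover different universes; TF diff {sorted(d_tf)[:5]}, "
            f"gene diff {sorted(d_g)[:5]}")
    return net_case - net_control.loc[net_case.index, net_case.columns]


def module_median_shift(shifts: pd.DataFrame, assignment: ModuleAssignment,
                        targets: pd.DataFrame) -> pd.DataFrame:
    """TF x module matrix of median shifts over each TF's module targets.

    ``targets`` is a boolean TF x gene mask (nonzero motif-prior hits).
    Only TFs with at least one target in every module are retained.
    """
    mods = assignment.modules
    if not mods:
        raise ValueError("assignment contains no named modules")
    genes = [g for g in shifts.columns if g in assignment.labels.index]
    targets = targets.loc[shifts.index, shifts.columns].astype(bool)
    rows = {}
    for tf in shifts.index:
        entry = {}
        for m in mods:
            mgenes = [g for g in assignment.genes_in(m) if g in shifts.columns]
            if not mgenes:
                raise ValueError(f"module {m} has no genes in the shift universe")
            tg = [g for g in mgenes if targets.loc[tf, g]]
            if not tg:
                entry = None
                break
            entry[m] = float(np.median(shifts.loc[tf, tg]))
        if entry is not None:
            rows[tf] = entry
    out = pd.DataFrame.from_dict(rows, orient="index", columns=mods)
    out.index.name = "tf"
    return out


def silhouette(distance: np.ndarray, labels: np.ndarray
               ) -> tuple[np.ndarray, float]:
    """Silhouette scores from a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a the mean intra-cluster
    distance (excluding self) and b the smallest mean distance to
    another cluster; singleton-cluster points score 0.
    """
    d = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance must be a square matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n, k = len(labels), len(uniq)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    counts = onehot.sum(axis=0)
    sums = d @ onehot  # mean-able per-cluster distance sums per point
    s = np.zeros(n)
    for i in range(n):
        own = codes[i]
        if counts[own] > 1:
            a = sums[i, own] / (counts[own] - 1)
            b = np.min([sums[i, c] / counts[c] for c in range(k) if c != own])
            denom = max(a, b)
            s[i] = 0.0 if denom == 0 else (b - a) / denom
        else:
            s[i] = 0.0
    return s, float(s.mean())


@dataclass
class TFClusterAssignment:
    """TF community labels with the silhouette-selected cluster count."""

    labels: pd.Series
    k: int
    silhouette_by_k: dict[int, float]
    method: str = "kmeans"


def cluster_tfs(shift_matrix: pd.DataFrame, k_min: int = 2, k_max: int = 10,
                n_init: int = 10, seed: int = 0,
                method: str = "kmeans") -> TFClusterAssignment:
    """Cluster TFs by module shift pattern; k maximizes mean silhouette.

    ``method='kmeans'`` (primary) or ``method='hierarchical'`` (Ward on
    Euclidean distances). Ties in silhouette prefer the smallest k.
    """
    x = shift_matrix.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 eligible TFs to cluster")
    if k_max >= n:
        warnings.warn(f"k range truncated to 2..{n - 1} ({n} TFs)")
        k_max = n - 1
    d = squareform(pdist(x, metric="euclidean"))
    link = ward(pdist(x)) if method == "hierarchical" else None
    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        if method == "kmeans":
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
            labels = km.fit_predict(x)
        elif method == "hierarchical":
            labels = fcluster(link, t=k, criterion="maxclust")
        else:
            raise ValueError(f"unknown clustering method {method!r}")
        if len(np.unique(labels)) < 2:
            continue
        _, scores[k] = silhouette(d, labels)
        labelings[k] = labels
    if not scores:
        raise ValueError("no candidate k produced at least 2 clusters")
    best_k = max(sorted(scores), key=lambda k: (scores[k], -k))
    labels = pd.Series(labelings[best_k], index=shift_matrix.index, name="cluster")
    return TFClusterAssignment(labels=labels, k=best_k,
                               silhouette_by_k=scores, method=method)


def tf_altered_regulation(shifts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-TF Wilcoxon signed-rank test of edge shifts against zero.

    A stand-in summary of how many TFs show altered regulation overall,
    BH-corrected across TFs; reported separately from the shift-pattern
    pipeline.
    """
    rows = []
    for tf in shifts.index:
        vals = shifts.loc[tf].to_numpy(dtype=float)
        vals = vals[vals != 0] if (vals == 0).all() else vals
        if len(vals) == 0 or (vals == 0).all():
            rows.append((tf, np.nan, 1.0))
            continue
        stat, p = stats.wilcoxon(vals, zero_method="wilcox")
        rows.append((tf, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["tf", "stat", "p"]).set_index("tf")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
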