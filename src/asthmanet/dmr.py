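"""Binding-location proximity test on differentially methylated regions.

For each DMR, every bound TF's motif-hit positions are smoothed into a
binding-density vector (a Gaussian kernel of 21-bp support and 5-bp SD
per hit, the whole vector normalized to sum to 1). Pairwise L1
distances between TF vectors form a distance matrix; TFs closer than
0.1 to another TF (shared or identical motifs) are eliminated
iteratively at random until no such pair remains. The mean silhouette
of the retained TFs under their regulatory-community labels is compared
with a permutation null (labels shuffled among retained TFs); the
p-value is the fraction of permutations whose silhouette strictly
exceeds the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motifs import PFM, scan
from .shift import silhouette


def binding_vector(hits: list[int] | np.ndarray, n_dmr: int,
                   window: int = 21, sd: float = 5.0) -> np.ndarray:
    """Gaussian-smoothed, sum-to-one binding density over a DMR.

    Each hit contributes a Gaussian (mean at the hit, SD ``sd``)
    truncated to the ``window``-bp support centered on the hit and
    clipped at the DMR bounds; the summed vector is normalized globally,
    so edge clipping never breaks the sum-to-one contract.
    """
    hits = np.asarray(hits, dtype=int)
    if hits.size == 0:
        raise ValueError("binding_vector requires at least one hit")
    if (hits < 0).any() or (hits >= n_dmr).any():
        raise ValueError(f"hit positions must lie in [0, {n_dmr})")
    half = (window - 1) // 2
    offsets = np.arange(-half, half + 1)
    kernel = sps.norm.pdf(offsets, loc=0.0, scale=sd)
    v = np.zeros(n_dmr)
    for p in hits:
        lo = max(p - half, 0)
        hi = min(p + half, n_dmr - 1)
        v[lo:hi + 1] += kernel[(lo - p) + half:(hi - p) + half + 1]
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate binding vector")
    return v / total


def distance_matrix(profiles: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise L1 distances between binding vectors (rows)."""
    x = profiles.to_numpy() if isinstance(profiles, pd.DataFrame) else np.asarray(profiles)
    if x.ndim != 2:
        raise ValueError("profiles must be a 2-D array (TF x bp)")
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, 0.0)
    return d


def eliminate_near_duplicates(d: np.ndarray, names: list[str],
                              threshold: float = 0.1,
                              rng: np.random.Generator | int | None = None
                              ) -> tuple[list[int], list[dict]]:
    """Drop TFs until no pair is closer than ``threshold``.

    Iteratively: list all offending pairs, pick one uniformly at random,
    drop one of its members uniformly at random. Returns the retained
    row indices (original order) and a log of drops.
    """
    rng = np.random.default_rng(rng)
    retained = list(range(d.shape[0]))
    log: list[dict] = []
    while len(retained) > 1:
        sub = d[np.ix_(retained, retained)]
        iu = np.triu_indices(len(retained), 1)
        close = np.nonzero(sub[iu] < threshold)[0]
        if close.size == 0:
            break
        pick = close[rng.integers(close.size)]
        i, j = retained[iu[0][pick]], retained[iu[1][pick]]
        drop = i if rng.integers(2) == 0 else j
        keep = j if drop == i else i
        log.append({"dropped": names[drop], "kept": names[keep],
                    "distance": float(d[i, j])})
        retained.remove(drop)
    if not retained:
        raise ValueError("all TFs eliminated; degenerate DMR")
    return retained, log


@dataclass
class ProximityResult:
    """Outcome of the binding-location proximity test on one DMR."""

    dmr_id: str
    retained_tfs: list[str]
    distance: np.ndarray | None
    observed_ss: float | None
    null_ss: np.ndarray | None
    p_value: float | None
    testable: bool
    elimination_log: list[dict] = field(default_factory=list)
    n_tfs_bound: int = 0

    @property
    def stars(self) -> str:
        if not self.testable or self.p_value is None:
            return ""
        for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p_value < cut:
                return mark
        return ""


def _null_silhouettes(d: np.ndarray, codes: np.ndarray, k: int,
                      n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Mean silhouettes of ``n_perm`` label permutations (vectorized)."""
    n = len(codes)
    perms = np.stack([rng.permutation(codes) for _ in range(n_perm)])
    onehot = np.zeros((n_perm, n, k))
    rows = np.repeat(np.arange(n_perm), n)
    cols = np.tile(np.arange(n), n_perm)
    onehot[rows, cols, perms.ravel()] = 1.0
    counts = onehot.sum(axis=1)  # n_perm x k
    sums = np.einsum("ij,pjk->pik", d, onehot)  # n_perm x n x k
    own = perms  # n_perm x n
    own_counts = np.take_along_axis(counts, own, axis=1)  # n_perm x n
    own_sums = np.take_along_axis(sums, own[:, :, None], axis=2)[:, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        a = own_sums / (own_counts - 1)
    means = sums / counts[:, None, :]
    means_masked = means.copy()
    p_idx = np.repeat(np.arange(n_perm), n)
    means_masked[p_idx, cols, own.ravel()] = np.inf
    b = means_masked.min(axis=2)
    denom = np.maximum(a, b)
    s = np.where((own_counts > 1) & (denom > 0), (b - a) / denom, 0.0)
    return s.mean(axis=1)


def proximity_test(profiles: pd.DataFrame, labels: pd.Series,
                   n_perm: int = 10000, seed: int | np.random.SeedSequence = 0,
                   dup_threshold: float = 0.1,
                   dmr_id: str = "") -> ProximityResult:
    """Permutation test of binding-location clustering by community label.

    ``profiles`` is TF x bp (rows sum to 1); ``labels`` maps each TF to
    its regulatory community. Returns an untestable result (not an
    exception) when fewer than two communities survive elimination.
    """
    tfs = list(profiles.index)
    rng = np.random.default_rng(seed)
    d = distance_matrix(profiles)
    retained, log = eliminate_near_duplicates(d, tfs, threshold=dup_threshold,
                                              rng=rng)
    kept_tfs = [tfs[i] for i in retained]
    kept_labels = labels.loc[kept_tfs]
    d_kept = d[np.ix_(retained, retained)]
    uniq, codes = np.unique(kept_labels.to_numpy(), return_inverse=True)
    if len(uniq) < 2:
        return ProximityResult(dmr_id=dmr_id, retained_tfs=kept_tfs,
                               distance=d_kept, observed_ss=None, null_ss=None,
                               p_value=None, testable=False,
                               elimination_log=log, n_tfs_bound=len(tfs))
    _, observed = silhouette(d_kept, codes)
    null = _null_silhouettes(d_kept, codes, len(uniq), n_perm, rng)
    p = float((null > observed).sum()) / n_perm
    return ProximityResult(dmr_id=dmr_id, retained_tfs=kept_tfs,
                           distance=d_kept, observed_ss=float(observed),
                           null_ss=null, p_value=p, testable=True,
                           elimination_log=log, n_tfs_bound=len(tfs))


def profiles_from_hits(hits_by_tf: dict[str, list[int]], n_dmr: int,
                       window: int = 21, sd: float = 5.0) -> pd.DataFrame:
    """Binding profiles for every TF with at least one hit (others excluded)."""
    rows = {tf: binding_vector(pos, n_dmr, window=window, sd=sd)
            for tf, pos in hits_by_tf.items() if len(pos) > 0}
    if not rows:
        return pd.DataFrame(np.empty((0, n_dmr)))
    return pd.DataFrame.from_dict(rows, orient="index")


def run_dmr_panel(dmr_seqs: dict[str, str], pfms: dict[str, PFM],
                  tf_clusters: pd.Series, threshold: float = 0.8,
                  n_perm: int = 10000, seed: int = 0, window: int = 21,
                  sd: float = 5.0, dup_threshold: float = 0.1,
                  hit_position: str = "start"
                  ) -> tuple[pd.DataFrame, dict[str, ProximityResult]]:
    """Scan each DMR and run the proximity test per DMR.

    Hit location is the motif start on the forward strand
    (``hit_position='midpoint'`` uses the motif midpoint instead).
    Returns a summary table plus the full per-DMR results.
    """
    if hit_position not in ("start", "midpoint"):
        raise ValueError(f"unknown hit_position {hit_position!r}")
    root = np.random.SeedSequence(seed)
    results: dict[str, ProximityResult] = {}
    rows = []
    dmr_ids = list(dmr_seqs)
    child_seeds = root.spawn(len(dmr_ids))
    for did, child in zip(dmr_ids, child_seeds):
        seq = dmr_seqs[did]
        hits_by_tf: dict[str, list[int]] = {}
        for tf, pfm in pfms.items():
            if tf not in tf_clusters.index:
                continue
            res = scan(pfm, seq, seq_id=did, threshold=threshold)
            pos = [h.start + (pfm.length // 2 if hit_position == "midpoint" else 0)
                   for h in res]
            if pos:
                hits_by_tf[tf] = pos
        profiles = profiles_from_hits(hits_by_tf, len(seq), window=window, sd=sd)
        if len(profiles) < 2:
            r = ProximityResult(dmr_id=did, retained_tfs=list(profiles.index),
                                distance=None, observed_ss=None, null_ss=None,
                                p_value=None, testable=False,
                                n_tfs_bound=len(profiles))
        else:
            r = proximity_test(profiles, tf_clusters, n_perm=n_perm,
                               seed=child, dup_threshold=dup_threshold,
                               dmr_id=did)
        results[did] = r
        rows.append({
            "dmr": did,
            "n_tfs_bound": r.n_tfs_bound,
            "n_retained": len(r.retained_tfs),
            "observed_ss": r.observed_ss,
            "null_mean": float(r.null_ss.mean()) if r.null_ss is not None else None,
            "p": r.p_value,
            "stars": r.stars,
            "flag": "ok" if r.testable else "untestable",
        })
    table = pd.DataFrame(rows, columns=["dmr", "n_tfs_bound", "n_retained",
                                        "observed_ss", "null_mean", "p",
                                        "stars", "flag"])
    return table, results
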