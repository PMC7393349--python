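"""Signed co-expression modules: adjacency, topological overlap, tree cut,
eigengenes, stimulation/interaction ANOVA, module networks and centrality.

The signed adjacency is a_ij = ((1 + cor_ij)/2)^beta with beta = 12; the
topological overlap matrix (TOM) rescales adjacency by shared-neighbor
structure; modules come from average-linkage clustering of 1 - TOM with
a static cut chosen to maximize the number of branches reaching the
minimum module size, followed by iterative eigengene merging at the 0.15
merge height. Module eigengenes are first principal components of the
gene-standardized module submatrix, sign-fixed to correlate positively
with the module mean profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy import stats

from .expression import ExpressionMatrix, bh_adjust

UNASSIGNED = "unassigned"


def signed_adjacency(expr: pd.DataFrame | ExpressionMatrix, beta: int = 12) -> pd.DataFrame:
    """Signed soft-threshold adjacency ((1 + r)/2)^beta, unit diagonal."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes to build a network")
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples to form correlations")
    sd = values.std(axis=1, ddof=1)
    zero_var = list(values.index[sd == 0])
    if zero_var:
        raise ValueError(f"zero-variance gene(s): {zero_var[:10]}")
    r = np.corrcoef(values.to_numpy())
    a = np.clip(((1.0 + r) / 2.0) ** beta, 0.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=values.index, columns=values.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a signed adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    diag = np.diag(a)
    k = a.sum(axis=1) - diag
    aa = a @ a
    l = aa - a * diag[:, None] - a * diag[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def module_eigengene(expr: pd.DataFrame, genes: list[str] | pd.Index
                     ) -> tuple[pd.Series, float]:
    """First principal component of the gene-standardized module submatrix.

    Returns (eigengene over samples, explained-variance fraction). The
    eigengene has unit norm; its sign is fixed so that it correlates
    positively with the module's mean standardized profile.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("a module eigengene needs at least 2 genes")
    x = expr.loc[genes].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        bad = [g for g, s in zip(genes, sd.ravel()) if s == 0]
        raise ValueError(f"zero-variance gene(s) in module: {bad[:10]}")
    xs = (x - mu) / sd
    _, s, vt = np.linalg.svd(xs, full_matrices=False)
    eig = vt[0]
    explained = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = xs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns, name="eigengene"), explained


@dataclass
class ModuleAssignment:
    """Gene -> module labels; genes in no module carry ``unassigned``."""

    labels: pd.Series

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.labels) - {UNASSIGNED},
                      key=lambda m: (-(self.labels == m).sum(), m))

    def genes_in(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


def _cut_at_best_height(link: np.ndarray, min_module_size: int,
                        max_cut_height: float = 0.95,
                        max_candidates: int = 400) -> np.ndarray:
    """Static-height cut: branches must be complete below the ceiling.

    Scans candidate heights up to ``max_cut_height`` (joins above it are
    background-level dissimilarity in a signed TOM) for the cut that
    maximizes the number, then the coverage, of branches reaching the
    minimum module size. Structureless input, whose joins all sit near
    the top of the dendrogram, therefore yields no module at all.
    """
    heights = np.unique(link[:, 2])
    mids = (heights[:-1] + heights[1:]) / 2.0 if len(heights) > 1 else heights
    cands = np.concatenate([mids, [heights[-1] + 1e-9]]) if len(heights) else np.array([0.0])
    cands = cands[cands <= max_cut_height]
    if len(cands) == 0:
        return np.arange(1, link.shape[0] + 2)  # all singleton branches
    if len(cands) > max_candidates:
        cands = np.quantile(cands, np.linspace(0, 1, max_candidates))
    best = None
    for h in cands:
        labels = fcluster(link, t=h, criterion="distance")
        sizes = np.bincount(labels)
        big = sizes[1:] >= min_module_size
        n_big = int(big.sum())
        covered = int(sizes[1:][big].sum())  # genes inside big branches
        if best is None or (n_big, covered) > (best[0], best[1]):
            best = (n_big, covered, labels)
    return best[2]


def cut_modules(tom: pd.DataFrame, expr: pd.DataFrame | None = None,
                min_module_size: int = 30, merge_height: float = 0.15,
                min_kme: float = 0.3, max_cut_height: float = 0.95
                ) -> ModuleAssignment:
    """Cut the TOM dendrogram into modules and merge correlated eigengenes.

    Average-linkage clustering of 1 - TOM is cut at the static height
    that maximizes the number of branches with at least
    ``min_module_size`` genes; undersized branches become unassigned.
    When ``expr`` is given, modules whose eigengenes correlate above
    1 - merge_height are merged iteratively until stable, and genes
    whose module membership (correlation with the module eigengene)
    falls below ``min_kme`` are released to unassigned. Modules are
    named M1, M2, ... in decreasing size order.
    """
    genes = list(tom.index)
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned")
        return ModuleAssignment(pd.Series(UNASSIGNED, index=tom.index, name="module"))
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = average(squareform(d, checks=False))
    raw = _cut_at_best_height(link, min_module_size, max_cut_height)
    labels = pd.Series(raw, index=tom.index)
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_module_size]
    assign = labels.where(labels.isin(keep), other=-1)

    if expr is not None:
        assign = _merge_by_eigengene(assign, expr, merge_height)
        assign = _apply_kme_floor(assign, expr, min_kme, min_module_size)

    named = _rename_by_size(assign)
    return ModuleAssignment(named)


def _apply_kme_floor(assign: pd.Series, expr: pd.DataFrame, min_kme: float,
                     min_module_size: int) -> pd.Series:
    """Release weakly-attached genes (|kME| handled signed: low positive
    membership) to unassigned; drop modules that fall under min size."""
    assign = assign.copy()
    for m in sorted(set(assign) - {-1}):
        members = assign.index[assign == m]
        eig, _ = module_eigengene(expr, members)
        x = expr.loc[members].to_numpy(dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        e = eig.to_numpy() - eig.to_numpy().mean()
        denom = np.sqrt((xc ** 2).sum(axis=1) * (e ** 2).sum())
        kme = xc @ e / denom
        weak = members[kme < min_kme]
        assign[weak] = -1
        if (assign == m).sum() < min_module_size:
            assign[assign == m] = -1
    return assign


def _merge_by_eigengene(assign: pd.Series, expr: pd.DataFrame,
                        merge_height: float) -> pd.Series:
    assign = assign.copy()
    while True:
        mods = sorted(set(assign) - {-1})
        if len(mods) < 2:
            break
        eigs = np.stack([
            module_eigengene(expr, assign.index[assign == m])[0].to_numpy()
            for m in mods
        ])
        c = np.corrcoef(eigs)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] > 1.0 - merge_height:
            assign[assign == mods[j]] = mods[i]
        else:
            break
    return assign


def _rename_by_size(assign: pd.Series) -> pd.Series:
    order = []
    for m in set(assign) - {-1}:
        members = assign.index[assign == m]
        order.append((-(len(members)), list(members)[0], m))
    mapping = {m: f"M{i + 1}" for i, (_, _, m) in enumerate(sorted(order))}
    mapping[-1] = UNASSIGNED
    return assign.map(mapping).rename("module")


def eigengene_matrix(expr: pd.DataFrame, assignment: ModuleAssignment
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Module x sample eigengene matrix plus explained-variance fractions."""
    rows, ev = {}, {}
    for m in assignment.modules:
        rows[m], ev[m] = module_eigengene(expr, assignment.genes_in(m))
    if not rows:
        raise ValueError("no modules to summarize")
    return pd.DataFrame(rows).T, pd.Series(ev, name="explained_variance")


def eigengene_interaction_test(eigengene: pd.Series, samples: pd.DataFrame
                               ) -> dict[str, float]:
    """Mixed two-way ANOVA on one module eigengene.

    Stimulation (NS vs TT) is the within-subject factor, group the
    between-subject factor. Returns F and p for the stimulation main
    effect and the group x stimulation interaction, plus the stimulation
    sum of squares.
    """
    df = samples.copy()
    df["y"] = eigengene.loc[df.index].to_numpy()
    for subj, sub in df.groupby("subject"):
        if sorted(sub["condition"]) != ["NS", "TT"]:
            raise ValueError(f"subject {subj!r} lacks a paired NS/TT sample")
    if np.isclose(df["y"].std(ddof=1), 0.0):
        raise ValueError("eigengene has zero variance; ANOVA undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=df, dv="y", within="condition",
                             between="group", subject="subject")
    aov = aov.set_index("Source")
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return {
        "F_stimulation": float(aov.loc["condition", "F"]),
        "p_stimulation": float(aov.loc["condition", pcol]),
        "F_interaction": float(aov.loc["Interaction", "F"]),
        "p_interaction": float(aov.loc["Interaction", pcol]),
        "SS_stimulation": float(aov.loc["condition", "SS"]),
    }


def module_network(eigengenes: pd.DataFrame, samples: pd.DataFrame,
                   group: str) -> pd.DataFrame:
    """Pairwise eigengene Pearson correlations within one group.

    Returns a long table (m1, m2, r, p, q, sign, significant) with BH
    correction applied within the group's family of module pairs.
    """
    cols = samples.index[samples["group"] == group]
    if len(cols) < 4:
        raise ValueError(f"group {group!r} has fewer than 4 samples")
    e = eigengenes[cols]
    mods = list(e.index)
    rows = []
    for i in range(len(mods)):
        for j in range(i + 1, len(mods)):
            r, p = stats.pearsonr(e.iloc[i], e.iloc[j])
            rows.append((mods[i], mods[j], float(r), float(p)))
    out = pd.DataFrame(rows, columns=["m1", "m2", "r", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["sign"] = np.where(out["r"] >= 0, "+", "-")
        out["significant"] = out["q"] < 0.05
    return out


def module_network_matrix(network: pd.DataFrame, modules: list[str]) -> pd.DataFrame:
    """Square symmetric r matrix (unit diagonal) from the long table."""
    m = pd.DataFrame(np.eye(len(modules)), index=modules, columns=modules)
    for _, row in network.iterrows():
        m.loc[row.m1, row.m2] = m.loc[row.m2, row.m1] = row.r
    return m


def module_centrality(genes: list[str] | pd.Index,
                      edges: list[tuple[str, str, float]]) -> pd.DataFrame:
    """Degree centrality on the undirected module subgraph.

    Edges are restricted to the module's genes; ranking ties are broken
    by summed edge weight, then lexicographic gene id. Returns the full
    ranking (columns: degree, weight_sum, rank).
    """
    genes = list(genes)
    gset = set(genes)
    degree = {g: 0 for g in genes}
    wsum = {g: 0.0 for g in genes}
    kept = 0
    for a, b, w in edges:
        if a in gset and b in gset and a != b:
            degree[a] += 1
            degree[b] += 1
            wsum[a] += w
            wsum[b] += w
            kept += 1
    if kept == 0:
        warnings.warn("empty module subgraph; all centralities zero")
    out = pd.DataFrame({"degree": pd.Series(degree), "weight_sum": pd.Series(wsum)})
    out["_id"] = out.index
    out = out.sort_values(["degree", "weight_sum", "_id"],
                          ascending=[False, False, True], kind="stable")
    out = out.drop(columns="_id")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
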