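"""Count containers, normalization and the paired differential-expression stage.

Normalization is median-of-ratios size factors followed by log2(x/sf + 1);
differential expression is a paired t-test on per-subject TT-NS
differences of the normalized values, BH-corrected within each group's
test family. This is a declared, pluggable stand-in for an off-the-shelf
variance-stabilizing + Wald pipeline: only its output (the set of genes
perturbed by stimulation) feeds the bespoke network analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUPS = ("control", "asthma")
CONDITIONS = ("NS", "TT")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``samples`` is indexed by sample id with columns ``subject``,
    ``group`` (control/asthma) and ``condition`` (NS/TT). Every subject
    must contribute exactly one NS and one TT sample.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("count columns and sample metadata rows disagree")
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("subject", "group", "condition"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        for subj, sub in self.samples.groupby("subject"):
            conds = sorted(sub["condition"])
            if conds != ["NS", "TT"]:
                raise ValueError(
                    f"subject {subj!r} must have exactly one NS and one TT "
                    f"sample, found {conds}"
                )
            if sub["group"].nunique() != 1:
                raise ValueError(f"subject {subj!r} appears in multiple groups")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, mask: pd.Series) -> "CountMatrix":
        keep = self.samples.index[mask]
        return CountMatrix(self.values[keep], self.samples.loc[keep])


@dataclass
class ExpressionMatrix:
    """Normalized gene x sample expression on a log2 scale."""

    values: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series
    transform: str = "median-of-ratios size factors, log2(x/sf + 1)"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("expression matrix contains non-finite values")


@dataclass
class DEResult:
    """Per-gene paired TT-vs-NS test results for one group."""

    group: str
    table: pd.DataFrame  # columns: log2fc, p, q, direction

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def significant(self, q_threshold: float) -> pd.Index:
        return self.table.index[self.table["q"] < q_threshold]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Genes with any zero count are excluded from the geometric-mean
    reference (the standard convention).
    """
    all_zero = counts.columns[(counts == 0).all(axis=0)]
    if len(all_zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(all_zero)}")
    ref_mask = (counts > 0).all(axis=1)
    if not ref_mask.any():
        raise ValueError("no gene has all-positive counts; cannot form reference")
    ref = counts.loc[ref_mask].astype(float)
    log_geo = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geo, axis=0)
    sf = np.exp(ratios.median(axis=0))
    sf.name = "size_factor"
    return sf


def normalize(counts: CountMatrix) -> ExpressionMatrix:
    """Normalize counts to log2((count / size_factor) + 1)."""
    sf = size_factors(counts.values)
    norm = np.log2(counts.values.astype(float).div(sf, axis=1) + 1.0)
    return ExpressionMatrix(values=norm, samples=counts.samples.copy(),
                            size_factors=sf)


def paired_de(counts: CountMatrix, group: str,
              expr: ExpressionMatrix | None = None) -> DEResult:
    """Paired TT-vs-NS test per gene within one group.

    Tests per-subject differences of normalized expression (TT - NS)
    against zero with a paired t-test; BH correction is applied across
    the genes tested within this group.
    """
    meta = counts.samples
    if group not in set(meta["group"]):
        raise ValueError(f"group {group!r} not present in sample metadata")
    if expr is None:
        expr = normalize(counts)
    sub = meta[meta["group"] == group]
    subjects = sub["subject"].unique()
    if len(subjects) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 subjects")
    ns_cols = [sub.index[(sub.subject == s) & (sub.condition == "NS")][0]
               for s in subjects]
    tt_cols = [sub.index[(sub.subject == s) & (sub.condition == "TT")][0]
               for s in subjects]
    diffs = expr.values[tt_cols].to_numpy() - expr.values[ns_cols].to_numpy()
    lfc = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    n = diffs.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance difference -> null
    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "q": q,
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
        },
        index=counts.gene_ids,
    )
    return DEResult(group=group, table=table)


def select_perturbed_union(de_control: DEResult, de_case: DEResult,
                           q_threshold: float = 0.05) -> pd.Index:
    """Genes with q below threshold in either group's paired test."""
    if set(de_control.gene_ids) != set(de_case.gene_ids):
        raise ValueError("differential-expression results cover different gene universes")
    sig = set(de_control.significant(q_threshold)) | set(de_case.significant(q_threshold))
    return pd.Index([g for g in de_control.gene_ids if g in sig])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    _, q, _, _ = multipletests(np.asarray(p, dtype=float), method="fdr_bh")
    return q
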