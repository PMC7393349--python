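"""Synthetic study generator.

Emulates the statistical structure the downstream analysis assumes:

* negative-binomial RNA-seq counts for paired NS/TT samples in a control
  and an asthma group, with gene modules driven by latent factors whose
  inter-module correlation signs differ between groups for a configured
  fraction of module pairs, and a per-module TT mean shift shared by
  both groups (no planted group x stimulation mean effect);
* information-rich position frequency matrices per TF with planted
  consensus occurrences in the promoters of each TF's intended targets;
* DMR sequences in which two TF communities occupy binding zones offset
  by ``cluster_separation`` bp;
* a symmetric TF-TF interaction prior with higher within-community
  weights;
* constructed case/control regulatory networks whose edge-weight
  difference carries community-specific sign patterns across modules.

All randomness descends from ``cfg.seed`` through a single SeedSequence
split per stage, so each generator is reproducible independently of the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .expression import CountMatrix
from .motifs import PFM

BASES = np.array(list("ACGT"))

# stage slots for the root SeedSequence
_STAGE_COUNTS, _STAGE_SEQS, _STAGE_PPI, _STAGE_SHIFT = range(4)


def _stage_rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    return np.random.default_rng(children[stage])


@dataclass
class GroundTruth:
    """Planted structure behind one simulated study."""

    gene_module_labels: pd.Series
    tf_cluster_labels: pd.Series
    module_sign: dict[str, pd.DataFrame]
    tt_direction: pd.Series
    tf_target_module: pd.Series
    tf_targets: dict[str, list[str]]
    community_shift_signs: pd.DataFrame
    consensus: dict[str, str] = field(default_factory=dict)
    promoter_motif_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    dmr_motif_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    dmr_tfs: dict[str, list[str]] = field(default_factory=dict)

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "gene_module_labels": self.gene_module_labels.to_dict(),
            "tf_cluster_labels": self.tf_cluster_labels.to_dict(),
            "module_sign": {g: df.values.tolist() for g, df in self.module_sign.items()},
            "tt_direction": self.tt_direction.to_dict(),
            "tf_target_module": self.tf_target_module.to_dict(),
            "tf_targets": self.tf_targets,
            "community_shift_signs": {
                "index": list(self.community_shift_signs.index),
                "columns": list(self.community_shift_signs.columns),
                "values": self.community_shift_signs.values.tolist(),
            },
            "consensus": self.consensus,
            "promoter_motif_positions": self.promoter_motif_positions,
            "dmr_motif_positions": self.dmr_motif_positions,
            "dmr_tfs": self.dmr_tfs,
        }


def module_names(n: int) -> list[str]:
    return [f"M{i + 1}" for i in range(n)]


def _psd_correlation(sign: np.ndarray, rho: float) -> np.ndarray:
    """Correlation matrix with off-diagonal rho * sign, clipped to PSD."""
    k = sign.shape[0]
    c = np.eye(k) + rho * (sign - np.diag(np.diag(sign)))
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 1e-3, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def simulate_counts(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the paired two-group count matrix and its ground truth.

    Gene log2-means are baseline + loading * module factor + per-module
    TT shift + subject baseline; counts are negative-binomial
    (gamma-Poisson) around the resulting means with common dispersion.
    TF transcripts are included as extra rows so regulatory-network
    co-expression matrices can include TF expression.
    """
    rng = _stage_rng(cfg, _STAGE_COUNTS)
    mods = module_names(cfg.n_modules)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    background = [f"G{cfg.n_genes + i:05d}" for i in range(cfg.n_background_genes)]
    tfs = [f"TF{i:03d}" for i in range(cfg.n_tfs)]

    gene_module = pd.Series(
        [mods[i % cfg.n_modules] for i in range(cfg.n_genes)]
        + ["unassigned"] * cfg.n_background_genes,
        index=genes + background, name="module")
    tf_comm = pd.Series(["A" if i < cfg.n_tfs // 2 else "B" for i in range(cfg.n_tfs)],
                        index=tfs, name="community")
    # each TF preferentially co-expresses with (and targets) one module;
    # community A TFs target the first half of the modules, community B
    # the second half, so regulatory changes separate by community
    half_m = max(cfg.n_modules // 2, 1)
    first, second = mods[:half_m], mods[half_m:] or mods
    tf_target_module = pd.Series(
        [first[i % len(first)] if tf_comm.iloc[i] == "A"
         else second[i % len(second)] for i in range(cfg.n_tfs)],
        index=tfs, name="target_module")
    tf_targets = {
        t: sorted(rng.choice(gene_module.index[gene_module == tf_target_module[t]],
                             size=min(cfg.targets_per_tf,
                                      int((gene_module == tf_target_module[t]).sum())),
                             replace=False).tolist())
        for t in tfs
    }

    # per-group inter-module correlation signs; the case group flips a fraction
    k = cfg.n_modules
    iu = np.triu_indices(k, 1)
    base_signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
    sign_ctrl = np.eye(k)
    sign_ctrl[iu] = base_signs
    sign_ctrl = sign_ctrl + sign_ctrl.T - np.eye(k)
    n_flip = int(round(cfg.flip_fraction * len(iu[0])))
    flip_idx = rng.choice(len(iu[0]), size=n_flip, replace=False)
    case_signs = base_signs.copy()
    case_signs[flip_idx] *= -1.0
    sign_case = np.eye(k)
    sign_case[iu] = case_signs
    sign_case = sign_case + sign_case.T - np.eye(k)
    module_sign = {
        "control": pd.DataFrame(sign_ctrl, index=mods, columns=mods),
        "asthma": pd.DataFrame(sign_case, index=mods, columns=mods),
    }
    chol = {
        g: np.linalg.cholesky(_psd_correlation(module_sign[g].values, cfg.module_corr))
        for g in module_sign
    }

    # alternating stimulation directions keep the library composition
    # balanced, so median-of-ratios size factors stay identifiable
    tt_dir = pd.Series([1.0 if i % 2 == 0 else -1.0 for i in range(k)],
                       index=mods, name="tt_direction")

    sample_rows = []
    for g, n_subj, prefix in (("control", cfg.n_subjects_control, "C"),
                              ("asthma", cfg.n_subjects_case, "A")):
        for s in range(n_subj):
            subj = f"{prefix}{s:03d}"
            for cond in ("NS", "TT"):
                sample_rows.append((f"{subj}_{cond}", subj, g, cond))
    samples = pd.DataFrame(sample_rows,
                           columns=["sample", "subject", "group", "condition"]
                           ).set_index("sample")

    all_ids = genes + background + tfs
    n_rows = len(all_ids)
    base_log2 = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_rows)
    loadings = rng.normal(1.0, 0.15, size=n_rows)
    row_module_idx = np.array(
        [mods.index(gene_module[g]) for g in genes]
        + [0] * cfg.n_background_genes
        + [mods.index(tf_target_module[t]) for t in tfs]
    )
    # background genes carry no module factor and no stimulation shift;
    # TF transcripts load a bit more weakly on their module factor
    load_scale = np.concatenate([np.ones(cfg.n_genes),
                                 np.zeros(cfg.n_background_genes),
                                 np.full(cfg.n_tfs, 0.8)])
    tt_mask = load_scale > 0

    subjects = samples["subject"].unique()
    subj_effect = pd.DataFrame(
        rng.normal(0.0, cfg.subject_sd, size=(n_rows, len(subjects))),
        index=all_ids, columns=subjects)

    # module-factor draws: one NS draw per subject; the TT draw persists
    # from it with correlation subject_factor_persistence
    subj_group = samples.drop_duplicates("subject").set_index("subject")["group"]
    rho = cfg.subject_factor_persistence
    factors: dict[tuple[str, str], np.ndarray] = {}
    for subj in subjects:
        ch = chol[subj_group[subj]]
        f_ns = ch @ rng.standard_normal(k)
        f_tt = rho * f_ns + np.sqrt(1.0 - rho ** 2) * (ch @ rng.standard_normal(k))
        factors[(subj, "NS")] = f_ns
        factors[(subj, "TT")] = f_tt

    log2_mu = np.empty((n_rows, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        f = factors[(row["subject"], row["condition"])]
        tt = (row["condition"] == "TT")
        log2_mu[:, j] = (
            base_log2
            + cfg.module_factor_sd * loadings * load_scale * f[row_module_idx]
            + (cfg.tt_effect_log2 * tt_dir.values[row_module_idx] * tt_mask
               if tt else 0.0)
            + subj_effect[row["subject"]].values
        )
    mu = np.maximum(2.0 ** log2_mu, 1.0)  # baseline floor: no all-zero genes
    lam = rng.gamma(shape=cfg.nb_dispersion, scale=mu / cfg.nb_dispersion)
    counts = rng.poisson(lam)

    cm = CountMatrix(pd.DataFrame(counts, index=all_ids, columns=samples.index),
                     samples)
    # community-level shift sign pattern: community A positive on the first
    # half of modules, negative on the rest; B the mirror image
    half = k // 2 if k > 1 else 1
    pattern = np.array([1.0 if i < half else -1.0 for i in range(k)])
    css = pd.DataFrame([pattern, -pattern], index=["A", "B"], columns=mods)
    truth = GroundTruth(
        gene_module_labels=gene_module,
        tf_cluster_labels=tf_comm,
        module_sign=module_sign,
        tt_direction=tt_dir,
        tf_target_module=tf_target_module,
        tf_targets=tf_targets,
        community_shift_signs=css,
    )
    return cm, truth


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _plant(seq: np.ndarray, plants: list[tuple[str, str]], positions: np.ndarray,
           rng: np.random.Generator) -> list[tuple[str, int]]:
    """Insert motif words at roughly the drawn positions without overlap.

    Plants are sorted by drawn position and nudged right until
    non-overlapping; if the block runs past the sequence end it is
    shifted left as a whole. Positions may be continuous (sort order is
    then tie-free); rounding happens at placement. Returns the realized
    (tf, start) list.
    """
    length = len(seq)
    positions = np.asarray(positions, dtype=float)
    order = np.argsort(positions, kind="stable")
    placed: list[tuple[str, int, str]] = []
    cursor = -1
    for idx in order:
        tf, word = plants[idx]
        start = max(int(round(positions[idx])), cursor)
        start = min(start, length - len(word))
        if start < cursor:
            start = cursor
        placed.append((tf, start, word))
        cursor = start + len(word)
    if cursor > length:
        if sum(len(word) for _, word in plants) > length:
            raise ConfigError(
                "planted motifs do not fit in the sequence; increase its length")
        # backward clamping pass: pull overflowing plants left, preserving order
        end_cursor = length
        for pos in range(len(placed) - 1, -1, -1):
            tf, start, word = placed[pos]
            start = min(start, end_cursor - len(word))
            placed[pos] = (tf, start, word)
            end_cursor = start
    out = []
    for tf, start, word in placed:
        seq[start:start + len(word)] = list(word)
        out.append((tf, start))
    return out


_RC = str.maketrans("ACGT", "TGCA")


def _dissimilar(word: str, existing: list[str], min_mismatch: int = 2,
                min_overlap: int = 5) -> bool:
    """True when ``word`` cannot cross-hit any existing word's sites.

    Every alignment of ``word`` against each existing word (both
    strands) and against shifted copies of itself must carry at least
    ``min_mismatch`` mismatches wherever the overlap spans
    ``min_overlap`` or more bases, so no planted occurrence of one
    motif scores within one mismatch of another motif's consensus.
    """
    L = len(word)
    others = []
    for v in existing:
        others.append(v)
        others.append(v.translate(_RC)[::-1])
    others.append(word.translate(_RC)[::-1])
    self_shifts = [(word, s) for s in range(-(L - min_overlap), L - min_overlap + 1)
                   if s != 0]
    pairs = [(v, s) for v in others
             for s in range(-(L - min_overlap), L - min_overlap + 1)]
    for v, s in pairs + self_shifts:
        lo, hi = max(0, s), min(L, len(v) + s)
        if hi - lo < min_overlap:
            continue
        mism = sum(word[i] != v[i - s] for i in range(lo, hi))
        if mism < min_mismatch:
            return False
    return True


def simulate_motifs_and_sequences(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, PFM], dict[str, str], dict[str, str], pd.DataFrame]:
    """Generate PFMs, promoter FASTA records, and DMR FASTA/BED records.

    Each TF receives a PFM whose per-column dominant base (count 16 of
    20) spells a unique consensus word; consensus occurrences are
    planted in the promoters of the TF's intended targets and, for DMRs,
    around the TF community's binding zone center. Realized positions
    are recorded on ``truth``.

    Returns ``(pfms, promoters, dmr_seqs, dmr_bed)``.
    """
    if cfg.motif_length > cfg.dmr_length:
        raise ConfigError("motif_length must not exceed dmr_length")
    rng = _stage_rng(cfg, _STAGE_SEQS)
    tfs = list(truth.tf_cluster_labels.index)

    consensus: dict[str, str] = {}
    words: list[str] = []
    for t in tfs:
        for _ in range(5000):
            word = "".join(_random_seq(rng, cfg.motif_length))
            if _dissimilar(word, words):
                break
        else:
            raise ConfigError(
                "could not draw mutually dissimilar consensus words; "
                "reduce n_tfs or increase motif_length")
        words.append(word)
        consensus[t] = word
    truth.consensus = consensus

    # column model: dominant base 17 of 20, remaining bases 1 each — a
    # uniform per-column score range, under which the 0.8 relative-score
    # threshold admits at most one mismatch from the consensus
    pfms: dict[str, PFM] = {}
    base_index = {b: i for i, b in enumerate("ACGT")}
    for t in tfs:
        counts = np.where(
            np.arange(4)[:, None]
            == np.array([base_index[b] for b in consensus[t]])[None, :],
            17.0, 1.0)
        pfms[t] = PFM(name=t, counts=counts)

    promoters: dict[str, str] = {}
    gene_plants: dict[str, list[tuple[str, str]]] = {}
    for t in tfs:
        for g in truth.tf_targets[t]:
            n_occ = int(rng.integers(1, 3))
            gene_plants.setdefault(g, []).extend([(t, consensus[t])] * n_occ)
    # TF transcripts get promoters too, so co-expression matrices over the
    # target universe can include TF expression
    for g in list(truth.gene_module_labels.index) + tfs:
        seq = _random_seq(rng, cfg.promoter_length)
        plants = gene_plants.get(g, [])
        if plants:
            pos = rng.integers(0, cfg.promoter_length - cfg.motif_length + 1,
                               size=len(plants))
            truth.promoter_motif_positions[g] = _plant(seq, plants, pos, rng)
        promoters[g] = "".join(seq)

    dmr_seqs: dict[str, str] = {}
    bed_rows = []
    comm = truth.tf_cluster_labels
    center = cfg.dmr_length / 2.0
    centers = {"A": center - cfg.cluster_separation / 2.0,
               "B": center + cfg.cluster_separation / 2.0}
    for d in range(cfg.n_dmrs):
        did = f"DMR{d:02d}"
        seq = _random_seq(rng, cfg.dmr_length)
        chosen: list[str] = []
        for c in ("A", "B"):
            pool = list(comm.index[comm == c])
            n_pick = min(cfg.dmr_tfs_per_community, len(pool))
            chosen += sorted(rng.choice(pool, size=n_pick, replace=False).tolist())
        plants: list[tuple[str, str]] = []
        pos_draws: list[float] = []
        for t in chosen:
            for _ in range(cfg.dmr_hits_per_tf):
                plants.append((t, consensus[t]))
                pos_draws.append(rng.normal(centers[comm[t]], cfg.dmr_position_sd))
        pos = np.clip(np.asarray(pos_draws), 0.0,
                      float(cfg.dmr_length - cfg.motif_length))
        truth.dmr_motif_positions[did] = _plant(seq, plants, pos, rng)
        truth.dmr_tfs[did] = chosen
        dmr_seqs[did] = "".join(seq)
        bed_rows.append((did, 0, cfg.dmr_length, did))
    dmr_bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name"])
    return pfms, promoters, dmr_seqs, dmr_bed


def simulate_ppi(cfg: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Symmetric TF-TF interaction prior, unit diagonal.

    Within-community weights are drawn Uniform(0.6, 0.9), between-
    community weights Uniform(0.1, 0.4).
    """
    rng = _stage_rng(cfg, _STAGE_PPI)
    tfs = list(truth.tf_cluster_labels.index)
    comm = truth.tf_cluster_labels
    n = len(tfs)
    w = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if comm.iloc[i] == comm.iloc[j]:
                w[i, j] = w[j, i] = rng.uniform(0.6, 0.9)
            else:
                w[i, j] = w[j, i] = rng.uniform(0.1, 0.4)
    return pd.DataFrame(w, index=tfs, columns=tfs)


def simulate_shift_networks(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Constructed (case, control) TF x gene edge-weight networks.

    The case-minus-control difference of each edge is the TF community's
    sign for the target gene's module times ``shift_delta``, plus
    Gaussian noise — the planted geometry behind shift-pattern cluster
    recovery.
    """
    rng = _stage_rng(cfg, _STAGE_SHIFT)
    tfs = list(truth.tf_cluster_labels.index)
    labeled = truth.gene_module_labels[truth.gene_module_labels != "unassigned"]
    genes = list(labeled.index)
    mods = list(truth.community_shift_signs.columns)
    gmod = np.array([mods.index(truth.gene_module_labels[g]) for g in genes])
    sign = np.stack([
        truth.community_shift_signs.loc[truth.tf_cluster_labels[t]].values[gmod]
        for t in tfs
    ])
    control = rng.standard_normal((len(tfs), len(genes)))
    case = control + cfg.shift_delta * sign + rng.normal(
        0.0, cfg.shift_noise_sd, size=control.shape)
    idx = pd.Index(tfs)
    cols = pd.Index(genes)
    return (pd.DataFrame(case, index=idx, columns=cols),
            pd.DataFrame(control, index=idx, columns=cols))
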