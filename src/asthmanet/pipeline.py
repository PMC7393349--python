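"""End-to-end orchestration: simulate -> expression -> modules -> prior ->
regulatory networks x4 -> regulatory shift -> DMR proximity.

Every stage reads the previous stage's plain-text outputs from the
output directory and can be re-run standalone; ``run_all`` executes the
eight stages in order and writes a manifest recording parameters and
the SHA-256 of every output file (relative paths only, so manifests
from identical runs are byte-identical). With ``resume=True`` a stage
whose outputs already exist is skipped.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from . import dmr as dmr_mod
from . import expression as expr_mod
from . import io
from .motifs import build_prior
from . import panda as panda_mod
from . import shift as shift_mod
from . import simulate as sim_mod
from . import wgcna

logger = logging.getLogger(__name__)

STAGES = ("simulate", "expression", "de", "modules", "prior", "panda",
          "shift", "dmr")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seed(cfg: PipelineConfig, slot: int) -> int:
    state = np.random.SeedSequence(cfg.seed).generate_state(8, dtype=np.uint32)
    return int(state[slot]) & 0x7FFFFFFF


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
    counts, truth = sim_mod.simulate_counts(sim_cfg)
    pfms, promoters, dmr_seqs, dmr_bed = sim_mod.simulate_motifs_and_sequences(
        sim_cfg, truth)
    ppi = sim_mod.simulate_ppi(sim_cfg, truth)
    io.write_counts(counts, out / "counts.tsv", out / "samples.tsv")
    io.write_jaspar(pfms, out / "motifs.jaspar")
    io.write_fasta(promoters, out / "promoters.fa")
    io.write_fasta(dmr_seqs, out / "dmrs.fa")
    io.write_bed(dmr_bed, out / "dmrs.bed")
    io.write_edge_list(ppi, out / "ppi.tsv")
    io.write_json(truth.to_jsonable(), out / "truth.json")


def stage_expression(cfg: PipelineConfig, out: Path) -> None:
    counts = io.read_counts(out / "counts.tsv", out / "samples.tsv")
    expr = expr_mod.normalize(counts)
    io.write_matrix(expr.values, out / "normalized.tsv", index_label="gene")
    expr.size_factors.to_frame().to_csv(out / "size_factors.tsv", sep="\t",
                                        index_label="sample")


def stage_de(cfg: PipelineConfig, out: Path) -> None:
    counts = io.read_counts(out / "counts.tsv", out / "samples.tsv")
    expr = expr_mod.normalize(counts)
    de = {}
    for group in expr_mod.GROUPS:
        de[group] = expr_mod.paired_de(counts, group, expr=expr)
        de[group].table.to_csv(out / f"de_{group}.tsv", sep="\t",
                               index_label="gene")
    perturbed = expr_mod.select_perturbed_union(de["control"], de["asthma"],
                                                cfg.q_threshold)
    # TF transcripts never enter the differential-expression universe of
    # interest but are carried alongside for network co-expression
    (out / "perturbed_genes.txt").write_text(
        "".join(f"{g}\n" for g in perturbed if not g.startswith("TF")))


def _perturbed_non_tf(out: Path) -> list[str]:
    return (out / "perturbed_genes.txt").read_text().split()


def stage_modules(cfg: PipelineConfig, out: Path) -> None:
    expr = io.read_matrix(out / "normalized.tsv")
    samples = pd.read_csv(out / "samples.tsv", sep="\t", index_col="sample")
    genes = _perturbed_non_tf(out)
    sub = expr.loc[genes]
    adj = wgcna.signed_adjacency(sub, beta=cfg.beta)
    tom = wgcna.topological_overlap(adj)
    assignment = wgcna.cut_modules(tom, expr=sub,
                                   min_module_size=cfg.min_module_size,
                                   merge_height=cfg.merge_height)
    assignment.labels.to_frame().to_csv(out / "modules.tsv", sep="\t",
                                        index_label="gene")
    eigs, ev = wgcna.eigengene_matrix(sub, assignment)
    io.write_matrix(eigs, out / "eigengenes.tsv", index_label="module")
    ev.to_frame().to_csv(out / "explained_variance.tsv", sep="\t",
                         index_label="module")
    anova_rows = {}
    for m in assignment.modules:
        anova_rows[m] = wgcna.eigengene_interaction_test(eigs.loc[m], samples)
    pd.DataFrame(anova_rows).T.to_csv(out / "eigengene_anova.tsv", sep="\t",
                                      index_label="module")
    for group in expr_mod.GROUPS:
        net = wgcna.module_network(eigs, samples, group)
        net.to_csv(out / f"module_network_{group}.tsv", sep="\t", index=False)
    # interaction edge list for centrality: strong within-module adjacency
    # (stand-in for an external protein-interaction network)
    cent_rows = []
    for m in assignment.modules:
        mg = list(assignment.genes_in(m))
        sub_a = adj.loc[mg, mg].to_numpy()
        iu = np.triu_indices(len(mg), 1)
        if len(iu[0]) == 0:
            continue
        thresh = np.quantile(sub_a[iu], 0.9)
        edges = [(mg[i], mg[j], float(sub_a[i, j]))
                 for i, j in zip(*iu) if sub_a[i, j] >= thresh]
        cent = wgcna.module_centrality(mg, edges)
        cent.insert(0, "module", m)
        cent_rows.append(cent)
    pd.concat(cent_rows).to_csv(out / "centrality.tsv", sep="\t",
                                index_label="gene")


def stage_prior(cfg: PipelineConfig, out: Path) -> None:
    pfms = io.read_jaspar(out / "motifs.jaspar")
    promoters = io.read_fasta(out / "promoters.fa")
    prior = build_prior(pfms, promoters, threshold=cfg.motif_threshold)
    io.write_matrix(prior, out / "prior.tsv", index_label="tf")


def stage_panda(cfg: PipelineConfig, out: Path) -> None:
    prior = io.read_matrix(out / "prior.tsv").astype(int)
    ppi = io.read_edge_list(out / "ppi.tsv")
    expr = io.read_matrix(out / "normalized.tsv")
    samples = pd.read_csv(out / "samples.tsv", sep="\t", index_col="sample")
    genes = _perturbed_non_tf(out)
    tfs = list(prior.index)
    universe = [g for g in genes if g in prior.columns] + \
        [t for t in tfs if t in prior.columns and t in expr.index]
    w0_counts = prior[universe]
    meta = {}
    for group in expr_mod.GROUPS:
        for cond in expr_mod.CONDITIONS:
            cols = samples.index[(samples.group == group)
                                 & (samples.condition == cond)]
            w0, p0, c0 = panda_mod.prepare_inputs(w0_counts, ppi,
                                                  expr.loc[universe, cols])
            net = panda_mod.panda_fit(w0, p0, c0, alpha=cfg.panda_alpha,
                                      tol=cfg.panda_tol,
                                      max_iter=cfg.panda_max_iter)
            io.write_matrix(net.weights, out / f"network_{group}_{cond}.tsv",
                            index_label="tf")
            meta[f"{group}_{cond}"] = {
                "alpha": cfg.panda_alpha, "tol": cfg.panda_tol,
                "iterations": net.n_iter, "converged": bool(net.converged),
            }
    io.write_json(meta, out / "panda_meta.json")


def stage_shift(cfg: PipelineConfig, out: Path) -> None:
    net_case = io.read_matrix(out / "network_asthma_TT.tsv")
    net_ctrl = io.read_matrix(out / "network_control_TT.tsv")
    prior = io.read_matrix(out / "prior.tsv").astype(int)
    labels = pd.read_csv(out / "modules.tsv", sep="\t", index_col="gene")["module"]
    assignment = wgcna.ModuleAssignment(labels)
    shifts = shift_mod.edge_shift(net_case, net_ctrl)
    targets = prior.loc[shifts.index, shifts.columns] > 0
    sm = shift_mod.module_median_shift(shifts, assignment, targets)
    io.write_matrix(sm, out / "shift_matrix.tsv", index_label="tf")
    sm.reset_index().melt(id_vars="tf", var_name="module",
                          value_name="median_shift").to_csv(
        out / "shift_long.tsv", sep="\t", index=False)
    clusters = shift_mod.cluster_tfs(sm, k_min=cfg.k_min, k_max=cfg.k_max,
                                     seed=_stage_seed(cfg, 5))
    clusters.labels.to_frame().to_csv(out / "tf_clusters.tsv", sep="\t",
                                      index_label="tf")
    pd.Series(clusters.silhouette_by_k, name="mean_silhouette").to_csv(
        out / "silhouette_by_k.tsv", sep="\t", index_label="k")
    altered = shift_mod.tf_altered_regulation(shifts)
    altered.to_csv(out / "tf_altered.tsv", sep="\t", index_label="tf")


def stage_dmr(cfg: PipelineConfig, out: Path) -> None:
    pfms = io.read_jaspar(out / "motifs.jaspar")
    dmr_seqs = io.read_fasta(out / "dmrs.fa")
    tf_clusters = pd.read_csv(out / "tf_clusters.tsv", sep="\t",
                              index_col="tf")["cluster"]
    table, results = dmr_mod.run_dmr_panel(
        dmr_seqs, pfms, tf_clusters, threshold=cfg.motif_threshold,
        n_perm=cfg.n_perm, seed=_stage_seed(cfg, 6),
        window=cfg.gaussian_window, sd=cfg.gaussian_sd,
        dup_threshold=cfg.dup_threshold)
    table.to_csv(out / "dmr_proximity.tsv", sep="\t", index=False)
    for did, r in results.items():
        if r.null_ss is not None:
            pd.Series(r.null_ss, name="null_ss").to_csv(
                out / f"dmr_null_{did}.tsv", sep="\t", index=False)
    # BED of motif hits per DMR (0-based half-open)
    from .motifs import scan
    bed_rows = []
    for did, seq in dmr_seqs.items():
        for tf, pfm in pfms.items():
            for h in scan(pfm, seq, seq_id=did, threshold=cfg.motif_threshold):
                bed_rows.append((did, h.start, h.start + pfm.length, tf,
                                 int(round(h.relative_score * 1000)), h.strand))
    io.write_bed(pd.DataFrame(bed_rows, columns=["chrom", "start", "end",
                                                 "name", "score", "strand"]),
                 out / "dmr_hits.bed")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "expression": stage_expression,
    "de": stage_de,
    "modules": stage_modules,
    "prior": stage_prior,
    "panda": stage_panda,
    "shift": stage_shift,
    "dmr": stage_dmr,
}

_STAGE_OUTPUTS = {
    "simulate": ["counts.tsv", "samples.tsv", "motifs.jaspar", "promoters.fa",
                 "dmrs.fa", "dmrs.bed", "ppi.tsv", "truth.json"],
    "expression": ["normalized.tsv", "size_factors.tsv"],
    "de": ["de_control.tsv", "de_asthma.tsv", "perturbed_genes.txt"],
    "modules": ["modules.tsv", "eigengenes.tsv", "explained_variance.tsv",
                "eigengene_anova.tsv", "module_network_control.tsv",
                "module_network_asthma.tsv", "centrality.tsv"],
    "prior": ["prior.tsv"],
    "panda": ["network_control_NS.tsv", "network_control_TT.tsv",
              "network_asthma_NS.tsv", "network_asthma_TT.tsv",
              "panda_meta.json"],
    "shift": ["shift_matrix.tsv", "shift_long.tsv", "tf_clusters.tsv",
              "silhouette_by_k.tsv", "tf_altered.tsv"],
    "dmr": ["dmr_proximity.tsv", "dmr_hits.bed"],
}


def run_all(cfg: PipelineConfig, resume: bool = False,
            stages: tuple[str, ...] = STAGES) -> Path:
    """Run the pipeline stages in order and write the manifest.

    Returns the output directory. Any stage failure raises
    :class:`StageError` naming the stage; earlier outputs remain on
    disk.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    executed = []
    for stage in stages:
        outputs = [out / f for f in _STAGE_OUTPUTS[stage]]
        if resume and all(f.exists() for f in outputs):
            logger.info("stage %s: outputs present, skipped (resume)", stage)
            executed.append({"stage": stage, "skipped": True})
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, exc) from exc
        logger.info("stage %s finished in %.1fs", stage,
                    time.perf_counter() - t0)
        executed.append({"stage": stage, "skipped": False})
    manifest = {
        "package_version": __version__,
        "parameters": cfg.to_dict(),
        "stages": executed,
        "files": {
            str(p.relative_to(out)): io.sha256_file(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    manifest["parameters"]["outdir"] = "."  # path-independent manifests
    io.write_json(manifest, out / "manifest.json")
    return out
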