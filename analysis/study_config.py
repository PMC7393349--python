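"""Shared configuration for the numbered analysis scripts.

A desk-scale rendition of the study design: 30 control and 19 asthma
subjects with paired NS/TT samples, four planted co-expression modules
among 1200 module genes (plus 2400 unperturbed background genes), 20
TFs in two regulatory communities, and ten 500-bp DMRs whose community
binding zones sit 250 bp apart. Heavy intermediates live under
``scratch/analysis`` (regenerated on demand); each script writes its
summary tables under ``results/``.
"""

from pathlib import Path

from asthmanet.config import PipelineConfig, SimulationConfig

WORKDIR = Path("scratch/analysis")
RESULTS = Path("results")


def analysis_config(seed: int = 20) -> PipelineConfig:
    return PipelineConfig(
        sim=SimulationConfig(
            n_genes=1200, n_background_genes=2400, n_tfs=20, n_modules=4,
            n_subjects_control=30, n_subjects_case=19, targets_per_tf=15,
            n_dmrs=10, dmr_length=500, cluster_separation=250),
        outdir=WORKDIR, n_perm=10000, seed=seed)
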