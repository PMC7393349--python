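"""Generate the synthetic study: counts, motifs, promoters, DMRs, PPI.

Writes the raw study files under scratch/analysis and a one-page design
summary to results/01_study_summary.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from asthmanet import io
from asthmanet.pipeline import run_all
from study_config import RESULTS, WORKDIR, analysis_config


def main() -> None:
    cfg = analysis_config()
    run_all(cfg, resume=True, stages=("simulate",))
    counts = io.read_counts(WORKDIR / "counts.tsv", WORKDIR / "samples.tsv")
    truth = io.read_json(WORKDIR / "truth.json")
    labels = pd.Series(truth["gene_module_labels"])
    rows = [
        ("genes_total", counts.values.shape[0]),
        ("samples", counts.values.shape[1]),
        ("subjects_control", (counts.samples.group == "control").sum() // 2),
        ("subjects_asthma", (counts.samples.group == "asthma").sum() // 2),
        ("planted_modules", labels[labels != "unassigned"].nunique()),
        ("module_genes", int((labels != "unassigned").sum())),
        ("background_genes", int((labels == "unassigned").sum())),
        ("tfs", len(truth["tf_cluster_labels"])),
        ("dmrs", len(truth["dmr_motif_positions"])),
        ("median_library_size", int(counts.values.sum(axis=0).median())),
    ]
    out = pd.DataFrame(rows, columns=["quantity", "value"])
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "01_study_summary.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    print(f"\nstudy files in {WORKDIR}/, summary in results/01_study_summary.tsv")


if __name__ == "__main__":
    main()
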