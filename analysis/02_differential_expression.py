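"""Normalize counts and select the stimulation-perturbed gene set.

Runs median-of-ratios normalization and the paired TT-vs-NS test per
group, then takes the union of genes at q < 0.05. Summary to
results/02_de_summary.tsv.
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
    run_all(cfg, resume=True, stages=("simulate", "expression", "de"))
    de = {g: pd.read_csv(WORKDIR / f"de_{g}.tsv", sep="\t", index_col=0)
          for g in ("control", "asthma")}
    perturbed = (WORKDIR / "perturbed_genes.txt").read_text().split()
    truth = io.read_json(WORKDIR / "truth.json")
    labels = pd.Series(truth["gene_module_labels"])
    planted = set(labels.index[labels != "unassigned"])
    rows = [
        ("sig_control_q05", int((de["control"].q < 0.05).sum())),
        ("sig_asthma_q05", int((de["asthma"].q < 0.05).sum())),
        ("perturbed_union", len(perturbed)),
        ("perturbed_that_are_planted_module_genes",
         sum(g in planted for g in perturbed)),
        ("background_false_positives",
         sum(g in labels.index and g not in planted for g in perturbed)),
    ]
    out = pd.DataFrame(rows, columns=["quantity", "value"])
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "02_de_summary.tsv", sep="\t", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
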