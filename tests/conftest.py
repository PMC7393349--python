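"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from asthmanet.config import SimulationConfig
from asthmanet import simulate as sim_mod


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        n_genes=120, n_background_genes=60, n_tfs=12, n_modules=4,
        n_subjects_control=10, n_subjects_case=8, targets_per_tf=8,
        n_dmrs=4, dmr_tfs_per_community=6, seed=101)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    counts, truth = sim_mod.simulate_counts(small_cfg)
    return counts, truth


@pytest.fixture(scope="session")
def small_sequences(small_cfg, small_study):
    _, truth = small_study
    return sim_mod.simulate_motifs_and_sequences(small_cfg, truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    genes = [f"g{i}" for i in range(4)]
    samples = ["s1_NS", "s1_TT", "s2_NS", "s2_TT"]
    rng = np.random.default_rng(5)
    values = pd.DataFrame(rng.integers(10, 200, size=(4, 4)),
                          index=genes, columns=samples)
    meta = pd.DataFrame(
        {"subject": ["s1", "s1", "s2", "s2"],
         "group": ["control"] * 4,
         "condition": ["NS", "TT", "NS", "TT"]},
        index=pd.Index(samples, name="sample"))
    return values, meta
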