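"""Configuration objects for the synthetic study and the pipeline.

Defaults encode the study design the pipeline targets: two groups
(control n=30, asthma n=19), paired unstimulated (NS) and tetanus-toxoid
(TT) stimulated samples per subject, and the published analysis
parameters (soft-threshold power 12, minimum module size 30, merge
height 0.15, promoter window -1000/+200, motif threshold 0.8, 21-bp/5-sd
binding kernel, duplicate-distance 0.1, 10,000 permutations).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field violates its constraints."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study generator.

    Counts are negative-binomial around log-normal gene baselines; gene
    modules are driven by latent factors whose inter-module correlation
    signs differ between groups for ``flip_fraction`` of module pairs.
    Promoters and DMRs carry planted consensus motif occurrences; in
    DMRs the two TF communities occupy binding zones offset by
    ``cluster_separation`` base pairs.
    """

    n_genes: int = 5000
    n_tfs: int = 20
    n_modules: int = 4
    n_subjects_control: int = 30
    n_subjects_case: int = 19
    nb_dispersion: float = 10.0
    module_factor_sd: float = 1.5
    flip_fraction: float = 0.5
    motif_length: int = 9
    promoter_length: int = 1200
    n_dmrs: int = 10
    dmr_length: int = 500
    cluster_separation: int = 250
    seed: int = 0

    # count-model details (log2 scale)
    n_background_genes: int = 10000
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    subject_sd: float = 0.5
    subject_factor_persistence: float = 0.6
    tt_effect_log2: float = 1.0
    module_corr: float = 0.35

    # motif/target geometry
    targets_per_tf: int = 15
    dmr_tfs_per_community: int = 10
    dmr_hits_per_tf: int = 2
    dmr_position_sd: float = 15.0

    # planted regulatory-shift geometry (constructed case/control networks)
    shift_delta: float = 1.0
    shift_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        counts = (
            "n_genes", "n_tfs", "n_modules", "n_subjects_control",
            "n_subjects_case", "motif_length", "promoter_length",
            "n_dmrs", "dmr_length", "targets_per_tf",
            "dmr_tfs_per_community", "dmr_hits_per_tf",
        )
        for name in counts:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        positives = (
            "nb_dispersion", "module_factor_sd", "baseline_log2_sd",
            "dmr_position_sd",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("flip_fraction", "subject_factor_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_background_genes < 0:
            raise ConfigError("n_background_genes must be >= 0")
        if self.promoter_length < self.motif_length:
            raise ConfigError("promoter_length must be >= motif_length")
        if self.motif_length > self.dmr_length:
            raise ConfigError("motif_length must not exceed dmr_length")
        if self.cluster_separation < 0:
            raise ConfigError("cluster_separation must be >= 0")
        if self.n_tfs < 2:
            raise ConfigError("n_tfs must be >= 2 (two TF communities)")
        if self.n_modules < 2:
            raise ConfigError("n_modules must be >= 2")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    Analysis parameter defaults equal the published values wherever the
    study states one; PANDA hyperparameters default to the algorithm's
    published defaults (the study prints none).
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: Path = Path("pipeline_out")

    q_threshold: float = 0.05
    beta: int = 12
    min_module_size: int = 30
    merge_height: float = 0.15
    motif_threshold: float = 0.8
    promoter_upstream: int = 1000
    promoter_downstream: int = 200
    panda_alpha: float = 0.1
    panda_tol: float = 1e-3
    panda_max_iter: int = 200
    k_min: int = 2
    k_max: int = 10
    gaussian_window: int = 21
    gaussian_sd: float = 5.0
    dup_threshold: float = 0.1
    n_perm: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not 0.0 <= self.q_threshold <= 1.0:
            raise ConfigError("q_threshold must lie in [0, 1]")
        if self.beta < 1:
            raise ConfigError("beta must be >= 1")
        if not 0.0 < self.panda_alpha <= 1.0:
            raise ConfigError("panda_alpha must lie in (0, 1]")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigError("cluster range must satisfy 2 <= k_min <= k_max")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)
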