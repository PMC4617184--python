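"""Pipeline run configuration with YAML round-trip.

Defaults equal the published analysis settings: low-count threshold 5,
4 removed expression PCs, 1-Mb cis window, SNP QC at call rate > 0.95 /
MAF > 0.05 / HWE P > 1e-4, 10 permutations at FDR < 0.05, BH FDR < 0.05
for DE, scale-free target R^2 0.90, minimum module size 25, MTR
selection |r| > 0.5, kME retention 0.6 and hub rules 0.8/0.6.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # preprocessing
    low_count_threshold: int = 5
    de_filter_mode: str = "total"
    eqtl_filter_mode: str = "any_sample"
    voom_weights: bool = True
    de_sex_regression: bool = False  # sex handled inside the DE model
    n_pcs_removed: int = 4
    protect_genetic_pcs: bool = True
    # DE
    de_fdr: float = 0.05
    de_prior_proportion: float = 0.01
    # eQTL
    cis_window_bp: int = 1_000_000
    call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    n_permutations: int = 10
    eqtl_fdr: float = 0.05
    fdr_scope: str = "separate"
    eqtl_mode: str = "both"
    # network
    target_r2: float = 0.90
    candidate_betas: list[int] = field(default_factory=lambda: list(range(1, 21)))
    signed_network: bool = False
    min_module_size: int = 25
    cut_quantile: float = 0.99
    mtr_threshold: float = 0.5
    mtr_alpha: float = 0.05
    kme_own_min: float = 0.6
    kme_other_max: float = 0.6
    hub_kme_min: float = 0.8
    hub_trait_min: float = 0.6
    # integration
    coexpr_edge_threshold: float = 0.1
    # general
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        for name, lo, hi in [
            ("de_fdr", 0, 1),
            ("eqtl_fdr", 0, 1),
            ("call_rate_min", 0, 1),
            ("maf_min", 0, 0.5),
            ("hwe_p_min", 0, 1),
            ("target_r2", 0, 1),
            ("mtr_threshold", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_permutations < 1 or self.cis_window_bp <= 0:
            raise ValueError("n_permutations and cis_window_bp must be positive")
        self.simulation.validate()

    def to_yaml(self, path) -> Path:
        path = Path(path)
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulation", {})
        if isinstance(sim.get("de_effect_range"), list):
            sim["de_effect_range"] = tuple(sim["de_effect_range"])
        if isinstance(sim.get("libsize_range"), list):
            sim["libsize_range"] = tuple(sim["libsize_range"])
        if isinstance(sim.get("founder_alt_freqs"), list):
            sim["founder_alt_freqs"] = tuple(sim["founder_alt_freqs"])
        cfg = cls(**data, simulation=SimulationConfig(**sim))
        cfg.validate()
        return cfg
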