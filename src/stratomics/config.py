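"""Per-stage analysis configuration with study defaults.

Defaults mirror the published analysis settings: SNF (K=30, alpha=0.7, T=20,
candidate clusters 2..10, variance filter 0.2); shadow-feature selection
(1000 iterations of 1000-feature subsets, 70% vote); Bayesian-network
consensus (150 restarts, 1000 refinement perturbations, max 5 parents);
consensus association network (1000 iterations of 400 features per layer,
within-iteration FDR<1e-6, 90% vote, final FDR<5e-5, communities >30); flux
filtering (1e-7 activity threshold, 250 display cut).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SNFConfig:
    K: int = 30
    alpha: float = 0.7
    T: int = 20
    cluster_range: tuple[int, int] = (2, 10)
    variance_threshold: float = 0.2
    n_clusters: int | None = None   # fix C instead of using the eigengap optimum

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.T < 1:
            raise ValueError("alpha must be > 0 and T >= 1")


@dataclass
class SelectionConfig:
    n_iter: int = 1000
    subset_size: int = 1000
    vote: float = 0.70
    min_support: int = 20
    shadow_rounds: int = 20
    n_trees: int = 25

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 < self.vote <= 1:
            raise ValueError("vote must be in (0, 1]")


@dataclass
class BNConfig:
    n_starts: int = 150
    refine_iters: int = 1000
    max_parents: int = 5

    def __post_init__(self) -> None:
        if self.n_starts < 1 or self.refine_iters < 0:
            raise ValueError("n_starts >= 1 and refine_iters >= 0 required")


@dataclass
class NetworkConfig:
    n_iter: int = 1000
    per_layer: int = 400
    fdr_within: float = 1e-6
    vote: float = 0.90
    final_fdr: float = 5e-5
    min_community: int = 30

    def __post_init__(self) -> None:
        for frac in (self.fdr_within, self.vote, self.final_fdr):
            if not 0 < frac <= 1:
                raise ValueError("fractional thresholds must be in (0, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class FluxConfig:
    flux_eps: float = 1e-7
    display_cut: float = 250.0


@dataclass
class DPAConfig:
    model: int = 2          # 1: HC vs PWH; 2: between clusters; 3: clusters + covariates
    covariates: list[str] = field(default_factory=list)
    fdr: float = 0.05
    enrich_fdr: float = 0.2


@dataclass
class AnalysisConfig:
    snf: SNFConfig = field(default_factory=SNFConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    bn: BNConfig = field(default_factory=BNConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    flux: FluxConfig = field(default_factory=FluxConfig)
    dpa: DPAConfig = field(default_factory=DPAConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {}
        for name, sub in (("snf", SNFConfig), ("selection", SelectionConfig),
                          ("bn", BNConfig), ("network", NetworkConfig),
                          ("flux", FluxConfig), ("dpa", DPAConfig)):
            if name in d:
                block = dict(d[name])
                if name == "snf" and "cluster_range" in block:
                    block["cluster_range"] = tuple(block["cluster_range"])
                kwargs[name] = sub(**block)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
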