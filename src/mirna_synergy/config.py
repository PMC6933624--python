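"""Run configuration: every tunable of the pipeline in one validated record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline tunables.

    Significance levels are raw (no multiple-testing correction is applied at
    selection or co-expression, and that choice is recorded in the run report).
    """

    alpha_pc: float = 0.05          # CI-test level for CPDAG estimation
    alpha_cox: float = 0.05         # univariate Cox Wald-test level
    alpha_corr: float = 0.05        # co-expression Pearson test level
    alpha_enrich: float = 0.05      # module enrichment flag level
    missing_threshold: float = 0.3  # max tolerated missing fraction per entity
    knn_k: int = 10                 # neighbours for imputation
    subset_cap: int = 10            # exhaustive miRNA-subset search up to this |A|
    module_exhaustive_cap: int = 16  # exhaustive (C*,D*) search when r+l <= cap
    equivalence_cap: int = 256      # max DAGs enumerated per equivalence class
    random_model: str = "rewire"    # "rewire" | "duplication"
    n_random: int = 100             # random baseline instances
    hub_fraction: float = 0.10      # top-degree fraction called hubs
    seed: int = 0
    scope: str = "local"            # CPDAG per target ("local") or over all genes
    use_abs_delta: bool = False     # maximise |delta| instead of signed delta
    module_objective: str = "sum"   # "sum" | "min" over per-mRNA delta
    min_module_mirnas: int = 2
    min_module_mrnas: int = 2

    def __post_init__(self) -> None:
        for name in ("alpha_pc", "alpha_cox", "alpha_corr", "alpha_enrich"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not (0.0 <= self.missing_threshold <= 1.0):
            raise ValueError("missing_threshold must be in [0,1]")
        for name in ("knn_k", "subset_cap", "equivalence_cap", "n_random",
                     "module_exhaustive_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.hub_fraction <= 1.0):
            raise ValueError("hub_fraction must be in (0,1]")
        if self.scope not in ("local", "global"):
            raise ValueError("scope must be 'local' or 'global'")
        if self.random_model not in ("rewire", "duplication"):
            raise ValueError("random_model must be 'rewire' or 'duplication'")
        if self.module_objective not in ("sum", "min"):
            raise ValueError("module_objective must be 'sum' or 'min'")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
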