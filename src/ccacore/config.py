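"""Run configuration: validated thresholds, clustering/classifier/survival options.

A RunConfig is a pydantic model: every stochastic stage gets an explicit seed
derived from the master seed by fixed offsets, and out-of-range thresholds are
rejected before any compute.  Configs round-trip through YAML.
"""

from __future__ import annotations

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["Thresholds", "ClusterParams", "ClassifierParams", "SurvivalParams", "RunConfig"]

# fixed offsets so each stochastic stage has its own reproducible stream
SEED_OFFSETS = {"simulate": 0, "purify": 1, "cluster": 2, "classify": 3, "nmf": 4}


class Thresholds(BaseModel):
    ntp_fdr: float = Field(0.1, ge=0.0, le=1.0)
    contamination: float = Field(0.25, ge=0.0, le=1.0)
    de_adj_p: float = Field(0.01, gt=0.0, le=1.0)
    de_abs_fc: float = Field(2.0, ge=1.0)
    confident_call_fdr: float = Field(0.05, gt=0.0, le=1.0)


class ClusterParams(BaseModel):
    k_min: int = Field(2, ge=2)
    k_max: int = Field(5, ge=2)
    reps: int = Field(1000, ge=10)
    subsample_frac: float = Field(0.8, gt=0.0, le=1.0)
    n_features: int = Field(2000, ge=10)
    inner: str = "hierarchical"

    @field_validator("k_max")
    @classmethod
    def _k_order(cls, v, info):
        if "k_min" in info.data and v < info.data["k_min"]:
            raise ValueError("k_max must be >= k_min")
        return v


class ClassifierParams(BaseModel):
    n_genes_c1: int = Field(20, ge=1)
    n_genes_c2: int = Field(10, ge=1)
    sigma_floor: float = Field(0.2, ge=0.0)
    n_perm: int = Field(1000, ge=10)
    sig_max_c1: int = Field(25, ge=1)
    sig_max_c2: int = Field(12, ge=1)


class SurvivalParams(BaseModel):
    roc_years: list[int] = Field(default_factory=lambda: [1, 2, 3, 4])
    nri_horizon_days: float = Field(730.0, gt=0.0)


class RunConfig(BaseModel):
    seed: int = 0
    thresholds: Thresholds = Field(default_factory=Thresholds)
    cluster: ClusterParams = Field(default_factory=ClusterParams)
    classifier: ClassifierParams = Field(default_factory=ClassifierParams)
    survival: SurvivalParams = Field(default_factory=SurvivalParams)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 7919 + SEED_OFFSETS[stage] + 1) % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
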