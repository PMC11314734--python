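"""Pipeline configuration: one validated object covering every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features import STANDARD_GRAVITY
from .io import IngestConfig
from .ml import ModelSpec, SplitConfig
from .synthetic import DEFAULT_NOISE_CV


@dataclass(frozen=True)
class PipelineConfig:
    """Validated settings for the end-to-end pipeline.

    Everything is checked on construction so a bad value fails before
    any stage runs.
    """

    ingest: IngestConfig = field(default_factory=IngestConfig)
    g: float = STANDARD_GRAVITY
    pct_reference: str = "post_threshold"  # or "whole_trial"
    t_test_equal_var: bool = False  # False = Welch
    corr_method: str = "pearson"  # or "spearman"
    ml_models: tuple[ModelSpec, ...] = (
        ModelSpec("knn", k=5), ModelSpec("knn", k=10),
        ModelSpec("svm"), ModelSpec("rf"),
    )
    ml_targets: tuple[str, ...] = ("age", "sex")
    ml_split: SplitConfig = field(default_factory=SplitConfig)
    ml_cv_folds: tuple[int, ...] = (3, 5)
    ml_standardize: bool = True
    synthetic_noise_cv: float = DEFAULT_NOISE_CV
    synthetic_shape: str = "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("g must be positive")
        if self.pct_reference not in ("post_threshold", "whole_trial"):
            raise ValueError(f"unknown pct_reference {self.pct_reference!r}")
        if self.corr_method not in ("pearson", "spearman"):
            raise ValueError(f"unknown corr_method {self.corr_method!r}")
        if self.synthetic_shape not in ("exponential", "logistic"):
            raise ValueError(f"unknown synthetic_shape {self.synthetic_shape!r}")
        for k in self.ml_cv_folds:
            if k not in (3, 5):
                raise ValueError("ml_cv_folds entries must be 3 or 5")
        for t in self.ml_targets:
            if t not in ("age", "sex"):
                raise ValueError(f"unknown ml target {t!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "ingest" in raw and isinstance(raw["ingest"], dict):
            raw["ingest"] = IngestConfig(**raw["ingest"])
        if "ml_split" in raw and isinstance(raw["ml_split"], dict):
            raw["ml_split"] = SplitConfig(**raw["ml_split"])
        if "ml_models" in raw:
            raw["ml_models"] = tuple(
                ModelSpec(**m) if isinstance(m, dict) else m
                for m in raw["ml_models"]
            )
        for key in ("ml_targets", "ml_cv_folds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        """Short stable hash identifying the configuration."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header_comment(self) -> str:
        return f"config_sha={self.digest()} seed={self.seed}"
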