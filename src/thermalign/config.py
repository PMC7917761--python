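"""Training configuration with the study's default hyperparameters."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

from .errors import ConfigError


@dataclass
class TrainConfig:
    """Hyperparameters for cascade training.

    Defaults follow the fixed settings of the study protocol: T=10 cascade
    stages, tree depth F=4, K=500 boosted trees per stage, P=400 candidate
    probe pixels per stage, with 400 random split candidates per tree node.
    """

    T: int = 10  # cascade stages
    K: int = 500  # boosted trees per stage
    F: int = 4  # tree depth
    P: int = 400  # probe pixels per stage pool
    n_candidates: int = 400  # random (u, v, theta) candidates per split node
    shrinkage: float = 0.1  # gradient-boosting learning rate (nu)
    spread: float = 0.15  # probe offset half-width in mean-shape units
    lambda_prior: float = 0.0  # closeness prior exp(-lambda * |u - v|) on pairs
    seed: int = 0
    oversample_inits: int = 1  # extra jittered initializations per image
    min_samples_leaf: int = 1
    normalization: str = "minmax"  # "minmax" | "fixed"
    fixed_range: tuple = (20.0, 40.0)

    def validate(self) -> "TrainConfig":
        if self.T < 1:
            raise ConfigError(f"T must be >= 1, got {self.T}")
        if self.K < 1:
            raise ConfigError(f"K must be >= 1, got {self.K}")
        if self.F < 1:
            raise ConfigError(f"tree depth F must be >= 1, got {self.F}")
        if self.P < 2:
            raise ConfigError(f"P must be >= 2, got {self.P}")
        if self.n_candidates < 1:
            raise ConfigError(f"n_candidates must be >= 1, got {self.n_candidates}")
        if not (0 < self.shrinkage <= 1):
            raise ConfigError(f"shrinkage must be in (0, 1], got {self.shrinkage}")
        if not self.spread > 0:
            raise ConfigError(f"spread must be positive, got {self.spread}")
        if self.lambda_prior < 0:
            raise ConfigError(f"lambda_prior must be >= 0, got {self.lambda_prior}")
        if self.oversample_inits < 1:
            raise ConfigError(f"oversample_inits must be >= 1, got {self.oversample_inits}")
        if self.min_samples_leaf < 1:
            raise ConfigError(f"min_samples_leaf must be >= 1, got {self.min_samples_leaf}")
        if self.normalization not in ("minmax", "fixed"):
            raise ConfigError(f"unknown normalization mode {self.normalization!r}")
        if len(self.fixed_range) != 2 or not self.fixed_range[0] < self.fixed_range[1]:
            raise ConfigError(f"fixed_range must be (lo, hi) with lo < hi, got {self.fixed_range}")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.fixed_range, list):
            cfg.fixed_range = tuple(cfg.fixed_range)
        return cfg.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_range"] = list(self.fixed_range)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, written into output provenance."""
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
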