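"""Pipeline configuration: validated constants and YAML loading."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Every tunable of the full pipeline, with the study's defaults.

    The fixed analysis constants are the study's: exclusion thresholds
    0.30 / 0.80 / 0.60 / 0.60, a quota of 60 respondents per cue per
    period, walk decay alpha = 0.75, top-20 nearest neighbors, 1000
    matched permutation pairs within a +-0.05 cosine tolerance.
    """

    # paths
    data_path: str | None = None
    lexicon_path: str | None = None
    variant_map_path: str | None = None
    registry_path: str | None = None
    anchors_path: str | None = None
    output_dir: str = "lexidrift_out"
    data_dialect: str = "auto"  # auto | wide | long

    # preprocessing
    sentence_frac: float = 0.30
    unique_frac: float = 0.80
    lexicon_frac: float = 0.60
    unknown_frac: float = 0.60
    quota: int = 60
    positions: tuple[str, ...] = ("R1", "R2", "R3")

    # drift
    pseudocount: float = 0.5

    # semantic space
    alpha: float = 0.75
    k_neighbors: int = 20
    ppmi_marginal: str = "uniform"

    # sense shift
    n_perm: int = 1000
    tol: float = 0.05

    seed: int = 0

    def validate(self) -> None:
        for name in ("sentence_frac", "unique_frac", "lexicon_frac",
                     "unknown_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.quota < 0:
            raise ConfigurationError("quota must be non-negative")
        if self.data_dialect not in ("auto", "wide", "long"):
            raise ConfigurationError(
                f"data_dialect must be auto, wide or long, "
                f"got {self.data_dialect!r}"
            )
        if not 0.0 <= self.alpha < 1.0:
            raise ConfigurationError("alpha must be in [0, 1)")
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be positive")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be positive")
        if self.tol < 0:
            raise ConfigurationError("tol must be non-negative")
        if self.pseudocount < 0:
            raise ConfigurationError("pseudocount must be non-negative")
        bad = set(self.positions) - {"R1", "R2", "R3"}
        if bad or not self.positions:
            raise ConfigurationError(
                f"positions must be a non-empty subset of R1-R3, got "
                f"{self.positions}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a YAML key-value document; unknown keys are rejected,
        keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        if "positions" in raw and raw["positions"] is not None:
            p = raw["positions"]
            raw["positions"] = tuple(p.split(",")) if isinstance(p, str) else tuple(p)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["positions"] = list(self.positions)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, for the run manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
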