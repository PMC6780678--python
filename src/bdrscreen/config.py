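"""Pipeline configuration: thresholds, covariate lists, inference options.

Serialized as YAML.  Simulation configs are loaded into
:class:`bdrscreen.simulate.SimConfig` from the same file format.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import InvalidConfigError
from .simulate import LcmsSpec, SimConfig, VisitSpec

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and options shared across pipeline stages."""

    snr_min: float = 10.0
    max_missing: float = 0.10
    cv_max: float = 0.25
    alpha: float = 0.05
    replication_nominal: float = 0.10
    longitudinal_covariates: tuple[str, ...] = ("race", "sex", "clinic", "treatment")
    cross_sectional_covariates: tuple[str, ...] = ("race", "sex")
    use_t: bool = False
    reml: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("max_missing", "cv_max", "alpha", "replication_nominal"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.alpha >= self.replication_nominal:
            logger.warning(
                "alpha (%g) >= replication_nominal (%g); tier 'nominal' will be empty",
                self.alpha, self.replication_nominal,
            )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise InvalidConfigError(f"unknown pipeline config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def load_sim_config(path: str | Path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "visit_spec" in data:
        data["visit_spec"] = tuple(VisitSpec(**v) for v in data["visit_spec"])
    if "visit_pattern" in data:
        data["visit_pattern"] = tuple(data["visit_pattern"])
    if "lcms" in data:
        data["lcms"] = LcmsSpec(**data["lcms"])
    known = {f.name for f in fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise InvalidConfigError(f"unknown simulation config key(s): {sorted(unknown)}")
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg


def config_hash(cfg) -> str:
    """Stable short hash of a config dataclass, for run logs."""
    payload = yaml.safe_dump(asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
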