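"""Pipeline configuration: typed defaults, YAML/JSON loading, validation.

The defaults reproduce the study constants: MRMR top-50, univariate Cox
concordance threshold 0.53, 100 runs at an 85% training subsample, 15%
stratified holdout, landmark horizons of 18 months (TTR) and 36 months
(DSS), and 2,000 bootstrap iterations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .aggregation import STRATEGIES
from .errors import ConfigurationError

__all__ = ["PipelineConfig", "validate_config", "load_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated end-to-end pipeline settings (all stages)."""

    # paths
    input_dir: str | None = None
    output_dir: str = "crlmrad_output"
    # synthetic cohort (used when no input tables are given)
    n_patients: int = 300
    n_features: int = 60
    n_informative: int = 3
    # preprocessing
    clip_lo_hu: float = -100.0
    clip_hi_hu: float = 200.0
    bin_width_hu: float = 25.0
    crop_margin_mm: float = 1.0
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    # aggregation
    strategies: tuple[str, ...] = STRATEGIES
    # selection cascade
    mrmr_k: int = 50
    cox_threshold: float = 0.53
    n_runs: int = 100
    subsample: float = 0.85
    consensus_fraction: float = 0.5
    # models
    models: tuple[str, ...] = ("rsf", "deepsurv")
    rsf_trees: int = 200
    rsf_min_leaf: int = 5
    neural: dict = field(default_factory=dict)
    # evaluation
    holdout_fraction: float = 0.15
    horizon_ttr_months: float = 18.0
    horizon_dss_months: float = 36.0
    n_boot: int = 2000
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("n_patients", self.n_patients >= 2, ">= 2"),
            ("n_features", self.n_features >= 1, ">= 1"),
            ("n_informative", 0 <= self.n_informative <= self.n_features,
             "in [0, n_features]"),
            ("clip window", self.clip_lo_hu < self.clip_hi_hu, "clip_lo < clip_hi"),
            ("bin_width_hu", self.bin_width_hu > 0, "> 0"),
            ("mrmr_k", self.mrmr_k >= 1, ">= 1"),
            ("cox_threshold", 0.0 <= self.cox_threshold <= 1.0, "in [0, 1]"),
            ("n_runs", self.n_runs >= 1, ">= 1"),
            ("subsample", 0.0 < self.subsample <= 1.0, "in (0, 1]"),
            ("consensus_fraction", 0.0 <= self.consensus_fraction <= 1.0, "in [0, 1]"),
            ("holdout_fraction", 0.0 < self.holdout_fraction < 1.0, "in (0, 1)"),
            ("horizon_ttr_months", self.horizon_ttr_months > 0, "> 0"),
            ("horizon_dss_months", self.horizon_dss_months > 0, "> 0"),
            ("n_boot", self.n_boot >= 1, ">= 1"),
            ("rsf_trees", self.rsf_trees >= 1, ">= 1"),
            ("rsf_min_leaf", self.rsf_min_leaf >= 1, ">= 1"),
        ]
        for name, ok, domain in checks:
            if not ok:
                raise ConfigurationError(f"{name}: value out of domain ({domain})")
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ConfigurationError(
                    f"strategies: unknown strategy {s!r}; valid: {STRATEGIES}"
                )
        for m in self.models:
            if m not in ("rsf", "deepsurv"):
                raise ConfigurationError(f"models: unknown model {m!r}")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


_TUPLE_FIELDS = {"log_sigmas_mm", "strategies", "models"}


def validate_config(raw: dict | None) -> PipelineConfig:
    """Build a validated PipelineConfig from a raw mapping.

    An empty/None document yields the all-defaults configuration.  Unknown
    keys and out-of-domain values raise :class:`ConfigurationError` naming
    the field.
    """
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {unknown}")
    for key in _TUPLE_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML or JSON configuration document."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigurationError("configuration document must be a mapping")
    return validate_config(raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of the configuration."""
    canon = json.dumps(config.asdict(), sort_keys=True, default=list)
    return hashlib.sha256(canon.encode()).hexdigest()
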