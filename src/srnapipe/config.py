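"""Run configuration: YAML-backed, strictly validated.

Defaults mirror the analysis thresholds used throughout the package:
alpha 0.05, |log2FC| >= 1.0, zero-adjustment 0.01, 18-30 nt inserts,
18-25 nt miRNA matching with <= 2 mismatches, target-score cutoff 4.0.
Unknown keys are rejected and every violated invariant is reported with
its field name.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .annotate import DEFAULT_PRIORITY
from .errors import ConfigError
from .preprocess import CleanParams
from .synthdata import DEFAULT_ADAPTER, DEFAULT_COMPOSITION
from .targets import ScoringScheme


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "srnapipe_out"
    depth: int = 50000

    adapter: str = DEFAULT_ADAPTER
    min_len: int = 18
    max_len: int = 30
    max_n: int = 0
    min_mean_quality: float = 20.0
    min_adapter_overlap: int = 6

    priority: list[str] = field(default_factory=lambda: list(DEFAULT_PRIORITY))
    max_mismatch: int = 2

    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    zero_adjust: float = 0.01
    exclusion_mode: str = "both"
    alternative: str = "two-sided"

    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    gap_penalty: float = 1.0
    core_start: int = 2
    core_end: int = 13
    max_target_score: float = 4.0

    race_n_clones: int = 1000
    race_canonical_fraction: float = 0.8
    qpcr_noise_sd: float = 0.25

    def clean_params(self) -> CleanParams:
        return CleanParams(
            adapter=self.adapter,
            min_len=self.min_len,
            max_len=self.max_len,
            max_n=self.max_n,
            min_mean_quality=self.min_mean_quality,
            min_adapter_overlap=self.min_adapter_overlap,
        )

    def scoring_scheme(self) -> ScoringScheme:
        return ScoringScheme(
            mismatch=self.mismatch_penalty,
            wobble=self.wobble_penalty,
            gap=self.gap_penalty,
            core_start=self.core_start,
            core_end=self.core_end,
            max_score=self.max_target_score,
        )

    def validate(self) -> None:
        errors = []
        if self.seed < 0:
            errors.append("seed: must be >= 0")
        if self.depth < 1:
            errors.append("depth: must be >= 1")
        if not self.adapter:
            errors.append("adapter: must be non-empty")
        if self.min_len > self.max_len:
            errors.append("min_len/max_len: min_len must be <= max_len")
        if min(self.min_len, self.max_n, self.min_adapter_overlap) < 0:
            errors.append("min_len/max_n/min_adapter_overlap: must be nonnegative")
        if self.max_mismatch < 0:
            errors.append("max_mismatch: must be >= 0")
        if not 0 <= self.alpha <= 1:
            errors.append("alpha: must be in [0, 1]")
        if self.min_abs_log2fc < 0:
            errors.append("min_abs_log2fc: must be >= 0")
        if self.zero_adjust <= 0:
            errors.append("zero_adjust: must be > 0")
        if self.exclusion_mode not in ("both", "either"):
            errors.append("exclusion_mode: must be 'both' or 'either'")
        if self.alternative not in ("two-sided", "greater", "less"):
            errors.append("alternative: must be 'two-sided', 'greater' or 'less'")
        if min(self.mismatch_penalty, self.wobble_penalty, self.gap_penalty) < 0:
            errors.append("penalties: must be nonnegative")
        if self.core_start > self.core_end:
            errors.append("core_start/core_end: core_start must be <= core_end")
        if self.race_n_clones < 1:
            errors.append("race_n_clones: must be >= 1")
        if not 0 <= self.race_canonical_fraction <= 1:
            errors.append("race_canonical_fraction: must be in [0, 1]")
        if self.qpcr_noise_sd < 0:
            errors.append("qpcr_noise_sd: must be >= 0")
        if errors:
            raise ConfigError("; ".join(errors))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def validate_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
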