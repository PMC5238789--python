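"""Pipeline configuration.

Every numeric threshold used by the pipeline lives in :class:`PipelineConfig`
so a run is fully described by one config file plus one seed.  The defaults
encode the parameter set the pipeline was designed around: a 16-nt read-length
floor, a two-round mapping strategy (round 1 against a dedicated small-ncRNA
reference with mismatch ratio < 0.05 over the matched length and a 16-nt
minimum match; round 2 end-to-end against the genome with mismatch ratio
< 0.023 over the read length and an 18-nt minimum), a 100-placement multimap
cap, a 400-nt cap on reference ncRNAs, contig assembly requiring at least five
reads overlapping by at least 1 nt, representative-contig clustering at a 95%
read-sharing fraction, and a BH-adjusted significance cutoff of padj < 0.1.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    # read preprocessing
    min_read_len: int = 16
    min_mean_quality: float = 17.0
    adapter: str | None = None
    adapter_min_overlap: int = 3
    adapter_max_err_rate: float = 0.1
    # two-round mapping
    round1_min_match: int = 16
    round2_min_match: int = 18
    round1_mismatch_ratio: float = 0.05  # exclusive bound, denominator = matched length
    round2_mismatch_ratio: float = 0.023  # exclusive bound, denominator = read length
    max_hits: int = 100
    seed_length: int = 10
    # reference construction
    max_ncrna_len: int = 400
    # contig assembly / clustering
    min_contig_reads: int = 5
    contig_overlap: int = 1
    share_frac: float = 0.95
    jaccard_sharing: bool = False
    # differential abundance
    padj_threshold: float = 0.1
    # reproducibility
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive_ints = (
            "min_read_len",
            "adapter_min_overlap",
            "round1_min_match",
            "round2_min_match",
            "max_hits",
            "seed_length",
            "max_ncrna_len",
            "min_contig_reads",
            "contig_overlap",
        )
        for name in positive_ints:
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 1:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        fractions = (
            "round1_mismatch_ratio",
            "round2_mismatch_ratio",
            "adapter_max_err_rate",
            "share_frac",
            "padj_threshold",
        )
        for name in fractions:
            value = getattr(self, name)
            if not (0.0 < float(value) <= 1.0):
                raise ConfigError(f"{name} must lie in (0, 1], got {value!r}")
        if self.min_mean_quality < 0:
            raise ConfigError("min_mean_quality must be non-negative")
        if not isinstance(self.rng_seed, int) or isinstance(self.rng_seed, bool):
            raise ConfigError("rng_seed must be an integer")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a ``key: value`` YAML config, filling missing keys with defaults.

    Unknown keys produce a warning rather than an error so configs can carry
    user bookkeeping fields.  ``None`` or an empty file yields pure defaults.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - message format
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed config file {path}{line}: {exc}") from exc
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    for key in sorted(unknown):
        warnings.warn(f"unknown config key ignored: {key}", stacklevel=2)
    kwargs = {k: v for k, v in data.items() if k in known}
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
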