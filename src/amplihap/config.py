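"""Pipeline configuration: one flat set of validated parameters.

Defaults encode the study conditions the package targets: 2x300 bp
reads, a 250 bp / mean-Q30 read filter, five random subsamples of
10,000 mapped reads, and an inclusive 1% reporting threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import haplo, readprep, simdata, varmap

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    # read preparation
    min_length: int = readprep.DEFAULT_MIN_LENGTH
    min_mean_quality: float = readprep.DEFAULT_MIN_MEAN_QUALITY
    min_overlap: int = readprep.DEFAULT_MIN_OVERLAP
    max_overlap_mismatch_fraction: float = readprep.DEFAULT_MAX_OVERLAP_MISMATCH
    adapters: tuple[str, str] = simdata.DEFAULT_ADAPTERS
    # mapping
    max_divergence: float = varmap.DEFAULT_MAX_DIVERGENCE
    # haplotype calling
    subsample_size: int = haplo.DEFAULT_SUBSAMPLE_SIZE
    n_subsamples: int = haplo.DEFAULT_N_SUBSAMPLES
    threshold: float = haplo.DEFAULT_THRESHOLD
    codominance_margin: float = haplo.DEFAULT_CODOMINANCE_MARGIN
    # simulation
    error_rate: float = simdata.DEFAULT_ERROR_RATE
    indel_error_rate: float = simdata.DEFAULT_INDEL_ERROR_RATE
    read_length: int = 300
    n_pairs: int = 50_000
    # phylogenetics
    bootstrap_replicates: int = 1000
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.min_mean_quality < 0:
            raise ValueError("filter thresholds must be non-negative")
        if not 0 <= self.threshold < 1:
            raise ValueError("threshold must lie in [0, 1)")
        if self.subsample_size < 1 or self.n_subsamples < 1:
            raise ValueError("subsampling parameters must be >= 1")
        object.__setattr__(self, "adapters", tuple(self.adapters))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adapters"] = list(d["adapters"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def replace(self, **overrides) -> "PipelineConfig":
        return dataclasses.replace(self, **overrides)


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a YAML config file (if given) and apply overrides.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "adapters" in data:
        data["adapters"] = tuple(data["adapters"])
    return PipelineConfig(**data)
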