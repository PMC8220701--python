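"""Pipeline configuration: line identities, thresholds and search parameters."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one place.

    Defaults mirror a five-genotype microarray comparison: a wild-type
    reference, a primary mutant, and three activation-tag suppressor lines,
    differential expression at |fold change| >= 1.5 and BH-FDR <= 0.05, and
    a parsimonious path-search sweep over 28 log-spaced edge penalties in
    [0.1, 5] with paths of at most 4 edges and 50 best paths per seed pair.
    """

    reference_line: str = "WS2"
    mutant_line: str = "bri1-5"
    suppressor_lines: tuple[str, ...] = ("brs1-1D", "bri1-1D", "bak1-1D")
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    cost_min: float = 0.1
    cost_max: float = 5.0
    cost_steps: int = 28
    path_length: int = 4
    k_paths: int = 50
    jaccard_min: float = 0.5
    max_edges: int = 500
    stability_resamples: int = 10
    stability_fraction: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.cost_min > 0:
            raise ValueError("cost_min must be > 0")
        if not self.cost_min < self.cost_max:
            raise ValueError("cost_min must be < cost_max")
        if self.cost_steps < 2:
            raise ValueError("cost_steps must be >= 2")
        if self.path_length < 1:
            raise ValueError("path_length must be >= 1")
        if self.k_paths < 1:
            raise ValueError("k_paths must be >= 1")
        if not 0.0 <= self.jaccard_min <= 1.0:
            raise ValueError("jaccard_min must lie in [0, 1]")
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must be > 1 (linear fold change)")
        if not 0 < self.stability_fraction <= 1:
            raise ValueError("stability_fraction must lie in (0, 1]")
        self.suppressor_lines = tuple(self.suppressor_lines)

    @property
    def log_fc_threshold(self) -> float:
        """The fold-change bound on the log2 scale."""
        return math.log2(self.fc_threshold)

    @property
    def non_reference_lines(self) -> tuple[str, ...]:
        return (self.mutant_line, *self.suppressor_lines)

    def penalties(self) -> list[float]:
        """Inclusive log-spaced penalty grid from cost_min to cost_max."""
        lo, hi = math.log(self.cost_min), math.log(self.cost_max)
        n = self.cost_steps
        return [math.exp(lo + (hi - lo) * i / (n - 1)) for i in range(n)]

    def require_three_suppressors(self) -> None:
        if len(self.suppressor_lines) != 3:
            raise ValueError(
                "group classification requires exactly three suppressor lines, "
                f"got {len(self.suppressor_lines)}"
            )

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["suppressor_lines"] = list(self.suppressor_lines)
        return d


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a flat YAML key-value file; keyword overrides win over the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
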