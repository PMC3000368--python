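"""Run configuration: defaults, YAML loading, CLI-override precedence.

Precedence is CLI flag > config file > built-in default.  The built-in
defaults are the published analysis parameters where one exists (1 kb
enrichment windows, p < 1e-3 calls, motif alpha 5e-5, 1 kb merge gap,
200 bp methylation windows, 10 kb TSS span, 20 kb heat-map span).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, Iterable, Mapping

import yaml

logger = logging.getLogger("islandkit")


@dataclass
class Config:
    # windowed enrichment calling
    window_bp: int = 1000
    step_bp: int = 200
    merge_gap_bp: int = 1000
    p_threshold: float = 1e-3
    n_randomizations: int = 10
    read_extension_bp: int = 200
    density_bin_bp: int = 25
    tss_flank_bp: int = 1000
    # motif scanning
    motif_alpha: float = 5e-5
    # CpG island criteria (Gardiner-Garden & Frommer convention)
    island_min_gc: float = 0.50
    island_min_oe: float = 0.60
    island_min_len: int = 200
    island_window_bp: int = 200
    max_n_fraction: float = 0.10
    # element discovery
    element_window_bp: int = 1000
    max_hits_per_window: int = 2
    # methylation composites
    meth_window_bp: int = 200
    meth_span_bp: int = 10000
    # heat-map matrices
    heatmap_span_bp: int = 20000
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "seed":
                continue
            value = getattr(self, f.name)
            if value is None or value <= 0:
                raise ValueError(f"config field {f.name} must be positive, got {value}")

    def replace(self, **overrides: Any) -> "Config":
        """New Config with non-None overrides applied."""
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)

    def as_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "Config":
        """Load a flat key: value YAML file; unknown keys are an error."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        cfg = cls(**data)
        return cfg.replace(**overrides)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def log_run(config: Config, inputs: Iterable[str | Path] = ()) -> None:
    """Log seed, config snapshot and input digests for reproducibility."""
    logger.info("config: %s", config.as_dict())
    logger.info("seed: %d", config.seed)
    for path in inputs:
        logger.info("input %s sha256=%s", path, file_digest(path))
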