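"""Pipeline configuration: defaults, ranges, and flat key-value parsing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the analysis chain.

    Defaults are the published operating point of the procedure: pairwise
    significance 0.05, k = 10 clusters, 3000 bp promoters, conservation
    E < 0.001, MATCH cutoffs 0.85 (matrix) / 0.95 (core), 17 control sets at
    Mann-Whitney p = 0.05.
    """

    alpha: float = 0.05
    de_use_adjusted: bool = True
    k: int = 10
    delta: float = 0.5
    rho: float = 0.5
    min_cluster_size: int = 10  # strict >: a size-10 cluster is excluded
    promoter_length: int = 3000
    evalue_max: float = 0.001
    mss_min: float = 0.85
    css_min: float = 0.95
    restrict_to_conserved: bool = True
    n_control_sets: int = 17
    mw_alpha: float = 0.05
    cluster_seed: int = 10
    control_seed: int = 17
    sim_seed: int = 0
    kmeans_restarts: int = 25

    _RANGES = {
        "alpha": (0.0, 1.0, False),
        "mw_alpha": (0.0, 1.0, False),
        "delta": (0.0, float("inf"), False),
        "rho": (0.0, 1.0, True),
        "mss_min": (0.0, 1.0, True),
        "css_min": (0.0, 1.0, True),
        "evalue_max": (0.0, float("inf"), False),
    }

    def __post_init__(self) -> None:
        for key, (lo, hi, closed) in self._RANGES.items():
            v = getattr(self, key)
            ok = lo <= v <= hi if closed else lo < v <= hi if hi != float("inf") else v > lo
            if not ok:
                bound = f"[{lo}, {hi}]" if closed else f"({lo}, {hi}]"
                raise ValueError(f"config key {key}={v} outside {bound}")
        for key in ("k", "min_cluster_size", "promoter_length", "n_control_sets", "kmeans_restarts"):
            if getattr(self, key) < 1:
                raise ValueError(f"config key {key} must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(raw: Mapping[str, Any] | str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a flat key-value mapping or YAML file.

    Missing keys take the published defaults; unknown keys are rejected;
    out-of-range values raise naming the key and bound.
    """
    if isinstance(raw, (str, Path)):
        text = Path(raw).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**dict(raw))


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
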