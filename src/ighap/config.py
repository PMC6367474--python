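"""Run configuration: documented thresholds, YAML loading, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    """All tunable thresholds with their defaults and domains.

    Defaults follow the standard analysis: deletion-candidate usage
    thresholds 0.001 (V) / 0.005 (D), BH q < 0.01, ε = 0.01, assignment and
    deletion certainty lK = 3, conservative grouping certainty lK = 10,
    pooled-anchor cutoff lK = 12, 1.5% minimum pooled D usage, 30%
    minor-allele anchor screen, 2000-read subject depth, 10-sequence genotype
    support.
    """

    candidate_thresh_v: float = 0.001
    candidate_thresh_d: float = 0.005
    q_cutoff: float = 0.01
    epsilon: float = 0.01
    lk_assign: float = 3.0
    lk_delete: float = 3.0
    lk_group: float = 10.0
    lk_pool: float = 12.0
    min_d_usage: float = 0.015
    minor_fraction: float = 0.30
    min_depth: int = 2000
    min_seqs: int = 10
    seed: int = 1
    priors: str = "uniform"

    _DOMAINS = {
        "candidate_thresh_v": (0.0, 1.0),
        "candidate_thresh_d": (0.0, 1.0),
        "q_cutoff": (0.0, 1.0),
        "epsilon": (0.0, 0.5),
        "lk_assign": (0.0, float("inf")),
        "lk_delete": (0.0, float("inf")),
        "lk_group": (0.0, float("inf")),
        "lk_pool": (0.0, float("inf")),
        "min_d_usage": (0.0, 1.0),
        "minor_fraction": (0.0, 0.5),
        "min_depth": (0, float("inf")),
        "min_seqs": (0, float("inf")),
    }

    def __post_init__(self):
        for name, (lo, hi) in self._DOMAINS.items():
            v = getattr(self, name)
            if not (lo <= v < hi or (hi == float("inf") and v >= lo)):
                raise ValueError(f"{name}={v} outside its domain [{lo}, {hi})")
        if self.priors not in ("uniform", "empirical"):
            raise ValueError("priors must be 'uniform' or 'empirical'")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML config, applying defaults for absent keys; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a YAML mapping")
    known = {f.name for f in fields(RunConfig) if not f.name.startswith("_")}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, val in raw.items():
        want = type(getattr(RunConfig, key, None))
        if want in (int, float) and not isinstance(val, (int, float)):
            raise ValueError(f"config key {key} expects a number, got {val!r}")
    return RunConfig(**raw)
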