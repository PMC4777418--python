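"""Run configuration: thresholds, seeds and layout, loadable from YAML."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

log = logging.getLogger("cisscreen")


@dataclass
class RunConfig:
    """Pipeline thresholds and bookkeeping.

    Percentile thresholds follow the screen's hit definition (Difference at
    its 90th percentile, Survival Index at its 75th); ``lethal_si_cutoff``
    marks knockdowns losing at least 70% viability on their own;
    ``de_alpha`` is the differential-expression shortlist cutoff and
    ``rank_max`` the Gene Score rank filter applied during integration.
    """

    lethal_si_cutoff: float = 30.0
    de_alpha: float = 0.005
    rank_max: int = 2000
    diff_percentile: float = 90.0
    si_percentile: float = 75.0
    layout: str = "paper"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("diff_percentile", "si_percentile"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must be in (0, 100), got {v}")
        if not 0 < self.de_alpha < 1:
            raise ValueError(f"de_alpha must be in (0, 1), got {self.de_alpha}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def log_run(stage: str, cfg: RunConfig) -> None:
    """Emit the one-line provenance record every CLI stage writes."""
    log.info("stage=%s config_hash=%s seed=%d", stage, cfg.hash(), cfg.seed)
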