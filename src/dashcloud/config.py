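"""Run configuration: thresholds, timezone, seed and paths.

Defaults encode the study rules: valid tracked days need >=600 kcal,
recall sets need mean energy in 600-3500 kcal collected at most 14 days
apart, and alpha = 0.05 two-sided.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    targets_path: Optional[str] = None  # None -> packaged defaults
    timezone: str = "America/New_York"
    min_valid_kcal: float = 600.0
    recall_kcal_bounds: tuple[float, float] = (600.0, 3500.0)
    max_recall_gap_days: int = 14
    alpha: float = 0.05
    seed: int = 42
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.min_valid_kcal <= 0:
            raise ValueError("min_valid_kcal must be positive")
        lo, hi = self.recall_kcal_bounds
        if lo <= 0 or hi <= 0:
            raise ValueError("recall kcal bounds must be positive")
        if lo >= hi:
            raise ValueError(f"recall kcal bounds must be ordered, got ({lo}, {hi})")
        if self.max_recall_gap_days <= 0:
            raise ValueError("max_recall_gap_days must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.recall_kcal_bounds = (float(lo), float(hi))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["recall_kcal_bounds"] = list(self.recall_kcal_bounds)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load a YAML/JSON config; absent keys fall back to defaults.

    Unknown keys are an error (listed); the fully-resolved config is echoed
    to the log.
    """
    payload = {}
    if path is not None:
        text = Path(path).read_text()
        payload = (json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "recall_kcal_bounds" in payload:
        payload["recall_kcal_bounds"] = tuple(payload["recall_kcal_bounds"])
    cfg = RunConfig(**payload)
    logger.info("resolved config: %s", cfg.to_dict())
    return cfg
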