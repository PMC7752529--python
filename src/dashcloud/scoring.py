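"""Nutrient-based DASH adherence index (Mellen-style).

Each of nine nutrients earns a credit of 0, 0.5 or 1 against a
calorie-standardized target; credits sum to a 0-9 total, where 9 is full
adherence to the DASH dietary pattern.  Full credit requires meeting the
target itself; half credit requires meeting a less stringent intermediate
threshold.  Boundary ties resolve toward the better credit so the score is
total on all non-negative inputs.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .intake import BASIS, NUTRIENTS, NutrientDensityProfile

#: Token a downstream consumer receives instead of a score for an unscored
#: (untracked or incomplete) day; deliberately distinct from 0.0.
NO_SCORE = None

_VALID_DIRECTIONS = ("min", "max")
_VALID_BASES = ("percent_of_energy", "per_1000_kcal", "per_day")


@dataclass(frozen=True)
class NutrientTargetSpec:
    """One DASH standard: direction, basis, target and half-credit threshold."""

    nutrient: str
    direction: str  # "min" (more is better) | "max" (less is better)
    basis: str
    target: float
    intermediate: float

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENTS:
            raise ValueError(f"unknown nutrient {self.nutrient!r}")
        if self.direction not in _VALID_DIRECTIONS:
            raise ValueError(f"direction must be min|max, got {self.direction!r}")
        if self.basis not in _VALID_BASES:
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.target <= 0:
            raise ValueError(f"{self.nutrient}: target must be > 0")
        if self.direction == "min" and not self.intermediate < self.target:
            raise ValueError(f"{self.nutrient}: min-type needs intermediate < target")
        if self.direction == "max" and not self.intermediate > self.target:
            raise ValueError(f"{self.nutrient}: max-type needs intermediate > target")


class TargetSet:
    """Exactly nine :class:`NutrientTargetSpec`, one per index component."""

    def __init__(self, specs: Iterable[NutrientTargetSpec]):
        specs = list(specs)
        names = [s.nutrient for s in specs]
        if sorted(names) != sorted(NUTRIENTS):
            raise ValueError(
                f"a TargetSet needs exactly the components {set(NUTRIENTS)}, got {names}"
            )
        self._specs = {s.nutrient: s for s in specs}

    def __getitem__(self, nutrient: str) -> NutrientTargetSpec:
        return self._specs[nutrient]

    def __iter__(self):
        return (self._specs[n] for n in NUTRIENTS)

    def __eq__(self, other) -> bool:
        return isinstance(other, TargetSet) and self._specs == other._specs

    @classmethod
    def default(cls) -> "TargetSet":
        """The shipped default standards with default intermediates."""
        text = resources.files("dashcloud").joinpath("data/targets_default.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_mapping(cls, payload: Mapping) -> "TargetSet":
        entries = payload["targets"] if "targets" in payload else payload
        return cls(
            NutrientTargetSpec(
                nutrient=e["nutrient"],
                direction=e["direction"],
                basis=e["basis"],
                target=float(e["target"]),
                intermediate=float(e["intermediate"]),
            )
            for e in entries
        )

    @classmethod
    def load(cls, path: str | Path) -> "TargetSet":
        """Load from a YAML or JSON targets config."""
        text = Path(path).read_text()
        payload = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_mapping(payload)

    def to_mapping(self) -> dict:
        return {
            "targets": [
                {
                    "nutrient": s.nutrient,
                    "direction": s.direction,
                    "basis": s.basis,
                    "target": s.target,
                    "intermediate": s.intermediate,
                }
                for s in self
            ]
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_mapping()
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass(frozen=True)
class DashScore:
    """Per-component credits and their 0-9 total for one day."""

    date: dt.date
    component_credits: Mapping[str, float]
    total: float

    def __post_init__(self) -> None:
        if set(self.component_credits) != set(NUTRIENTS):
            raise ValueError("component_credits must cover all nine components")
        if abs(self.total - sum(self.component_credits.values())) > 1e-12:
            raise ValueError("total does not equal the sum of credits")


def score_component(value: float, spec: NutrientTargetSpec) -> float:
    """Credit a single standardized value: 1, 0.5 or 0 against its standard.

    min-type: 1 if value >= target, 0.5 if intermediate <= value < target,
    else 0.  max-type: 1 if value <= target, 0.5 if target < value <=
    intermediate, else 0.  Boundaries are inclusive toward the better credit.
    """
    if value < 0:
        raise ValueError(f"{spec.nutrient}: standardized value must be >= 0, got {value}")
    if spec.direction == "min":
        if value >= spec.target:
            return 1.0
        if value >= spec.intermediate:
            return 0.5
        return 0.0
    if value <= spec.target:
        return 1.0
    if value <= spec.intermediate:
        return 0.5
    return 0.0


def score_day(
    profile: NutrientDensityProfile,
    targets: TargetSet,
    date: Optional[dt.date] = None,
) -> DashScore:
    """Score one standardized day: nine credits and their sum.

    Credits are exact sums of halves, so no rounding is ever applied to the
    total.
    """
    credits = {spec.nutrient: score_component(profile[spec.nutrient], spec) for spec in targets}
    return DashScore(
        date=date if date is not None else dt.date.min,
        component_credits=credits,
        total=sum(credits.values()),
    )


def mean_score(scores: Sequence[DashScore | float]) -> float:
    """Arithmetic mean of score totals (accepts DashScore objects or totals)."""
    if len(scores) == 0:
        raise ValueError("mean_score of an empty list is undefined")
    totals = [s.total if isinstance(s, DashScore) else float(s) for s in scores]
    return sum(totals) / len(totals)
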