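"""Daily-intake data model and calorie-relative standardization.

The DASH adherence index compares nine nutrients against targets expressed
on calorie-relative bases: percent of energy for the macronutrients
(total fat, saturated fat, protein), density per 1000 kcal for cholesterol,
fiber, magnesium, calcium and potassium, and an absolute daily amount for
sodium.  This module defines the atomic participant-day record, the
standardized profile, and the conversion between them.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

#: The nine index components, in canonical order.
NUTRIENTS = (
    "total_fat",
    "saturated_fat",
    "protein",
    "cholesterol",
    "fiber",
    "magnesium",
    "calcium",
    "potassium",
    "sodium",
)

#: Standardization basis per component.
BASIS = {
    "total_fat": "percent_of_energy",
    "saturated_fat": "percent_of_energy",
    "protein": "percent_of_energy",
    "cholesterol": "per_1000_kcal",
    "fiber": "per_1000_kcal",
    "magnesium": "per_1000_kcal",
    "calcium": "per_1000_kcal",
    "potassium": "per_1000_kcal",
    "sodium": "per_day",
}

#: Atwater energy-conversion factors, kcal per gram.
KCAL_PER_G_FAT = 9.0
KCAL_PER_G_PROTEIN = 4.0

#: Macro-energy plausibility slack: fat+protein energy may exceed reported
#: kcal by this factor before a warning is emitted (never an error).
MACRO_PLAUSIBILITY_FACTOR = 1.25

#: Native units of each raw nutrient field (documentation + CSV headers).
NATIVE_UNITS = {
    "total_fat": "g",
    "saturated_fat": "g",
    "protein": "g",
    "cholesterol": "mg",
    "fiber": "g",
    "magnesium": "mg",
    "calcium": "mg",
    "potassium": "mg",
    "sodium": "mg",
}

INTAKE_CSV_COLUMNS = [
    "participant_id",
    "date",
    "energy_kcal",
    "total_fat_g",
    "saturated_fat_g",
    "protein_g",
    "cholesterol_mg",
    "fiber_g",
    "magnesium_mg",
    "calcium_mg",
    "potassium_mg",
    "sodium_mg",
]

RECALL_CSV_COLUMNS = INTAKE_CSV_COLUMNS + ["recall_date"]


class DegenerateDayError(ValueError):
    """Raised when a day has non-positive energy and cannot be standardized."""


class IncompleteIntakeError(ValueError):
    """Raised when nutrient fields required for scoring are missing."""

    def __init__(self, missing: Iterable[str]):
        self.missing = tuple(missing)
        super().__init__(f"intake record missing nutrient fields: {', '.join(self.missing)}")


@dataclass(frozen=True)
class DailyIntake:
    """One participant-day of energy and the nine DASH nutrients, native units.

    Nutrient fields are optional: commercial food databases frequently lack
    micronutrient values (magnesium and potassium especially), and missing
    amounts are flagged rather than imputed.  Records with any missing
    component are never scored.
    """

    participant_id: str
    date: dt.date
    energy: float  # kcal/day
    total_fat: Optional[float] = None  # g
    saturated_fat: Optional[float] = None  # g
    protein: Optional[float] = None  # g
    cholesterol: Optional[float] = None  # mg
    fiber: Optional[float] = None  # g
    magnesium: Optional[float] = None  # mg
    calcium: Optional[float] = None  # mg
    potassium: Optional[float] = None  # mg
    sodium: Optional[float] = None  # mg

    def __post_init__(self) -> None:
        if self.energy is None or self.energy < 0:
            raise ValueError(f"energy must be >= 0, got {self.energy}")
        for name in NUTRIENTS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        tf, sf = self.total_fat, self.saturated_fat
        if tf is not None and sf is not None and sf > tf:
            raise ValueError(f"saturated_fat ({sf} g) exceeds total_fat ({tf} g)")
        if tf is not None and self.protein is not None and self.energy > 0:
            macro_kcal = KCAL_PER_G_FAT * tf + KCAL_PER_G_PROTEIN * self.protein
            if macro_kcal > self.energy * MACRO_PLAUSIBILITY_FACTOR:
                warnings.warn(
                    f"fat+protein energy ({macro_kcal:.0f} kcal) implausible for "
                    f"reported {self.energy:.0f} kcal on {self.date} "
                    f"({self.participant_id})",
                    stacklevel=2,
                )

    @property
    def complete(self) -> bool:
        """True when all nine nutrient fields are present."""
        return all(getattr(self, n) is not None for n in NUTRIENTS)

    @property
    def missing_fields(self) -> tuple[str, ...]:
        return tuple(n for n in NUTRIENTS if getattr(self, n) is None)


@dataclass(frozen=True)
class NutrientDensityProfile:
    """Calorie-standardized values, one per component on its own basis.

    total_fat / saturated_fat / protein are % of energy; cholesterol, fiber,
    magnesium, calcium and potassium are amount per 1000 kcal; sodium is the
    absolute mg/day amount, exactly as the DASH standards print it.
    """

    total_fat: float
    saturated_fat: float
    protein: float
    cholesterol: float
    fiber: float
    magnesium: float
    calcium: float
    potassium: float
    sodium: float

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in NUTRIENTS}

    def __getitem__(self, nutrient: str) -> float:
        if nutrient not in NUTRIENTS:
            raise KeyError(nutrient)
        return getattr(self, nutrient)


def compute_densities(intake: DailyIntake) -> NutrientDensityProfile:
    """Standardize a complete intake record to the DASH target bases.

    Percent-of-energy uses the Atwater factors (fat 9 kcal/g, protein
    4 kcal/g) against total reported kcal; densities are amount x 1000 /
    energy; sodium passes through as mg/day.

    Raises
    ------
    DegenerateDayError
        If energy is not strictly positive.
    IncompleteIntakeError
        If any nutrient field is missing (names the fields).
    """
    if intake.energy <= 0:
        raise DegenerateDayError(
            f"cannot standardize a day with energy {intake.energy} kcal"
        )
    if not intake.complete:
        raise IncompleteIntakeError(intake.missing_fields)
    e = intake.energy
    return NutrientDensityProfile(
        total_fat=intake.total_fat * KCAL_PER_G_FAT * 100.0 / e,
        saturated_fat=intake.saturated_fat * KCAL_PER_G_FAT * 100.0 / e,
        protein=intake.protein * KCAL_PER_G_PROTEIN * 100.0 / e,
        cholesterol=intake.cholesterol * 1000.0 / e,
        fiber=intake.fiber * 1000.0 / e,
        magnesium=intake.magnesium * 1000.0 / e,
        calcium=intake.calcium * 1000.0 / e,
        potassium=intake.potassium * 1000.0 / e,
        sodium=intake.sodium,
    )


def densities_to_intake(
    profile_values: dict[str, float],
    energy: float,
    participant_id: str,
    date: dt.date,
) -> DailyIntake:
    """Invert :func:`compute_densities`: absolute amounts at a given energy.

    Used by the cohort simulator to emit raw intake records whose
    standardized values reproduce ``profile_values``.
    """
    if energy <= 0:
        raise DegenerateDayError(f"energy must be > 0, got {energy}")
    amounts = {}
    for n in NUTRIENTS:
        v = profile_values[n]
        basis = BASIS[n]
        if basis == "percent_of_energy":
            kcal_per_g = KCAL_PER_G_FAT if "fat" in n else KCAL_PER_G_PROTEIN
            amounts[n] = v / 100.0 * energy / kcal_per_g
        elif basis == "per_1000_kcal":
            amounts[n] = v * energy / 1000.0
        else:  # per_day
            amounts[n] = v
    return DailyIntake(participant_id=participant_id, date=date, energy=energy, **amounts)


def classify_recall_day(recall_date: dt.date | str) -> str:
    """Classify a calendar date as ``weekend`` (Sat/Sun) or ``weekday``."""
    if isinstance(recall_date, str):
        try:
            recall_date = dt.date.fromisoformat(recall_date)
        except ValueError as exc:
            raise ValueError(f"unparseable date: {recall_date!r}") from exc
    if not isinstance(recall_date, dt.date):
        raise TypeError(f"expected a date, got {type(recall_date).__name__}")
    return "weekend" if recall_date.weekday() >= 5 else "weekday"


@dataclass(frozen=True)
class RecallRecord:
    """A 24-hour dietary recall: an intake record tied to its recall date."""

    intake: DailyIntake
    recall_date: dt.date
    timepoint: Optional[str] = None  # baseline | month3, when known

    @property
    def day_class(self) -> str:
        return classify_recall_day(self.recall_date)

    @property
    def energy(self) -> float:
        return self.intake.energy


@dataclass
class ValidationIssue:
    """Per-row report emitted by the CSV readers."""

    line: int
    field: str
    reason: str


def _parse_row(row: pd.Series, line: int, issues: list[ValidationIssue]) -> Optional[DailyIntake]:
    def _num(col: str) -> Optional[float]:
        v = row.get(col)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        try:
            return float(v)
        except (TypeError, ValueError):
            issues.append(ValidationIssue(line, col, f"not a number: {v!r}"))
            return None

    try:
        date = dt.date.fromisoformat(str(row["date"]))
    except ValueError:
        issues.append(ValidationIssue(line, "date", f"not an ISO date: {row['date']!r}"))
        return None
    energy = _num("energy_kcal")
    if energy is None:
        issues.append(ValidationIssue(line, "energy_kcal", "missing energy"))
        return None
    kwargs = {n: _num(f"{n}_{NATIVE_UNITS[n]}") for n in NUTRIENTS}
    try:
        return DailyIntake(
            participant_id=str(row["participant_id"]), date=date, energy=energy, **kwargs
        )
    except ValueError as exc:
        issues.append(ValidationIssue(line, "-", str(exc)))
        return None


def _check_header(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: malformed CSV header; missing columns {missing}, "
            f"found {list(df.columns)}"
        )


def read_intake_csv(path) -> tuple[list[DailyIntake], list[ValidationIssue]]:
    """Read a daily diet-tracking CSV; empty cells are missing values.

    Returns the parsed records plus a validation report (line number, field,
    reason) for every rejected or degraded row; issues are also logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, INTAKE_CSV_COLUMNS, str(path))
    issues: list[ValidationIssue] = []
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        rec = _parse_row(row, line=i + 2, issues=issues)
        if rec is not None:
            records.append(rec)
    for issue in issues:
        logger.debug("intake csv %s line %d field %s: %s", path, issue.line, issue.field, issue.reason)
    return records, issues


def read_recalls_csv(path) -> tuple[list[RecallRecord], list[ValidationIssue]]:
    """Read a 24-hour-recall CSV (intake columns + ``recall_date``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, RECALL_CSV_COLUMNS, str(path))
    issues: list[ValidationIssue] = []
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        line = i + 2
        rec = _parse_row(row, line=line, issues=issues)
        if rec is None:
            continue
        try:
            recall_date = dt.date.fromisoformat(str(row["recall_date"]))
        except ValueError:
            issues.append(ValidationIssue(line, "recall_date", f"not an ISO date: {row['recall_date']!r}"))
            continue
        tp = str(row["timepoint"]) if "timepoint" in df.columns and row.get("timepoint") else None
        records.append(RecallRecord(intake=rec, recall_date=recall_date, timepoint=tp))
    return records, issues


def intake_to_row(intake: DailyIntake) -> dict:
    """Serialize a record to the intake CSV schema (None -> empty cell)."""
    row = {
        "participant_id": intake.participant_id,
        "date": intake.date.isoformat(),
        "energy_kcal": intake.energy,
    }
    for n in NUTRIENTS:
        v = getattr(intake, n)
        row[f"{n}_{NATIVE_UNITS[n]}"] = "" if v is None else v
    return row
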