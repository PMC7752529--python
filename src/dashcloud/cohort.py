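"""Study-calibrated synthetic cohort generator.

Emulates a two-arm mHealth feasibility trial in women with elevated blood
pressure: permuted-block randomization (random even block sizes 4-8),
daily nutrient intakes whose scored DASH adherence matches a configured
latent level (defaults: baseline mean 2.3, SD 1.3; +0.8 change in both
arms over three months), diet-tracking presence starting near 4.6 valid
days/week with a linear weekly decline (intervention 0.23 days/week per
week steeper than the flat comparator), 24-hour-recall pairs at baseline
and month 3 with a configurable protocol-violation contamination rate, and
follow-up blood pressure linearly coupled to the measured DASH-score
change (SBP -2.5, DBP -1.6 mmHg per unit).  Every stream is reproducible:
one child generator per participant, derived from (master seed,
participant index).

The intake generator inverts the scorer: it apportions the latent total
into per-component credits (largest-remainder apportionment of half-credit
units, then a sum-preserving jitter), samples each standardized value
strictly inside its credit's band, and converts back to absolute amounts
at a drawn energy — so scoring the emitted record with the same TargetSet
reproduces the drawn credits exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .analysis import OUTCOME_COLUMNS
from .intake import (
    INTAKE_CSV_COLUMNS,
    NUTRIENTS,
    RECALL_CSV_COLUMNS,
    DailyIntake,
    RecallRecord,
    classify_recall_day,
    compute_densities,
    densities_to_intake,
    intake_to_row,
)
from .scoring import TargetSet, score_day
from .tracking import assess_recall_validity

#: Outer physiologic edge of each component's zero-credit band (same basis
#: units as the targets).  Fixed constants of the default generator.
ZERO_CREDIT_BOUND = {
    "total_fat": 60.0,  # % of energy
    "saturated_fat": 25.0,  # % of energy
    "protein": 4.0,  # % of energy (low side)
    "cholesterol": 450.0,  # mg/1000 kcal
    "fiber": 0.0,  # g/1000 kcal (low side)
    "magnesium": 30.0,  # mg/1000 kcal (low side)
    "calcium": 60.0,  # mg/1000 kcal (low side)
    "potassium": 250.0,  # mg/1000 kcal (low side)
    "sodium": 8000.0,  # mg/day
}

#: Full-credit band spans a 2x margin beyond the target (min-type: up to
#: 2*target; max-type: down to target/2).
FULL_CREDIT_MARGIN = 2.0

_BAND_INSET = 1e-6  # keep samples strictly inside bands (float round trips)

ROSTER_CSV_COLUMNS = [
    "participant_id",
    "arm",
    "enrollment_date",
    "baseline_sbp",
    "baseline_dbp",
    "month3_sbp",
    "month3_dbp",
]


@dataclass
class CohortParams:
    """All simulator knobs; defaults are the study-calibrated conditions."""

    n_participants: int = 59
    block_sizes: tuple[int, ...] = (4, 6, 8)
    arms: tuple[str, str] = ("intervention", "comparator")
    # latent DASH adherence (0-9 scale)
    baseline_adherence_mean: float = 2.3
    baseline_adherence_sd: float = 1.3
    adherence_change_mean: dict = field(
        default_factory=lambda: {"intervention": 0.8, "comparator": 0.8}
    )
    adherence_change_sd: float = 1.3
    # diet-tracking engagement
    tracking_initial_rate: float = 4.6  # valid days/week at week 0, cohort mean
    tracking_rate_sd: float = 1.0  # between-participant SD of the initial rate
    tracking_decline: dict = field(
        default_factory=lambda: {"intervention": 0.23, "comparator": 0.0}
    )  # valid days/week lost per week
    invalid_day_rate: float = 0.05  # present-but-<600-kcal contamination
    weeks: int = 12
    study_length_days: int = 90
    # blood pressure (mmHg)
    sbp_baseline_mean: float = 122.9
    sbp_baseline_sd: float = 14.2
    dbp_baseline_mean: float = 80.2
    dbp_baseline_sd: float = 8.8
    sbp_coupling: float = -2.5  # mmHg per unit DASH change
    dbp_coupling: float = -1.6
    sbp_residual_sd: float = 9.0
    dbp_residual_sd: float = 7.4
    sbp_arm_effect: float = 0.0  # additive month-3 shift, intervention arm
    dbp_arm_effect: float = 0.0
    # energy distribution for generated days (kcal)
    energy_mean: float = 1800.0
    energy_sd: float = 350.0
    # recall protocol
    recall_invalid_rate: float = 0.1
    missing_followup_rate: float = 0.1
    study_start: dt.date = dt.date(2017, 9, 1)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        for b in self.block_sizes:
            if b % 2 != 0:
                raise ValueError(f"block sizes must be even for a 2-arm trial, got {b}")
        for name in ("baseline_adherence_sd", "adherence_change_sd", "sbp_baseline_sd",
                     "dbp_baseline_sd", "energy_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("sbp_residual_sd", "dbp_residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.baseline_adherence_mean <= 9:
            raise ValueError("baseline_adherence_mean must lie in [0, 9]")
        for name in ("invalid_day_rate", "recall_invalid_rate", "missing_followup_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.tracking_initial_rate <= 7:
            raise ValueError("tracking_initial_rate must lie in [0, 7]")
        if self.tracking_rate_sd < 0:
            raise ValueError("tracking_rate_sd must be >= 0")
        if isinstance(self.study_start, str):
            self.study_start = dt.date.fromisoformat(self.study_start)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortParams":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown cohort parameters: {sorted(unknown)}")
        if "block_sizes" in payload:
            payload["block_sizes"] = tuple(payload["block_sizes"])
        if "arms" in payload:
            payload["arms"] = tuple(payload["arms"])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["study_start"] = self.study_start.isoformat()
        payload["block_sizes"] = list(self.block_sizes)
        payload["arms"] = list(self.arms)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def permuted_block_randomize(
    n: int,
    block_sizes: Sequence[int] = (4, 6, 8),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    arms: tuple[str, str] = ("intervention", "comparator"),
) -> list[str]:
    """Permuted-block arm assignment with random block sizes.

    Every completed block is exactly balanced between the two arms; block
    sizes are drawn uniformly from ``block_sizes`` (all even).
    Deterministic given the seed.
    """
    block_sizes = tuple(int(b) for b in block_sizes)
    for b in block_sizes:
        if b % 2 != 0 or b <= 0:
            raise ValueError(f"block sizes must be positive and even, got {b}")
    if n > 0 and n < min(block_sizes):
        raise ValueError(f"n={n} smaller than the smallest block {min(block_sizes)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    assignments: list[str] = []
    while len(assignments) < n:
        b = int(rng.choice(block_sizes))
        block = [arms[0]] * (b // 2) + [arms[1]] * (b // 2)
        rng.shuffle(block)
        assignments.extend(block)
    return assignments[:n]


def _truncnorm_location(mean: float, sd: float, low: float = 0.0, high: float = 9.0) -> float:
    """Location of a [low, high]-truncated normal whose *truncated* mean is
    ``mean`` — so the generated cohort mean matches the configured mean
    rather than being inflated by truncation at zero."""
    if not low < mean < high:
        raise ValueError(f"mean {mean} must lie strictly inside [{low}, {high}]")

    def gap(loc: float) -> float:
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    return float(optimize.brentq(gap, low - 6 * sd, high + 6 * sd))


def _sample_truncnorm(rng: np.random.Generator, loc: float, sd: float,
                      low: float = 0.0, high: float = 9.0) -> float:
    a, b = (low - loc) / sd, (high - loc) / sd
    return float(stats.truncnorm.ppf(rng.random(), a, b, loc=loc, scale=sd))


def _allocate_credits(latent: float, rng: np.random.Generator) -> np.ndarray:
    """Half-credit units (0, 1 or 2) per component summing to ~2*latent.

    Randomized rounding keeps the expectation of the credit sum equal to
    the latent level exactly; largest-remainder apportionment (equal
    quotas, seeded tie-break) spreads units evenly before a sum-preserving
    jitter redistributes them.
    """
    h_exact = 2.0 * latent
    total = int(np.floor(h_exact))
    if rng.random() < h_exact - total:
        total += 1
    base, rem = divmod(total, 9)
    halves = np.full(9, base, dtype=np.int64)
    if rem:
        halves[rng.permutation(9)[:rem]] += 1
    for _ in range(12):  # mix which components carry the credits
        i, j = rng.integers(0, 9, size=2)
        if i != j and halves[i] > 0 and halves[j] < 2:
            halves[i] -= 1
            halves[j] += 1
    return halves


def _credit_band(spec, credit: float) -> tuple[float, float]:
    if spec.direction == "min":
        if credit == 1.0:
            return spec.target, FULL_CREDIT_MARGIN * spec.target
        if credit == 0.5:
            return spec.intermediate, spec.target
        return ZERO_CREDIT_BOUND[spec.nutrient], spec.intermediate
    if credit == 1.0:
        return spec.target / FULL_CREDIT_MARGIN, spec.target
    if credit == 0.5:
        return spec.target, spec.intermediate
    return spec.intermediate, ZERO_CREDIT_BOUND[spec.nutrient]


def generate_daily_intake(
    latent_adherence: float,
    targets: TargetSet,
    rng: np.random.Generator,
    participant_id: str = "SYN",
    date: dt.date = dt.date(2017, 9, 1),
    energy: Optional[float] = None,
    energy_mean: float = 1800.0,
    energy_sd: float = 350.0,
) -> DailyIntake:
    """Draw one intake record whose DASH score has expectation ``latent_adherence``.

    Scoring the emitted record with the same ``targets`` reproduces the
    drawn credits exactly (values are sampled strictly inside their bands,
    and saturated fat is clamped to total fat without leaving its band).
    """
    if not 0.0 <= latent_adherence <= 9.0:
        raise ValueError(f"latent adherence must lie in [0, 9], got {latent_adherence}")
    halves = _allocate_credits(latent_adherence, rng)
    values: dict[str, float] = {}
    for idx, nutrient in enumerate(NUTRIENTS):
        lo, hi = _credit_band(targets[nutrient], halves[idx] / 2.0)
        u = rng.uniform(_BAND_INSET, 1.0 - _BAND_INSET)
        values[nutrient] = lo + u * (hi - lo)
    # physiological consistency: saturated fat cannot exceed total fat.
    # Both are % of energy, and the fat full-credit floor (target/2) sits
    # above the saturated-fat intermediate, so the clamp never changes the
    # saturated-fat credit.
    if values["saturated_fat"] > values["total_fat"]:
        values["saturated_fat"] = values["total_fat"]
    if energy is None:
        energy = float(np.clip(rng.normal(energy_mean, energy_sd), 800.0, 3200.0))
    return densities_to_intake(values, energy, participant_id, date)


def simulate_tracking(
    weeks: int,
    initial_rate: float,
    decline: float,
    rng: np.random.Generator,
    invalid_day_rate: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate diary presence/validity flags, one row per study week.

    Week ``w`` has Binomial(7, clamp((initial_rate - decline*w)/7, 0, 1))
    valid days, so the expected weekly valid-day count declines linearly by
    exactly ``decline`` until clamping.  A fraction of the remaining days
    are present-but-invalid (<600 kcal logs); the rest are absent.

    Returns ``(present, valid)`` boolean arrays of shape (weeks, 7), with
    valid a subset of present.
    """
    if not 0.0 <= initial_rate <= 7.0:
        raise ValueError("initial_rate must lie in [0, 7]")
    present = np.zeros((weeks, 7), dtype=bool)
    valid = np.zeros((weeks, 7), dtype=bool)
    for w in range(weeks):
        p = float(np.clip((initial_rate - decline * w) / 7.0, 0.0, 1.0))
        valid[w] = rng.random(7) < p
        extra = ~valid[w] & (rng.random(7) < invalid_day_rate)
        present[w] = valid[w] | extra
    return present, valid


def simulate_bp(
    baseline_bp,
    delta_dash,
    coupling: float,
    residual_sd: float,
    rng: np.random.Generator,
):
    """Month-3 blood pressure: baseline + coupling * ΔDASH + Gaussian noise.

    ``coupling`` is negative when adherence improvement lowers pressure.
    """
    if residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    baseline_bp = np.asarray(baseline_bp, dtype=float)
    noise = rng.normal(0.0, residual_sd, size=baseline_bp.shape) if residual_sd > 0 else 0.0
    out = baseline_bp + coupling * np.asarray(delta_dash, dtype=float) + noise
    return float(out) if out.ndim == 0 else out


def simulate_engagement_panel(
    params: CohortParams,
    n_per_arm: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Long-format weekly valid-day panel for both arms, ready for the
    engagement-trend mixed model.

    Each participant draws an initial tracking rate from
    Normal(tracking_initial_rate, tracking_rate_sd) clipped to [0, 7] — the
    between-participant heterogeneity the random intercept absorbs — then
    declines linearly at the arm's configured rate.
    """
    rows = []
    for arm in params.arms:
        decline = params.tracking_decline[arm]
        for i in range(n_per_arm):
            rate0 = float(np.clip(
                rng.normal(params.tracking_initial_rate, params.tracking_rate_sd), 0.0, 7.0
            ))
            _, valid = simulate_tracking(
                params.weeks, rate0, decline, rng, params.invalid_day_rate
            )
            rows.extend(
                {
                    "participant_id": f"{arm}-{i:04d}",
                    "week": w,
                    "valid_days": int(valid[w].sum()),
                    "arm": arm,
                }
                for w in range(params.weeks)
            )
    return pd.DataFrame(rows, columns=["participant_id", "week", "valid_days", "arm"])


_INVALID_RECALL_MODES = ("no-weekend", "gap", "low-kcal", "high-kcal")


def _first_weekday(date: dt.date) -> dt.date:
    while date.weekday() >= 5:
        date += dt.timedelta(days=1)
    return date


def _first_saturday(date: dt.date) -> dt.date:
    while date.weekday() != 5:
        date += dt.timedelta(days=1)
    return date


def _generate_recalls(
    rng: np.random.Generator,
    latent: float,
    anchor: dt.date,
    make_invalid: bool,
    targets: TargetSet,
    params: CohortParams,
    participant_id: str,
    timepoint: str,
) -> tuple[list[RecallRecord], Optional[str]]:
    """One weekend + one weekday recall near ``anchor``; optionally violate
    exactly one protocol rule (the contamination mode returned)."""
    mode = _INVALID_RECALL_MODES[int(rng.integers(len(_INVALID_RECALL_MODES)))] if make_invalid else None
    weekday_date = _first_weekday(anchor + dt.timedelta(days=1))
    if mode == "no-weekend":
        other = _first_weekday(weekday_date + dt.timedelta(days=1))
        dates = [weekday_date, other]
    elif mode == "gap":
        dates = [weekday_date, _first_saturday(weekday_date + dt.timedelta(days=15))]
    else:
        dates = [weekday_date, _first_saturday(anchor + dt.timedelta(days=1))]
    if mode == "low-kcal":
        energies = rng.uniform(350.0, 550.0, size=2)
    elif mode == "high-kcal":
        energies = rng.uniform(3600.0, 4200.0, size=2)
    else:
        energies = np.clip(rng.normal(params.energy_mean, params.energy_sd, size=2), 800.0, 3200.0)
    recalls = []
    for date, energy in zip(dates, energies):
        intake = generate_daily_intake(
            latent, targets, rng, participant_id, date, energy=float(energy)
        )
        recalls.append(RecallRecord(intake=intake, recall_date=date, timepoint=timepoint))
    return recalls, mode


@dataclass
class Cohort:
    """Generated datasets plus the latent truth used to create them."""

    params: CohortParams
    intake: pd.DataFrame
    recalls: pd.DataFrame
    roster: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("intake", "recalls", "roster", "outcomes", "truth"):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def _score_recalls(recalls: list[RecallRecord], targets: TargetSet) -> Optional[float]:
    assessment = assess_recall_validity(recalls)
    used = assessment.recalls_used or recalls
    if not used:
        return None
    totals = [score_day(compute_densities(r.intake), targets, r.recall_date).total for r in used]
    return float(np.mean(totals))


def generate_cohort(
    params: CohortParams,
    outdir: Optional[str | Path] = None,
    targets: Optional[TargetSet] = None,
    include_diary: bool = True,
) -> Cohort:
    """Generate a complete, internally consistent synthetic trial dataset.

    Emits the daily-diary intake table (``include_diary=False`` skips it
    when only recalls/outcomes are needed), baseline and month-3 recall
    pairs, the roster, the analysis-ready outcomes table, and the latent
    truth.  Re-running with identical params is byte-identical.
    """
    if targets is None:
        targets = TargetSet.default()
    n = params.n_participants
    master = np.random.default_rng(params.seed)
    arms = permuted_block_randomize(
        n, params.block_sizes, rng=master, arms=params.arms
    ) if n else []
    enroll_offsets = master.integers(0, 15 * 7, size=n) if n else np.array([], dtype=int)
    base_loc = _truncnorm_location(params.baseline_adherence_mean, params.baseline_adherence_sd)

    intake_rows: list[dict] = []
    recall_rows: list[dict] = []
    roster_rows: list[dict] = []
    outcome_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(n):
        rng = np.random.default_rng([params.seed, i])
        pid = f"P{i + 1:04d}"
        arm = arms[i]
        enrollment = params.study_start + dt.timedelta(days=int(enroll_offsets[i]))
        b_lat = _sample_truncnorm(rng, base_loc, params.baseline_adherence_sd)
        delta_lat = rng.normal(params.adherence_change_mean[arm], params.adherence_change_sd)
        m_lat = float(np.clip(b_lat + delta_lat, 0.0, 9.0))
        dropout = rng.random() < params.missing_followup_rate

        # --- daily diary ------------------------------------------------
        if include_diary:
            rate0 = float(np.clip(
                rng.normal(params.tracking_initial_rate, params.tracking_rate_sd), 0.0, 7.0
            ))
            present, valid = simulate_tracking(
                params.weeks,
                rate0,
                params.tracking_decline[arm],
                rng,
                params.invalid_day_rate,
            )
            present[0, 0] = valid[0, 0] = True  # baseline day always logged
            span = params.weeks * 7
            for w in range(params.weeks):
                for d in range(7):
                    if not present[w, d]:
                        continue
                    day = w * 7 + d
                    date = enrollment + dt.timedelta(days=day)
                    latent_day = b_lat + (m_lat - b_lat) * day / span
                    energy = None if valid[w, d] else float(rng.uniform(250.0, 590.0))
                    rec = generate_daily_intake(
                        latent_day, targets, rng, pid, date,
                        energy=energy,
                        energy_mean=params.energy_mean,
                        energy_sd=params.energy_sd,
                    )
                    intake_rows.append(intake_to_row(rec))

        # --- recalls ----------------------------------------------------
        base_invalid = rng.random() < params.recall_invalid_rate
        base_recalls, base_mode = _generate_recalls(
            rng, b_lat, enrollment, base_invalid, targets, params, pid, "baseline"
        )
        baseline_dash = _score_recalls(base_recalls, targets)
        month3_recalls: list[RecallRecord] = []
        month3_mode = None
        month3_dash = None
        if not dropout:
            m3_invalid = rng.random() < params.recall_invalid_rate
            m3_anchor = enrollment + dt.timedelta(days=params.study_length_days)
            month3_recalls, month3_mode = _generate_recalls(
                rng, m_lat, m3_anchor, m3_invalid, targets, params, pid, "month3"
            )
            month3_dash = _score_recalls(month3_recalls, targets)
        for r in base_recalls + month3_recalls:
            row = intake_to_row(r.intake)
            row["recall_date"] = r.recall_date.isoformat()
            row["timepoint"] = r.timepoint
            recall_rows.append(row)

        # --- blood pressure ----------------------------------------------
        baseline_sbp = float(rng.normal(params.sbp_baseline_mean, params.sbp_baseline_sd))
        baseline_dbp = float(rng.normal(params.dbp_baseline_mean, params.dbp_baseline_sd))
        if dropout or month3_dash is None or baseline_dash is None:
            month3_sbp = month3_dbp = np.nan
        else:
            measured_delta = month3_dash - baseline_dash
            arm_sbp = params.sbp_arm_effect if arm == params.arms[0] else 0.0
            arm_dbp = params.dbp_arm_effect if arm == params.arms[0] else 0.0
            month3_sbp = simulate_bp(
                baseline_sbp, measured_delta, params.sbp_coupling, params.sbp_residual_sd, rng
            ) + arm_sbp
            month3_dbp = simulate_bp(
                baseline_dbp, measured_delta, params.dbp_coupling, params.dbp_residual_sd, rng
            ) + arm_dbp

        roster_rows.append({
            "participant_id": pid,
            "arm": arm,
            "enrollment_date": enrollment.isoformat(),
            "baseline_sbp": baseline_sbp,
            "baseline_dbp": baseline_dbp,
            "month3_sbp": month3_sbp,
            "month3_dbp": month3_dbp,
        })
        outcome_rows.append({
            "participant_id": pid,
            "arm": arm,
            "baseline_dash": baseline_dash,
            "month3_dash": month3_dash,
            "baseline_dash_valid": not base_invalid,
            "month3_dash_valid": (not dropout) and month3_mode is None,
            "baseline_sbp": baseline_sbp,
            "month3_sbp": month3_sbp,
            "baseline_dbp": baseline_dbp,
            "month3_dbp": month3_dbp,
        })
        truth_rows.append({
            "participant_id": pid,
            "arm": arm,
            "latent_baseline": b_lat,
            "latent_month3": m_lat,
            "latent_delta": m_lat - b_lat,
            "dropout": dropout,
            "baseline_recall_mode": base_mode or "valid",
            "month3_recall_mode": ("missing" if dropout else (month3_mode or "valid")),
        })

    cohort = Cohort(
        params=params,
        intake=pd.DataFrame(intake_rows, columns=INTAKE_CSV_COLUMNS),
        recalls=pd.DataFrame(recall_rows, columns=RECALL_CSV_COLUMNS + ["timepoint"]),
        roster=pd.DataFrame(roster_rows, columns=ROSTER_CSV_COLUMNS),
        outcomes=pd.DataFrame(outcome_rows, columns=OUTCOME_COLUMNS),
        truth=pd.DataFrame(
            truth_rows,
            columns=["participant_id", "arm", "latent_baseline", "latent_month3",
                     "latent_delta", "dropout", "baseline_recall_mode", "month3_recall_mode"],
        ),
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort
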