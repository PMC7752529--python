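"""Self-monitoring engagement and dietary-recall validity.

Engagement is operationalized as *valid tracked days*: a diary day counts
only when a log exists and reported energy is at least 600 kcal.  Weekly
counts (7-day blocks anchored on the randomization date) feed a
random-intercept mixed model of days-tracked-per-week over time with a
time-by-group interaction, the study's engagement-trend analysis.  The
module also applies the recall-protocol validity rules used to decide
whether a participant-timepoint's 24-hour recalls can be scored: at least
two recalls covering one weekend day and one weekday, collected no more
than two weeks apart, with mean energy between 600 and 3500 kcal.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .intake import RecallRecord

logger = logging.getLogger(__name__)

MIN_VALID_KCAL = 600.0
RECALL_KCAL_BOUNDS = (600.0, 3500.0)
MAX_RECALL_GAP_DAYS = 14


@dataclass(frozen=True)
class TrackingDay:
    """One diary day: whether anything was logged, and at what energy."""

    participant_id: str
    date: dt.date
    present: bool
    energy: Optional[float] = None

    @property
    def valid(self) -> bool:
        return is_valid_tracking_day(self)


def is_valid_tracking_day(day: TrackingDay, min_kcal: float = MIN_VALID_KCAL) -> bool:
    """A day counts as tracked iff a log exists with energy >= 600 kcal."""
    return bool(day.present and day.energy is not None and day.energy >= min_kcal)


@dataclass
class EngagementSummary:
    participant_id: str
    weekly_valid_days: list[int]  # one count per complete 7-day block
    mean_days_per_week: float
    meets_5plus: bool


def weekly_engagement(
    days: Sequence[TrackingDay],
    randomization_date: dt.date,
    n_weeks: Optional[int] = None,
    min_kcal: float = MIN_VALID_KCAL,
) -> EngagementSummary:
    """Count valid days per 7-day block from randomization.

    Duplicate rows for the same date are deduplicated (a date is valid if
    any of its rows is valid); days preceding randomization are excluded
    with a warning.  Partial terminal weeks are excluded from the mean.
    ``n_weeks`` caps/extends the block count so untracked trailing weeks
    count as zeros.
    """
    pid = days[0].participant_id if days else ""
    valid_dates = set()
    last_date = randomization_date
    for d in days:
        if d.date < randomization_date:
            logger.warning(
                "excluding tracking day %s before randomization %s (%s)",
                d.date, randomization_date, d.participant_id,
            )
            continue
        last_date = max(last_date, d.date)
        if is_valid_tracking_day(d, min_kcal):
            valid_dates.add(d.date)
    if n_weeks is None:
        n_weeks = ((last_date - randomization_date).days + 1) // 7
    counts = [0] * n_weeks
    for date in valid_dates:
        w = (date - randomization_date).days // 7
        if 0 <= w < n_weeks:
            counts[w] += 1
    mean = float(np.mean(counts)) if counts else 0.0
    return EngagementSummary(pid, counts, mean, meets_5plus=mean >= 5.0)


@dataclass
class EffectEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI bounds must bracket the point estimate")


@dataclass
class TrendFit:
    """Fixed effects of the engagement-trend mixed model.

    ``time_slope`` is the weekly change in valid days/week in the reference
    arm; ``interaction`` is the additional weekly change in the other arm.
    """

    intercept: EffectEstimate
    time_slope: EffectEstimate
    group_effect: EffectEstimate
    interaction: EffectEstimate
    random_intercept_var: float
    reference_arm: str
    other_arm: str
    diagnostics: dict = field(default_factory=dict)

    def arm_slope(self, arm: str) -> float:
        """Weekly trend in valid days/week for one arm."""
        if arm == self.reference_arm:
            return self.time_slope.estimate
        if arm == self.other_arm:
            return self.time_slope.estimate + self.interaction.estimate
        raise KeyError(arm)

    def arm_decline(self, arm: str) -> float:
        """Decline magnitude (positive = losing days/week per week)."""
        return -self.arm_slope(arm)


def fit_engagement_trend(
    panel: pd.DataFrame,
    reference_arm: str = "comparator",
    reml: bool = True,
) -> TrendFit:
    """Random-intercept mixed model of weekly valid-day counts.

    ``panel`` needs columns participant_id, week (continuous, in weeks),
    valid_days, arm (two levels).  Fixed effects: intercept, week, arm and
    week x arm; random intercept per participant.  The residual structure
    is independent within participant (the backend does not support an
    unstructured residual covariance; flagged in diagnostics) — the
    contract is the fixed-effect estimates and their Wald CIs.
    """
    required = {"participant_id", "week", "valid_days", "arm"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    arms = sorted(panel["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"need exactly 2 arms, got {arms}")
    if panel.groupby("participant_id")["week"].nunique().min() < 2:
        raise ValueError("need >=2 weeks per participant")
    if reference_arm not in arms:
        raise ValueError(f"reference arm {reference_arm!r} not in {arms}")
    other_arm = next(a for a in arms if a != reference_arm)

    md = smf.mixedlm(
        f"valid_days ~ week * C(arm, Treatment('{reference_arm}'))",
        data=panel,
        groups=panel["participant_id"],
    )
    try:
        import warnings

        with warnings.catch_warnings():
            # convergence status is recorded in diagnostics instead
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = md.fit(reml=reml)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular design: {exc}") from exc

    arm_term = f"C(arm, Treatment('{reference_arm}'))[T.{other_arm}]"
    names = {
        "intercept": "Intercept",
        "time_slope": "week",
        "group_effect": arm_term,
        "interaction": f"week:{arm_term}",
    }
    ci = res.conf_int(alpha=0.05)
    effects = {}
    for key, term in names.items():
        effects[key] = EffectEstimate(
            estimate=float(res.params[term]),
            se=float(res.bse[term]),
            ci_low=float(ci.loc[term, 0]),
            ci_high=float(ci.loc[term, 1]),
            p_value=float(res.pvalues[term]),
        )
    return TrendFit(
        **effects,
        random_intercept_var=float(res.cov_re.iloc[0, 0]),
        reference_arm=reference_arm,
        other_arm=other_arm,
        diagnostics={
            "converged": bool(res.converged),
            "residual_covariance": "independent (random-intercept model; "
            "unstructured residual covariance unsupported by backend)",
            "method": "REML" if reml else "ML",
            "n_obs": int(len(panel)),
            "n_groups": int(panel["participant_id"].nunique()),
        },
    )


@dataclass
class RecallAssessment:
    participant_id: str
    timepoint: str
    recalls_used: list[RecallRecord]
    valid: bool
    failure_reasons: list[str]
    mean_energy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.valid != (not self.failure_reasons):
            raise ValueError("valid must hold exactly when failure_reasons is empty")


def assess_recall_validity(
    recalls: Sequence[RecallRecord],
    participant_id: str = "",
    timepoint: str = "",
    kcal_bounds: tuple[float, float] = RECALL_KCAL_BOUNDS,
    max_gap_days: int = MAX_RECALL_GAP_DAYS,
) -> RecallAssessment:
    """Apply the recall-protocol validity rules for one participant-timepoint.

    Rules: >=2 recalls; >=1 weekend day and >=1 weekday; recalls used no
    more than ``max_gap_days`` apart; mean energy of the recalls used within
    ``kcal_bounds``.  When more than two recalls exist, the earliest weekend
    and earliest weekday recall are used (deterministic choice).  Failures
    are reasons, never exceptions.
    """
    reasons: list[str] = []
    weekend = sorted((r for r in recalls if r.day_class == "weekend"), key=lambda r: r.recall_date)
    weekday = sorted((r for r in recalls if r.day_class == "weekday"), key=lambda r: r.recall_date)
    if len(recalls) < 2:
        reasons.append("too-few-recalls")
    if not weekend:
        reasons.append("no-weekend")
    if not weekday:
        reasons.append("no-weekday")

    if weekend and weekday:
        used = [weekend[0], weekday[0]]
        gap = abs((used[0].recall_date - used[1].recall_date).days)
        if gap > max_gap_days:
            reasons.append("gap>14d")
    else:
        used = list(recalls)

    mean_energy = None
    if used:
        mean_energy = float(np.mean([r.energy for r in used]))
        if mean_energy < kcal_bounds[0]:
            reasons.append("kcal<600")
        elif mean_energy > kcal_bounds[1]:
            reasons.append("kcal>3500")

    return RecallAssessment(
        participant_id=participant_id,
        timepoint=timepoint,
        recalls_used=used,
        valid=not reasons,
        failure_reasons=reasons,
        mean_energy=mean_energy,
    )
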