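"""Randomized-trial outcome analyses.

Three estimators mirror the feasibility trial's statistical plan:
within-arm change from baseline to month 3 (paired repeated-measures
analysis), the baseline-adjusted between-arm difference at month 3
(ANCOVA-style linear regression of the 3-month outcome on arm and its
baseline value), and the association between change in DASH adherence and
change in blood pressure (least-squares slope and Pearson correlation).
Missing follow-up is handled by likelihood-based estimation on all
randomized participants with available data (available-case under MAR);
alpha = 0.05 two-sided throughout, with Wald-type CIs on residual degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

ALPHA = 0.05

OUTCOME_COLUMNS = [
    "participant_id",
    "arm",
    "baseline_dash",
    "month3_dash",
    "baseline_dash_valid",
    "month3_dash_valid",
    "baseline_sbp",
    "month3_sbp",
    "baseline_dbp",
    "month3_dbp",
]


@dataclass
class AdjustedEffect:
    """A point estimate with Wald CI and p-value, plus what it adjusts for."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    covariates: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-9 <= self.estimate <= self.ci_high + 1e-9):
            raise ValueError("CI bounds must bracket the estimate")


def within_group_change(
    baseline: Sequence[float], month3: Sequence[float], label: str = ""
) -> AdjustedEffect:
    """Mean change (month 3 - baseline) within one arm, paired analysis.

    With only two timepoints the repeated-measures analysis reduces to the
    paired t machinery: mean difference, t-based 95% CI and p-value over
    pairwise-complete observations.
    """
    base = np.asarray(baseline, dtype=float)
    follow = np.asarray(month3, dtype=float)
    if base.shape != follow.shape:
        raise ValueError("baseline and month3 must be the same length")
    mask = ~np.isnan(base) & ~np.isnan(follow)
    diffs = follow[mask] - base[mask]
    n = diffs.size
    if n < 2:
        raise ValueError(f"need >=2 paired observations, got {n}")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1 - ALPHA / 2, df=n - 1)
    if se == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        return AdjustedEffect(mean, mean, mean, p, n, label=label)
    tstat = mean / se
    p = float(2 * stats.t.sf(abs(tstat), df=n - 1))
    return AdjustedEffect(mean, mean - tcrit * se, mean + tcrit * se, p, n, label=label)


def adjusted_group_difference(
    df: pd.DataFrame,
    outcome: str,
    baseline: Optional[str],
    arm_col: str = "arm",
    treated: str = "intervention",
    label: str = "",
) -> AdjustedEffect:
    """Between-arm coefficient from regressing a 3-month outcome on arm
    (treated minus reference) and, when given, its baseline value.

    Rows with a missing outcome (or missing baseline covariate) are dropped:
    likelihood-based estimation over all randomized participants with
    available data.
    """
    arms = set(df[arm_col].dropna().unique())
    if len(arms) < 2:
        raise ValueError(f"both arms must be represented, got {sorted(arms)}")
    if treated not in arms:
        raise ValueError(f"treated arm {treated!r} not found in {sorted(arms)}")
    reference = next(a for a in sorted(arms) if a != treated)
    cols = [outcome, arm_col] + ([baseline] if baseline else [])
    data = df[cols].dropna().copy()
    if data[arm_col].nunique() < 2:
        raise ValueError("only one arm left after dropping missing outcomes")
    data["_treated"] = (data[arm_col] == treated).astype(float)
    formula = f"{outcome} ~ _treated" + (f" + {baseline}" if baseline else "")
    res = smf.ols(formula, data=data).fit()
    ci = res.conf_int(alpha=ALPHA)
    return AdjustedEffect(
        estimate=float(res.params["_treated"]),
        ci_low=float(ci.loc["_treated", 0]),
        ci_high=float(ci.loc["_treated", 1]),
        p_value=float(res.pvalues["_treated"]),
        n=int(res.nobs),
        covariates=(baseline,) if baseline else (),
        label=label or f"{outcome}: {treated} vs {reference}, baseline-adjusted",
    )


@dataclass
class AssociationResult:
    """ΔBP-on-ΔDASH least-squares fit with its Pearson correlation.

    ``slope`` keeps the regression sign (negative when DASH improvement
    accompanies a BP decrease); ``decrease_per_unit`` reports the same
    effect as the positive mmHg-decrease magnitude per unit of DASH
    improvement, the scale on which such effects are usually quoted.
    """

    slope: float
    slope_ci: tuple[float, float]
    r: float
    p_value: float
    n: int
    decrease_per_unit: float = field(init=False)
    by_arm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.decrease_per_unit = -self.slope


def dash_bp_association(
    delta_dash: Sequence[float],
    delta_bp: Sequence[float],
    arm: Optional[Sequence[str]] = None,
) -> AssociationResult:
    """Slope of blood-pressure change on DASH-score change, with Pearson r.

    Computed over complete pairs, overall and (when arm labels are given)
    per arm.  The identity slope = r * sd(ΔBP)/sd(ΔDASH) holds exactly.
    """
    x = np.asarray(delta_dash, dtype=float)
    y = np.asarray(delta_bp, dtype=float)
    if x.shape != y.shape:
        raise ValueError("delta_dash and delta_bp must be the same length")
    mask = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in delta_dash: slope undefined")
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(1 - ALPHA / 2, df=n - 2)
    result = AssociationResult(
        slope=float(fit.slope),
        slope_ci=(float(fit.slope - tcrit * fit.stderr), float(fit.slope + tcrit * fit.stderr)),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=n,
    )
    if arm is not None:
        arm = np.asarray(arm, dtype=object)[mask]
        for a in sorted(set(arm)):
            sel = arm == a
            if sel.sum() >= 3 and np.ptp(x[sel]) > 0:
                result.by_arm[a] = dash_bp_association(x[sel], y[sel])
    return result


def _dash_with_validity(df: pd.DataFrame, per_protocol: bool) -> pd.DataFrame:
    """Per-protocol: blank DASH values whose recall set failed validity."""
    data = df.copy()
    if per_protocol:
        for tp in ("baseline", "month3"):
            flag = f"{tp}_dash_valid"
            if flag in data.columns:
                data.loc[~data[flag].astype("boolean").fillna(False), f"{tp}_dash"] = np.nan
    return data


def analyze_outcomes(df: pd.DataFrame, per_protocol: bool = True, treated: str = "intervention") -> dict:
    """Run the full outcome battery on an outcomes table.

    Returns within-arm changes, baseline-adjusted between-arm differences
    for the DASH score and both blood pressures, and the DASH-change vs
    BP-change association block.
    """
    data = _dash_with_validity(df, per_protocol)
    out: dict = {"per_protocol": per_protocol, "within_group": {}, "adjusted": {}}
    for arm_name, grp in data.groupby("arm"):
        out["within_group"][arm_name] = {
            m: within_group_change(grp[f"baseline_{m}"], grp[f"month3_{m}"], label=f"{m} change ({arm_name})")
            for m in ("dash", "sbp", "dbp")
            if (~grp[f"baseline_{m}"].isna() & ~grp[f"month3_{m}"].isna()).sum() >= 2
        }
    for m in ("dash", "sbp", "dbp"):
        out["adjusted"][m] = adjusted_group_difference(
            data, outcome=f"month3_{m}", baseline=f"baseline_{m}", treated=treated
        )
    delta_dash = data["month3_dash"] - data["baseline_dash"]
    assoc = {}
    for m in ("sbp", "dbp"):
        delta_bp = data[f"month3_{m}"] - data[f"baseline_{m}"]
        ok = (~delta_dash.isna() & ~delta_bp.isna()).sum()
        if ok >= 3 and np.nanstd(delta_dash) > 0:
            assoc[m] = dash_bp_association(delta_dash, delta_bp, arm=data["arm"])
    out["association"] = assoc
    return out


def sensitivity_with_invalid(df: pd.DataFrame, treated: str = "intervention") -> dict:
    """Per-protocol and sensitivity (invalid recalls included) fits, side by side."""
    return {
        "per_protocol": analyze_outcomes(df, per_protocol=True, treated=treated),
        "sensitivity": analyze_outcomes(df, per_protocol=False, treated=treated),
    }
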