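import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dashcloud.cohort import (
    CohortParams,
    _truncnorm_location,
    generate_cohort,
    generate_daily_intake,
    permuted_block_randomize,
    simulate_bp,
    simulate_tracking,
)
from dashcloud.intake import compute_densities
from dashcloud.scoring import score_day
from dashcloud.tracking import assess_recall_validity
from dashcloud.intake import RecallRecord, DailyIntake, NUTRIENTS, NATIVE_UNITS

# ------------------------------------------------------------ randomization


def test_fixed_block_size_balances_every_block():
    arms = permuted_block_randomize(8, block_sizes=(4,), seed=0)
    for k in (4, 8):
        prefix = arms[:k]
        assert prefix.count("intervention") == k // 2


@given(seed=st.integers(0, 2000), sizes=st.sets(st.sampled_from([4, 6, 8]), min_size=1))
@settings(max_examples=80, derandomize=True)
def test_block_balance_bound(seed, sizes):
    n = 59
    arms = permuted_block_randomize(n, block_sizes=sorted(sizes), seed=seed)
    diff = abs(arms.count("intervention") - arms.count("comparator"))
    assert diff <= max(sizes) // 2
    assert len(arms) == n


def test_randomizer_determinism():
    a = permuted_block_randomize(59, seed=123)
    b = permuted_block_randomize(59, seed=123)
    assert a == b


def test_odd_block_size_rejected():
    with pytest.raises(ValueError, match="even"):
        permuted_block_randomize(10, block_sizes=(5,), seed=0)


def test_n_below_smallest_block_rejected():
    with pytest.raises(ValueError):
        permuted_block_randomize(3, block_sizes=(4,), seed=0)


# ------------------------------------------------------- intake round trip


def test_extreme_latents_force_exact_scores(targets, rng):
    for latent, expected in ((9.0, 9.0), (0.0, 0.0)):
        for _ in range(20):
            intake = generate_daily_intake(latent, targets, rng)
            assert score_day(compute_densities(intake), targets).total == expected


def test_generated_scores_are_valid_half_steps(targets, rng):
    for _ in range(200):
        latent = rng.uniform(0, 9)
        total = score_day(compute_densities(generate_daily_intake(latent, targets, rng)), targets).total
        assert 0.0 <= total <= 9.0 and (2 * total) == int(2 * total)


def test_roundtrip_mean_matches_latent(targets, rng):
    """Law of large numbers: the scorer applied to generated days is an
    unbiased reader of the latent adherence level."""
    totals = [
        score_day(compute_densities(generate_daily_intake(4.5, targets, rng)), targets).total
        for _ in range(3000)
    ]
    assert np.mean(totals) == pytest.approx(4.5, abs=0.1)


def test_generated_intake_is_physiological(targets, rng):
    for _ in range(100):
        intake = generate_daily_intake(rng.uniform(0, 9), targets, rng)
        assert intake.saturated_fat <= intake.total_fat
        assert intake.complete and intake.energy > 0


def test_latent_out_of_range_rejected(targets, rng):
    with pytest.raises(ValueError):
        generate_daily_intake(9.5, targets, rng)


# ----------------------------------------------------------- tracking sim


def test_zero_decline_keeps_weekly_expectation_flat(rng):
    counts = np.zeros(8)
    for _ in range(300):
        _, valid = simulate_tracking(8, 4.6, 0.0, rng)
        counts += valid.sum(axis=1)
    weekly_means = counts / 300
    assert np.all(np.abs(weekly_means - 4.6) < 0.3)


def test_steep_decline_clamps_at_zero(rng):
    _, valid = simulate_tracking(12, 7.0, 2.0, rng)
    assert valid[6:].sum() == 0  # rate hits zero by week 4 and stays


def test_valid_days_subset_of_present(rng):
    present, valid = simulate_tracking(12, 4.6, 0.23, rng, invalid_day_rate=0.3)
    assert np.all(present | ~valid)
    assert present.sum() >= valid.sum()


def test_decline_slope_recovery(rng):
    """OLS on mean weekly counts recovers the configured decline."""
    weeks = 12
    counts = np.zeros(weeks)
    n = 500
    for _ in range(n):
        _, valid = simulate_tracking(weeks, 4.6, 0.23, rng)
        counts += valid.sum(axis=1)
    slope = np.polyfit(np.arange(weeks), counts / n, 1)[0]
    assert slope == pytest.approx(-0.23, abs=0.03)


# ----------------------------------------------------------------- bp sim


def test_noiseless_bp_coupling_is_exact(rng):
    assert simulate_bp(120.0, 2.0, -2.5, 0.0, rng) == pytest.approx(115.0)


def test_zero_coupling_centres_on_baseline(rng):
    vals = simulate_bp(np.full(4000, 120.0), np.zeros(4000), 0.0, 9.0, rng)
    assert np.mean(vals) == pytest.approx(120.0, abs=0.5)


def test_negative_residual_sd_rejected(rng):
    with pytest.raises(ValueError):
        simulate_bp(120.0, 1.0, -2.5, -1.0, rng)


# ------------------------------------------------------------- full cohort


def test_truncnorm_location_corrects_for_truncation():
    loc = _truncnorm_location(2.3, 1.3)
    assert loc < 2.3  # location shifts down to offset the floor at zero
    from scipy import stats

    a, b = (0 - loc) / 1.3, (9 - loc) / 1.3
    assert stats.truncnorm.mean(a, b, loc=loc, scale=1.3) == pytest.approx(2.3, abs=1e-9)


def test_empty_cohort_has_schema_valid_files(tmp_path):
    cohort = generate_cohort(CohortParams(n_participants=0), outdir=tmp_path)
    for name in ("intake", "recalls", "roster", "outcomes"):
        df = pd.read_csv(tmp_path / f"{name}.csv")
        assert len(df) == 0 and len(df.columns) > 0
    assert "energy_kcal" in cohort.intake.columns


def test_cohort_generation_is_deterministic():
    params = CohortParams(n_participants=12, seed=99)
    a = generate_cohort(params)
    b = generate_cohort(CohortParams(n_participants=12, seed=99))
    for name in ("intake", "recalls", "roster", "outcomes", "truth"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))


def test_cohort_outcomes_within_scale():
    cohort = generate_cohort(CohortParams(n_participants=40, seed=5), include_diary=False)
    o = cohort.outcomes
    dash = pd.concat([o.baseline_dash, o.month3_dash]).dropna()
    assert ((dash >= 0) & (dash <= 9)).all()
    assert o.baseline_sbp.between(60, 200).all()


def test_recall_contamination_matches_intended_flags():
    """Generated recall pairs violate the protocol rules exactly when their
    contamination mode says so."""
    cohort = generate_cohort(
        CohortParams(n_participants=60, seed=11, recall_invalid_rate=0.5),
        include_diary=False,
    )
    recalls = cohort.recalls
    truth = cohort.truth.set_index("participant_id")

    def to_record(row):
        intake = DailyIntake(
            participant_id=row["participant_id"],
            date=dt.date.fromisoformat(row["date"]),
            energy=float(row["energy_kcal"]),
            **{n: float(row[f"{n}_{NATIVE_UNITS[n]}"]) for n in NUTRIENTS},
        )
        return RecallRecord(intake=intake, recall_date=dt.date.fromisoformat(row["recall_date"]))

    checked = 0
    for (pid, tp), grp in recalls.groupby(["participant_id", "timepoint"]):
        mode = truth.loc[pid, f"{'baseline' if tp == 'baseline' else 'month3'}_recall_mode"]
        assessment = assess_recall_validity([to_record(r) for _, r in grp.iterrows()])
        assert assessment.valid is (mode == "valid"), (pid, tp, mode, assessment.failure_reasons)
        checked += 1
    assert checked >= 100  # both timepoints for most participants


def test_dropouts_have_missing_followup():
    cohort = generate_cohort(
        CohortParams(n_participants=50, seed=3, missing_followup_rate=0.4),
        include_diary=False,
    )
    merged = cohort.outcomes.merge(cohort.truth, on="participant_id")
    drop = merged[merged.dropout]
    assert len(drop) > 0
    assert drop.month3_dash.isna().all() and drop.month3_sbp.isna().all()


def test_diary_contains_baseline_day_for_everyone():
    cohort = generate_cohort(CohortParams(n_participants=10, seed=21))
    first = cohort.intake.groupby("participant_id")["date"].min()
    enroll = cohort.roster.set_index("participant_id")["enrollment_date"]
    assert (first == enroll.loc[first.index]).all()


def test_params_yaml_roundtrip(tmp_path):
    params = CohortParams(n_participants=25, seed=7, recall_invalid_rate=0.2)
    path = tmp_path / "params.yaml"
    params.to_yaml(path)
    assert CohortParams.from_yaml(path) == params


def test_unknown_param_key_rejected(tmp_path):
    path = tmp_path / "params.yaml"
    path.write_text("n_participants: 5\nnot_a_knob: 1\n")
    with pytest.raises(ValueError, match="unknown"):
        CohortParams.from_yaml(path)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        CohortParams(block_sizes=(5,))
    with pytest.raises(ValueError):
        CohortParams(baseline_adherence_sd=0.0)
    with pytest.raises(ValueError):
        CohortParams(recall_invalid_rate=1.5)
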