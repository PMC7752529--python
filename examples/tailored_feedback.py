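"""Compose the daily tailored-feedback text for a scored day and show the
90-day message cadence (daily at noon for two weeks, weekly after, Sunday
topic messages)."""

import datetime as dt

from dashcloud import (
    DailyIntake,
    TargetSet,
    build_schedule,
    classify_components,
    compose_daily_message,
    compute_densities,
    load_tip_bank,
    score_day,
)

targets = TargetSet.default()
intake = DailyIntake(
    "demo", dt.date(2017, 9, 14), 1900.0,
    total_fat=55.0, saturated_fat=11.0, protein=90.0, cholesterol=180.0,
    fiber=20.0, magnesium=260.0, calcium=700.0, potassium=2100.0, sodium=3100.0,
)
profile = compute_densities(intake)
score = score_day(profile, targets, intake.date)
best, struggle = classify_components(score, targets, profile)

msg = compose_daily_message(
    participant_id="demo", first_name="Dana", score=score,
    best=best, struggle=struggle, tip_bank=load_tip_bank(),
    date=intake.date + dt.timedelta(days=1), study_day=4,
)
print("Daily feedback text:\n ", msg.body, "\n")

schedule = build_schedule("demo", enrollment_date=dt.date(2017, 9, 10))
print("90-day cadence:",
      len(schedule.of_kind('daily_feedback')), "daily,",
      len(schedule.of_kind('weekly_feedback')), "weekly,",
      len(schedule.of_kind('topic')), "Sunday topic messages")
print("The score in the text is yesterday's DASH total; the praised and")
print("coached components are the closest call and the farthest miss.")
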