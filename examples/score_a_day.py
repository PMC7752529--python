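"""Standardize one day of tracked intake and score it on the 0-9 DASH index.

The raw amounts below are a fairly typical Western-diet day: energy-dense,
salty, light on fiber and minerals.  Standardization expresses each
nutrient on the basis its DASH standard uses (% of energy, per 1000 kcal,
or absolute mg for sodium); each component then earns 0, 0.5 or 1 points.
"""

import datetime as dt

from dashcloud import DailyIntake, TargetSet, compute_densities, score_day

intake = DailyIntake(
    participant_id="demo",
    date=dt.date(2017, 9, 14),
    energy=2000.0,
    total_fat=84.2,      # g  -> 37.9 % of energy
    saturated_fat=28.0,  # g  -> 12.6 % of energy
    protein=80.0,        # g  -> 16.0 % of energy
    cholesterol=344.4,   # mg -> 172.2 mg/1000 kcal
    fiber=18.2,          # g  -> 9.1 g/1000 kcal
    magnesium=284.4,     # mg -> 142.2 mg/1000 kcal
    calcium=988.8,       # mg -> 494.4 mg/1000 kcal
    potassium=2636.0,    # mg -> 1318 mg/1000 kcal
    sodium=3223.6,       # mg (absolute)
)

targets = TargetSet.default()
profile = compute_densities(intake)
score = score_day(profile, targets, intake.date)

print(f"{'component':<15}{'standardized':>14}{'target':>10}{'credit':>8}")
for spec in targets:
    arrow = "<=" if spec.direction == "max" else ">="
    print(f"{spec.nutrient:<15}{profile[spec.nutrient]:>14.1f}"
          f"{arrow}{spec.target:>8.1f}{score.component_credits[spec.nutrient]:>8.1f}")
print(f"\nTotal DASH score: {score.total} / 9")
print("Half credits mark components between the target and its more lenient")
print("intermediate threshold; this day earns partial credit on fat, protein,")
print("calcium and sodium and misses everything else outright.")
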