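# Default DASH nutrient standards (Mellen-style nutrient index).
# direction: min = "more is better" (full credit at/above target),
#            max = "less is better" (full credit at/below target).
# intermediate: half-credit threshold; min-type (2/3)*target, max-type
#            1.5*target, rounded to two decimals.
targets:
  - nutrient: total_fat
    direction: max
    basis: percent_of_energy
    target: 27.0
    intermediate: 40.5
  - nutrient: saturated_fat
    direction: max
    basis: percent_of_energy
    target: 6.0
    intermediate: 9.0
  - nutrient: protein
    direction: min
    basis: percent_of_energy
    target: 18.0
    intermediate: 12.0
  - nutrient: cholesterol
    direction: max
    basis: per_1000_kcal
    target: 71.4
    intermediate: 107.1
  - nutrient: fiber
    direction: min
    basis: per_1000_kcal
    target: 14.8
    intermediate: 9.87
  - nutrient: magnesium
    direction: min
    basis: per_1000_kcal
    target: 238.0
    intermediate: 158.67
  - nutrient: calcium
    direction: min
    basis: per_1000_kcal
    target: 590.0
    intermediate: 393.33
  - nutrient: potassium
    direction: min
    basis: per_1000_kcal
    target: 2238.0
    intermediate: 1492.0
  - nutrient: sodium
    direction: max
    basis: per_day
    target: 2400.0
    intermediate: 3600.0
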