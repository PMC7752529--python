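"""Generate a complete synthetic trial dataset and summarize it.

Writes the four analysis-ready CSVs (daily diary, 24-hour recalls, roster,
outcomes) plus the latent truth, then reports what the study's own
engagement and validity rules see in the generated data.
"""

from pathlib import Path

import pandas as pd

from dashcloud import CohortParams, generate_cohort

outdir = Path("scratch/example_cohort")
cohort = generate_cohort(CohortParams(n_participants=59, seed=2017), outdir=outdir)

print("files:", ", ".join(p.name for p in sorted(outdir.glob("*.csv"))))
print(f"participants: {len(cohort.roster)} "
      f"({(cohort.roster.arm == 'intervention').sum()} intervention / "
      f"{(cohort.roster.arm == 'comparator').sum()} comparator)")
print(f"diary rows: {len(cohort.intake)}, recall rows: {len(cohort.recalls)}")

o = cohort.outcomes
print(f"baseline DASH (recall-scored): mean {o.baseline_dash.mean():.2f} "
      f"(SD {o.baseline_dash.std():.2f})")
print(f"valid recall sets: baseline {o.baseline_dash_valid.mean():.0%}, "
      f"month 3 {o.month3_dash_valid.mean():.0%}")
print(f"3-month follow-up present: {o.month3_sbp.notna().mean():.0%}")
print("\nEverything is reproducible: the same params and seed regenerate")
print("byte-identical files.")
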