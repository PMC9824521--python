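"""Simulate a small elderly-household cohort and look at what it contains.

The generator emits the four CSV-shaped tables the pipeline consumes
(subjects, heart rate, activity intervals, questionnaire answers) plus a
separate ground-truth table of the latent daily stress state that drives
them — useful for checking signal recovery, never used as a feature.
"""

import adlstress as a

config = a.CohortConfig(n_households=3, n_days=7, seed=1)
cohort = a.simulate_cohort(config)

print(f"subjects ({len(cohort.subjects)}):")
print(cohort.subjects.to_string(index=False))
print(f"\nheart-rate samples: {len(cohort.heart_rate)} "
      f"(every {config.hr_sample_period} s, {config.missingness:.0%} dropout)")
print(f"activity intervals: {len(cohort.activities)}")
print("\nfirst day of S01:")
s01 = cohort.activities[cohort.activities.subject_id == "S01"]
print(s01.head(8).to_string(index=False))
print("\nquestionnaire answers (1-5 Likert, MQ reverse-coded):")
print(cohort.answers.head(6).to_string(index=False))

# Each simulated day is tiled by activity intervals; the latent stress
# state shapes RRI dispersion, bedtimes, and the Likert answers.
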