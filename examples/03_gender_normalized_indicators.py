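"""Gender-normalized activity, biometric, and mixed indicators.

Raw time shares (Ar) and per-activity Lorenz areas (Br) are not comparable
across a cohort where housework is split along gender lines, so both are
divided by their gender-group mean: Ai and Bi average exactly 1 within
each (gender, activity) group, and Mixed = Ai * Bi combines how *long* a
subject does an activity with how *stressed* their heart rhythm is while
doing it.
"""

import adlstress as a

cohort = a.simulate_cohort(a.CohortConfig(n_households=4, n_days=5, seed=3))
frame, _ = a.build_dataset(cohort, "proposed2")
genders = cohort.subjects.set_index("subject_id")["gender"]

import pandas as pd

raw = []
for _, row in frame.iterrows():
    for act in a.ACTIVITIES:
        raw.append({
            "subject_id": row["subject_id"], "date": row["date"],
            "question": row["question"], "activity": act,
            "gender": genders[row["subject_id"]],
            "Ar": row[f"time_24h__{act}"] / 86400.0,
            "Br": row[f"lp_area_24h__{act}"],
        })
table = a.build_indicator_table(pd.DataFrame(raw))

one = table[(table.subject_id == "S01")
            & (table.date == "2023-03-03") & (table.question == "NQ")]
print("indicators for S01 (woman), 2023-03-03, night questionnaire:")
print(one[["activity", "Ar", "Br", "Ai", "Bi", "Mixed"]]
      .to_string(index=False, float_format=lambda v: f"{v:8.3f}"))

check = table.groupby(["date", "question", "gender", "activity"])["Ai"].mean()
print(f"\nnormalization identity: group means of Ai span "
      f"[{check.min():.12f}, {check.max():.12f}] (all exactly 1)")

# Ai > 1: this subject spends more time on the activity than the average
# woman in the cohort that day; Bi > 1: her heart shows *more* variability
# (less stress) during it; Mixed weighs the two together.
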