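"""Derive study outcomes and categorical features from raw questionnaire records.

Builds three subjects by hand, applies the clinical cut points to their raw
measurements and derives the four binary symptom outcomes from the seven
ordinal items.
"""

import pandas as pd

from gmdhscreen.outcomes import derive_outcomes
from gmdhscreen.schema import QuestionnaireRecord, categorize_measurements

subjects = [
    # three weekly-or-worse emotional items -> mild-to-moderate symptoms
    QuestionnaireRecord(
        subject_id="s1", q1="once_a_week", q2="every_day",
        q3="more_than_once_a_week", q4="never", q5="rarely",
        q6="no", q7="rarely",
        age_years=13, sleep_hours=4.5, screen_hours=5.0, waist_cm=62,
        height_cm=118, birth_weight_g=2400, family_size=6,
        life_satisfaction=4, breakfast_days_per_week=1,
    ),
    # depression item positive, everything else quiet
    QuestionnaireRecord(
        subject_id="s2", q1="never", q2="never", q3="never", q4="never",
        q5="never", q6="yes", q7="never",
        age_years=9, sleep_hours=9.0, screen_hours=1.0, waist_cm=50,
        height_cm=130, birth_weight_g=3300, family_size=4,
        life_satisfaction=8, breakfast_days_per_week=7,
    ),
    # worried most of the time (sleep-preventing) -> worriedness outcome
    QuestionnaireRecord(
        subject_id="s3", q1="rarely", q2="never", q3="once_a_week",
        q4="never", q5="never", q6="no", q7="most_of_the_time",
        age_years=17, sleep_hours=7.0, screen_hours=3.0, waist_cm=70,
        height_cm=165, birth_weight_g=4100, family_size=3,
        life_satisfaction=6, breakfast_days_per_week=4,
    ),
]

items = pd.DataFrame(
    [{q: getattr(r, q) for q in ("q1", "q2", "q3", "q4", "q5", "q6", "q7")}
     for r in subjects],
    index=[r.subject_id for r in subjects],
)
print("Binary outcomes (1 = symptom present):")
print(derive_outcomes(items))
# s1 flags mild_moderate (3 of 5 items at weekly+), s2 depression, s3
# worriedness; 'psychiatric' is the union of the three.

print("\nDerived categorical features for s1:")
for feature, level in categorize_measurements(subjects[0]).items():
    print(f"  {feature:22s} -> {level}")
# e.g. sleep 4.5 h falls in the lowest band, waist/height 62/118 = 0.53 > 0.5
# marks abdominal obesity, birth weight 2400 g is below the 2500 g cut.
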