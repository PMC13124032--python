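"""Generate a small synthetic perinatal wearable cohort and inspect it.

The generator draws, for each participant, an individual quadratic
gestational trend per feature (vertex week ~ N(33, 3) by default), daily
Gaussian noise, MCAR missingness, subgroup labels, and adverse/severe
events that shift feature means within +/-7 days.
"""

import dataclasses

from nof1gest import CohortConfig, generate_cohort

config = dataclasses.replace(CohortConfig(), n_participants=20, seed=42)
cohort = generate_cohort(config)

print(f"participants: {len(cohort.participants)}")
print(f"daily observation rows: {len(cohort.observations)} "
      f"({cohort.observations['value'].isna().mean():.0%} missing)")
print(f"events: {len(cohort.events)}")
print("\nfirst participant:")
print(cohort.participants.iloc[0])
print("\ntrue HRV quadratic coefficients (a*w^2 + b*w + c) and vertex week:")
print(cohort.ground_truth.coefficients.query("feature == 'hrv'").head())

# The vertex week is the gestational week at which the individual's
# trajectory bottoms out (its "inflection" in the weekly analysis); the
# printed values are the ground truth later estimators should recover.
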