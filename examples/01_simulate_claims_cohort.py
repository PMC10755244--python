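"""Generate a synthetic claims-style PTSD cohort and peek at its tables.

The generator lays down a latent severity process with treatment-confounder
feedback, then emits the four administrative tables (persons, diagnosis
claims, prescriptions, check-ups) an insurance database would hold.
"""

from msmcvd import SimParams, generate_cohort

params = SimParams(n_persons=2000, n_intervals=12, seed=42)
raw = generate_cohort(params)

print(f"persons: {len(raw.persons)} rows")
print(raw.persons.head(3).to_string(index=False))
print(f"\nclaims: {len(raw.claims)} rows (ICD-10, setting, procedure flags)")
print(raw.claims.head(3).to_string(index=False))
print(f"\nprescriptions: {len(raw.prescriptions)} rows "
      f"(ATC code, dose, days supplied)")
print(raw.prescriptions.head(3).to_string(index=False))

ever_rx = raw.prescriptions["person_id"].nunique() / len(raw.persons)
print(f"\never dispensed an antidepressant: {ever_rx:.1%}")
print(f"cardiovascular deaths recorded: {len(raw.deaths)}")
print("\nEvery person indexes at day 0 (first PTSD claim); follow-up runs in")
print("91-day intervals until the first MACE or the last insurance claim.")
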