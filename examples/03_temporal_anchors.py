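"""Derive index, lookback and first-symptom anchors for confirmed cases.

On validation-style synthetic data (where the generator plants the true
index event 76 days before the first specialist-unit visit), derives the
per-patient anchors, applies the eligibility filter, and prints the
first-symptom specialty distribution — the specialty under which each
patient's earliest coded symptom event was recorded.
"""

import datetime as dt

from ipahes import AnchorConfig, first_symptom_specialty_distribution, synth, validation_eligibility

ds = synth.generate(
    synth.GeneratorConfig(seed=3, subpopulations=[synth.phase2_case_spec(300)])
)
records = {r.patient_id: r for r in ds.records()}
gt = ds.ground_truth.set_index("patient_id")
visits = {pid: dt.date.fromisoformat(gt.loc[pid, "first_center_visit"]) for pid in records}

eligible, attrition = validation_eligibility(records, visits, list(records), AnchorConfig())
print("Validation-cohort attrition:")
for rule, n in attrition:
    print(f"  {rule:<24s} {n:>5d}")

a = next(iter(eligible.values()))
print(f"\nExample patient {a.patient_id}:")
print(f"  lookback {a.lookback_date}  <=  first symptom {a.first_symptom_date}"
      f"  <=  index {a.index_date}  <=  first center visit {a.first_center_visit}")

dist, n_absent = first_symptom_specialty_distribution(eligible.values())
print("\nFirst-symptom specialty distribution (% of patients with a symptom):")
for spc, pct in sorted(dist.items(), key=lambda kv: -kv[1]):
    print(f"  {spc:<20s} {pct:5.1f}")
print(f"  (no coded first symptom: {n_absent})")
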