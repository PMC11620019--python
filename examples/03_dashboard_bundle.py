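"""Build the five dashboard panels for one interaction rule.

Takes the tacrolimus + CYP3A5-genotyping surveillance rule from the demo
cohort and computes: affected patients over time, demographics, medical-unit
breakdown, pharmacology dosage coverage, and assay results by status.
"""

import tempfile

from cypscreen import build_bundle, detect, demo_profile, generate, load_rules

ds = generate(demo_profile(seed=1))
with tempfile.TemporaryDirectory() as td:
    rules = load_rules(ds.write(td)["kb"])
rule = next(r for r in rules if r.substrate == "tacrolimus")

hits = detect([rule], ds.prescriptions, ds.labs,
              period=ds.config.period_dg, analyte_map=ds.analyte_map)
bundle = build_bundle(
    rule, hits,
    prescriptions=ds.prescriptions, labs=ds.labs, patients=ds.patients,
    analyte_map=ds.analyte_map, period=ds.config.period_dg,
)

print(f"{bundle.cytochrome}: {bundle.substrate} + {bundle.perpetrator}")
print(f"affected patients: {bundle.n_patients}")
nonzero = [(b, c) for b, c in bundle.time_series if c][:6]
print(f"first monthly bins with hits: {nonzero}")
print(f"sex distribution: {bundle.sex_counts}")
print(f"busiest age bands: "
      f"{sorted(bundle.age_band_counts.items(), key=lambda kv: -kv[1])[:3]}")
print(f"unit breakdown: {bundle.unit_breakdown}")
print(f"dosage coverage: {bundle.dosage_coverage:.0%} of affected patients "
      "had a tacrolimus concentration assay")
print(f"assay results by status: {bundle.dosage_by_status}")
# Status counts are per assay event, not per patient: a patient assayed
# twice contributes two bars (export with dedupe_patient=True to keep only
# each patient's first assay).
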