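"""Render the boolean co-prescription query for one knowledge-base rule.

Loads the shipped worked example — flecainide (a CYP1A2 substrate, 13 UCD
dispensing codes) against norfloxacin (a CYP1A2 inhibitor, 12 codes) — and
renders the two-clause query used to interrogate a clinical data warehouse.
"""

import importlib.resources

from cypscreen import build_query, count_code_combinations, load_rules

DATA = importlib.resources.files("cypscreen") / "data"

(rule,) = load_rules(str(DATA / "example_kb.tsv"))
query = build_query(rule)

print(f"rule: {rule.cytochrome} {rule.substrate} --{rule.relation}--> "
      f"{rule.perpetrator}")
print(f"substrate codes:   {len(rule.substrate_codes)}")
print(f"perpetrator codes: {len(rule.perpetrator_codes)}")
print(f"code combinations: {count_code_combinations([rule])}")
print()
print(query.text)
# The query is true for a patient-day iff at least one dispensing code from
# each parenthesised clause was prescribed that day: 13 x 12 = 156 code
# pairs collapsed into one boolean expression.
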