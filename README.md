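# cypscreen

Screening of cytochrome-P450–mediated drug–drug and drug–genotype
co-prescriptions in hospital EHR event data.

## The problem

The hepatic cytochrome P450 (CYP450) enzyme family metabolizes most drugs.
When a *substrate* of an isoform is co-prescribed with a strong *inhibitor*
of that isoform, the substrate's blood concentration rises (overdose risk —
e.g. fluconazole inhibiting CYP3A4 raises tacrolimus levels, risking
nephrotoxicity); co-prescription with an *inducer* lowers it (underdose risk
— e.g. carbamazepine inducing the metabolism of paracetamol). A related
pharmacogenetic concern pairs a drug with a genotyping act: clopidogrel, a
prodrug activated by CYP2C19, is ineffective in carriers of loss-of-function
variants, so each clopidogrel prescription should trigger CYP2C19
genotyping.

`cypscreen` is a population-level screening tool for pharmacologists: given
an interaction knowledge base and flat EHR event files, it finds every
patient-day on which such a combination occurred, summarizes each
interaction (patients, hospitalization days, prescriptions), and computes
the per-interaction dashboard panels used to monitor whether affected
patients actually received therapeutic drug monitoring.

## The method

1. **Knowledge base** — a table of rules (cytochrome, substrate, relation
   ∈ {`p_inhib`, `p_induc`, `mutation`}, perpetrator) with each substance's
   UCD dispensing codes (13-digit French *unité commune de dispensation*
   identifiers). Rows where substrate and perpetrator are the same molecule
   are removed; code lists are intersected with the institutional formulary;
   the combination metric Σ |substrate codes| × |perpetrator codes| tracks
   the blow-up from substance pairs to code pairs.
2. **Query generation** — each drug–drug rule renders as the boolean
   two-clause query
   `(SUB1 or SUB2 or ...) and (PERP1 or PERP2 or ...)`,
   the exchange dialect for warehouse interrogation; a parser and an
   in-process evaluator make the dialect round-trippable and testable.
3. **Detection** — a hit is a (rule, patient, calendar day) with at least
   one substrate-code prescription and, on the same day, either a
   perpetrator-code prescription (drug–drug) or a genotyping lab act with a
   configured analyte (drug–genotype). Per rule:
   `n_patients` (distinct patients) ≤ `n_days` (distinct patient-days) and
   `n_patients` ≤ `n_prescriptions` (distinct matched substrate lines).
4. **Dashboards** — five panels per rule: patients over time (filterable by
   medical unit), sex/age demographics, unit breakdown, pharmacology dosage
   coverage (fraction of affected patients with a substrate concentration
   assay in the matching window), and assay results by status.
5. **Synthetic EHR** — a seeded generator plants exact co-occurrence counts
   and coverage fractions in a background of inert events, so every stage is
   verifiable against ground truth without hospital data.

## Worked example

```bash
python examples/01_worked_example_query.py
```

```
rule: CYP1A2 flecainid --p_inhib--> norfloxacin
substrate codes:   13
perpetrator codes: 12
code combinations: 156

(3400890352246 or 3400892468143 or ... or 3400894250951) and (3400891057980 or ... or 3400892884516)
```

Flecainide (13 dispensing codes) is a CYP1A2 substrate and norfloxacin (12
codes) an inhibitor: the 156 code pairs collapse into one query that is true
for any patient-day carrying at least one code from each clause.

Running the full pipeline on the shipped demo cohort
(`python examples/02_simulate_detect_summarize.py`) prints the screening
table, e.g.:

```
Cytochrome    Substrate    Type Inhibitor or inducer  Number of patients  Number of hospitalization days  Number of prescriptions
    CYP3A4  paracetamol p_induc        carbamazepine                  50                              55                       55
    ...
    CYP3A5   tacrolimus mutation      genotype cyp3a5                 675                            1411                     3336
```

50 patients had paracetamol and carbamazepine co-prescribed on at least one
shared hospitalization day; 675 patients had tacrolimus prescribed on the
same day as a CYP3A5 genotyping act (1411 patient-days, 3336 order lines).
`python examples/03_dashboard_bundle.py` then shows the tacrolimus
dashboard: 60% dosage coverage, assay statuses {below: 125, in_range: 148,
above: 132}, demographics and unit breakdowns.

## Command line

```bash
cypscreen simulate --seed 1 --out fixtures/
cypscreen run --kb fixtures/kb.tsv --formulary fixtures/formulary.txt \
    --prescriptions fixtures/prescriptions.tsv --labs fixtures/labs.tsv \
    --patients fixtures/patients.tsv --analyte-map fixtures/analyte_map.yaml \
    --out results/
```

Subcommands `validate-kb`, `filter`, `queries`, `detect`, `dashboard`,
`simulate`, and `run` mirror the pipeline stages; exit codes are 0
(success), 2 (validation failure), 3 (runtime failure).

## File formats

* **KB**: TSV with columns `cytochrome, substrate, relation, perpetrator,
  substrate_ucds, perpetrator_ucds`; code cells are `" or "`-separated.
* **Formulary**: one UCD code per line, `#` comments.
* **Events**: TSV with ISO-8601 dates — prescriptions
  (`event_id, patient_id, stay_id, day, code, unit`), labs
  (`event_id, patient_id, day, analyte, kind, value, status`), patients
  (`patient_id, sex, birth_date`).
* **Analyte map**: YAML with `dosage` (substrate → assay analyte codes) and
  `genotyping` (genotype-test label → act analyte codes) sections.

See `docs/methods.md` for the modeling choices and their rationale.
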