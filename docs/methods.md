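# Methods

## Detection model

A co-occurrence is defined at (patient, calendar day) granularity: a
drug–drug hit requires at least one prescription of a substrate dispensing
code and at least one of a perpetrator code for the same patient on the
same day; a drug–genotype hit pairs a substrate prescription with a
genotyping laboratory act on the same day. The same-day join is applied
uniformly to both rule kinds. The headline metric "number of
hospitalization days" counts distinct (patient, day) pairs, which only
makes sense under day-level joining; a stricter (patient, stay, day) join
is available for drug–drug rules via `join_on="stay_day"` for sites whose
stay identifiers are reliable. Lab events carry no stay identifier, so
mutation rules always join at day level.

"Number of prescriptions" is defined here as the number of distinct
*substrate* prescription events matched across a rule's hits. This is an
interpretive choice: it yields days = prescriptions when each hit day
carries one substrate order line (the common case for co-prescription
screening) while allowing prescriptions > days for intensively monitored
drugs such as tacrolimus, where several order lines can share a day.
Counting perpetrator lines as well would double-count the panel whose
subject is the substrate's exposure.

Ranking of rules is by a chosen metric (patients by default), descending,
with deterministic lexicographic tie-breaks on (cytochrome, substrate,
perpetrator) so that repeated runs order ties identically.

## Knowledge-base handling

Substance labels are canonicalized (whitespace-trimmed, case-folded) before
any comparison; the self-interaction filter removes rows whose substrate
and perpetrator canonicalize to the same string. Molecule identity beyond
the label (salts, stereoisomers, terminology-server synonymy) is out of
scope: a KB exported with inconsistent naming will under-remove self-pairs,
and the validation report is the place such rows surface.

UCD codes are validated as 13 decimal digits but their GTIN check digit is
not verified — the format check catches column slips and truncation, which
are the realistic failure modes in flat exports. The loader is strictly 1:1
with file rows (duplicates are reported, never silently collapsed), because
line counts before/after each filtering stage are themselves reporting
outputs.

The formulary filter intersects each rule's code lists with the
institutional code set and drops rules whose substrate side empties, or
whose perpetrator side empties for non-mutation rules (a mutation rule's
perpetrator is a lab act, not a drug, and legitimately has no codes). An
empty formulary raises instead of silently dropping everything, so "no
formulary supplied" is never confused with "no overlap". The filter is
idempotent and monotone in the formulary; both properties are tested.

## Query dialect

The rendered form is frozen: lowercase ` or ` / ` and `, one pair of
parentheses per clause, codes in knowledge-base order. There is no operator
precedence or nesting because the screening pipeline only ever generates
this two-clause shape; the parser is correspondingly strict and reports the
character offset of the first violation. Evaluation is set-intersection on
each clause, monotone in the present-code set.

## Dashboard aggregations

* Time bins are calendar days, ISO weeks, or calendar months; a patient is
  counted once per bin, and bins with zero count are materialized over the
  whole analysis period so exported series align across rules.
* Age is computed at the patient's first hit date and assigned to half-open
  bands, decades `[0,10) … [90,120)` by default (cohort demographics vary
  by site; the bands are a parameter).
* Dosage coverage = covered / affected patients, where "covered" means at
  least one substrate concentration assay in the matching window. The
  window defaults to *same stay* as a hit (monitoring extends beyond the
  co-prescription day: levels are adjusted during and after the
  combination); `same_day` and `period` are available. An empty denominator
  yields a missing value ("n/a"), not zero.
* Assay statuses are counted per event, so a patient assayed repeatedly
  contributes repeatedly — a known duplication in this kind of dashboard,
  kept deliberately and controllable with `dedupe_patient=True` (keeps each
  patient's earliest assay). The status vocabulary
  {below, in_range, above, unknown} is a pragmatic normalization: lab feeds
  rarely share a coding system, and any unrecognized status maps to
  `unknown`. If a feed provides numeric values with reference ranges the
  status column should be precomputed upstream; the package trusts it.
* Bundles are pydantic models; the JSON export is schema-stable and
  round-trips exactly, and the HTML export embeds all five panels as
  static charts.

## Synthetic cohort generator

The generator's purpose is sharp, deterministic ground truth rather than
epidemiologic realism. Three construction rules make planted counts exact:

1. every planted hit occupies a "virgin" (patient, day) cell — no other
   rule's planted events share it — so rules sharing a substance (e.g.
   paracetamol under several perpetrators, or clopidogrel as both a
   perpetrator drug and a genotyped substrate) can never create accidental
   hits or inflate each other's substrate-line counts;
2. rule patient sets are drawn disjointly from the cohort, making per-rule
   dosage-coverage fractions exact under every matching window;
3. background prescriptions use a code pool disjoint from all rule codes,
   and background labs use unmapped analytes, so background is inert by
   construction.

Configurations that violate feasibility (more planted days than
patient-day cells, duplicate substance pairs, prescriptions < days) are
rejected before any file is written. All randomness flows through one
`numpy` generator seeded from the config, and files are written in a fixed
sort order, so identical seeds give byte-identical fixtures.

Defaults: cohort ages ~ N(62, 18²) truncated to [0, 100] (hospital
inpatient populations skew old), sex ratio 0.5, two background
prescriptions and 0.5 background lab events per patient over the study
span, six medical units. Synthetic UCD codes are drawn in the `3400…`
13-digit space so format validation is exercised end to end.

The shipped `demo_profile` plants the magnitudes of a published hospital
deployment — drug–drug patient counts (50, 25, 21, 20, 13, 12, 12, 12)
over 2021-06-01..2021-09-30 and drug–genotype triples
(675 patients / 1411 days / 3336 prescriptions for tacrolimus + CYP3A5;
804 / 823 / 828 for clopidogrel + CYP2C19) over 2019-01-01..2021-09-30,
with planted dosage coverages of 0.30 (paracetamol), 0.60 (tacrolimus) and
0.50 (clopidogrel), three self-pair KB rows and two off-formulary rows —
so a demo run exercises every pipeline stage at realistic scale (~12,500
events, ~2 s end to end) and its report parallels the deployment visually.
Recovering these planted numbers verifies the pipeline's bookkeeping; it
does not re-derive any hospital result, which depends on that hospital's
warehouse and knowledge base.

What the generator does **not** emulate: co-prescription prevalence
patterns, dose regimens, transfers between units within a stay (each
synthetic patient has one stay), free-text lab results, or terminology
noise. Passing tests on synthetic data therefore demonstrate correctness
of the detection and aggregation logic, not performance of the screening
approach on real warehouse data.

## Analysis windows

The two analysis periods are first-class, mandatory configuration — the
drug–drug window defaults to 2021-06-01..2021-09-30 and the drug–genotype
window to 2019-01-01..2021-09-30 (genotyping is rarer, so a longer window
is needed for stable counts). Shrinking either period can only shrink
counts; this monotonicity is tested.

## Numerical and determinism choices

The analysis path (everything except `simulate`) contains no randomness.
All outputs are sorted deterministically: hits by (rule, patient, day),
summaries by rank metric with lexicographic tie-breaks, file manifests by
name. The run report records a SHA-256 configuration hash and per-file
output checksums so two runs can be compared mechanically. Planted
coverage fractions are exact only when `f × n_patients` is integral;
otherwise the nearest integer count of covered patients is planted.
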