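"""Seeded synthetic-EHR generator with plantable ground-truth interactions.

Stands in for a hospital data warehouse: emits a knowledge base, a
formulary, patient / prescription / lab event tables and an analyte map,
together with a ground-truth record of every planted co-occurrence.  The
construction is exact rather than statistical:

* each planted hit occupies its own (patient, day) cell — no two rules'
  planted events ever share one, so no accidental co-occurrence or
  substrate-count inflation can arise between rules sharing a substance;
* rule patient sets are drawn disjointly from the cohort, so per-rule
  dosage-coverage fractions are exact under every matching window;
* background prescriptions draw codes from a pool disjoint from every
  rule's code lists, and background lab events use unmapped analytes.

Under these constraints, detection on generated data recovers the planted
hit set exactly (no false positives or negatives), which makes end-to-end
tests sharp.  What this deliberately does NOT emulate is the messiness of
real warehouses (overlapping regimens, coding drift, free-text results).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError
from .events import AnalyteMap, Period

DEFAULT_UNITS = ("CARDIO", "NEPHRO", "HEPATO", "ICU", "GERIATRICS", "NEURO")

_MAX_RESAMPLE = 10_000


@dataclass(frozen=True)
class RuleSpec:
    """Skeleton of one interaction rule to plant.

    ``n_patients`` patients receive planted co-occurrences on ``n_days``
    distinct patient-days in total (each patient gets at least one), backed
    by ``n_prescriptions`` substrate order lines.  ``dosage_coverage`` plants
    a blood-concentration assay for exactly that fraction of the rule's
    patients (choose a fraction with integral ``f × n_patients``).
    """

    cytochrome: str
    substrate: str
    relation: str
    perpetrator: str
    n_patients: int
    n_days: int | None = None
    n_prescriptions: int | None = None
    n_substrate_codes: int = 3
    n_perpetrator_codes: int = 3
    dosage_coverage: float | None = None

    @property
    def days(self) -> int:
        return self.n_days if self.n_days is not None else self.n_patients

    @property
    def prescriptions(self) -> int:
        return self.n_prescriptions if self.n_prescriptions is not None else self.days

    @property
    def is_mutation(self) -> bool:
        return self.relation == "mutation"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int
    rules: tuple[RuleSpec, ...]
    n_patients: int = 200
    period_dd: Period = Period(dt.date(2021, 6, 1), dt.date(2021, 9, 30))
    period_dg: Period = Period(dt.date(2019, 1, 1), dt.date(2021, 9, 30))
    n_self_pair_rules: int = 0
    n_nonformulary_rules: int = 0
    background_rx_per_patient: float = 2.0
    background_lab_per_patient: float = 0.5
    n_background_codes: int = 30
    units: tuple[str, ...] = DEFAULT_UNITS
    sex_ratio_f: float = 0.5
    age_mean: float = 62.0
    age_sd: float = 18.0
    age_min: float = 0.0
    age_max: float = 100.0


@dataclass
class RuleTruth:
    """Planted ground truth for one rule."""

    rule_id: str
    patients: list[str]
    hit_days: list[tuple[str, str]]  # (patient_id, ISO day)
    n_prescriptions: int
    covered_patients: list[str]
    dosage_statuses: dict[str, str]  # lab event_id -> status


@dataclass
class GroundTruth:
    rules: dict[str, RuleTruth]
    self_pair_rule_ids: list[str]
    nonformulary_rule_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "self_pair_rule_ids": self.self_pair_rule_ids,
            "nonformulary_rule_ids": self.nonformulary_rule_ids,
            "rules": {
                rid: {
                    "patients": t.patients,
                    "hit_days": [list(hd) for hd in t.hit_days],
                    "n_prescriptions": t.n_prescriptions,
                    "covered_patients": t.covered_patients,
                    "dosage_statuses": t.dosage_statuses,
                }
                for rid, t in self.rules.items()
            },
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "GroundTruth":
        return cls(
            rules={
                rid: RuleTruth(
                    rule_id=rid,
                    patients=r["patients"],
                    hit_days=[tuple(hd) for hd in r["hit_days"]],
                    n_prescriptions=r["n_prescriptions"],
                    covered_patients=r["covered_patients"],
                    dosage_statuses=r["dosage_statuses"],
                )
                for rid, r in raw["rules"].items()
            },
            self_pair_rule_ids=raw["self_pair_rule_ids"],
            nonformulary_rule_ids=raw["nonformulary_rule_ids"],
        )


@dataclass
class SyntheticDataset:
    """In-memory result of one generation run."""

    kb: pd.DataFrame
    formulary: list[str]
    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    analyte_map: AnalyteMap
    ground_truth: GroundTruth
    config: SimulationConfig
    paths: dict[str, Path] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all fixture files (TSV + YAML + JSON) deterministically."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "kb": out / "kb.tsv",
            "formulary": out / "formulary.txt",
            "patients": out / "patients.tsv",
            "prescriptions": out / "prescriptions.tsv",
            "labs": out / "labs.tsv",
            "analyte_map": out / "analyte_map.yaml",
            "ground_truth": out / "ground_truth.json",
        }
        self.kb.to_csv(paths["kb"], sep="\t", index=False)
        paths["formulary"].write_text(
            "# synthetic formulary\n" + "\n".join(self.formulary) + "\n"
        )
        self.patients.to_csv(paths["patients"], sep="\t", index=False)
        self.prescriptions.to_csv(paths["prescriptions"], sep="\t", index=False)
        self.labs.to_csv(paths["labs"], sep="\t", index=False)
        self.analyte_map.to_yaml(paths["analyte_map"])
        paths["ground_truth"].write_text(
            json.dumps(self.ground_truth.to_dict(), indent=1, sort_keys=True) + "\n"
        )
        self.paths = paths
        return paths


def _check_feasible(config: SimulationConfig) -> None:
    # two rules over the same substance pair would share code lists and
    # cross-match each other's planted cells — exact planting is impossible
    seen_pairs: set[frozenset[str] | tuple[str, str]] = set()
    for r in config.rules:
        key = (
            (r.substrate, r.perpetrator)
            if r.is_mutation
            else frozenset((r.substrate, r.perpetrator))
        )
        if key in seen_pairs:
            raise GenerationError(
                f"two rules plant the same substance pair "
                f"{r.substrate}/{r.perpetrator}"
            )
        seen_pairs.add(key)
    total_patients = sum(r.n_patients for r in config.rules)
    if total_patients > config.n_patients:
        raise GenerationError(
            f"rules require {total_patients} distinct patients but the cohort "
            f"has only {config.n_patients}"
        )
    for spec in config.rules:
        period = config.period_dg if spec.is_mutation else config.period_dd
        if spec.n_patients < 0:
            raise GenerationError(f"{spec.substrate}/{spec.perpetrator}: "
                                  "n_patients must be >= 0")
        if spec.days < spec.n_patients:
            raise GenerationError(
                f"{spec.substrate}/{spec.perpetrator}: n_days ({spec.days}) "
                f"< n_patients ({spec.n_patients})"
            )
        if spec.prescriptions < spec.days:
            raise GenerationError(
                f"{spec.substrate}/{spec.perpetrator}: n_prescriptions "
                f"({spec.prescriptions}) < n_days ({spec.days})"
            )
        if spec.days > spec.n_patients * period.n_days:
            raise GenerationError(
                f"{spec.substrate}/{spec.perpetrator}: {spec.days} hit days do "
                f"not fit in {spec.n_patients} patients x {period.n_days} days"
            )
        if spec.dosage_coverage is not None and not (0 <= spec.dosage_coverage <= 1):
            raise GenerationError(
                f"{spec.substrate}/{spec.perpetrator}: dosage_coverage must be "
                f"in [0, 1], got {spec.dosage_coverage}"
            )
    # occupancy headroom so rejection sampling terminates quickly
    for period, specs in (
        (config.period_dd, [r for r in config.rules if not r.is_mutation]),
        (config.period_dg, [r for r in config.rules if r.is_mutation]),
    ):
        cells = config.n_patients * period.n_days
        need = sum(r.days for r in specs)
        if need > cells // 2:
            raise GenerationError(
                f"{need} planted hit days exceed half of the "
                f"{cells} available patient-day cells"
            )


def _new_code(rng: np.random.Generator, used: set[str]) -> str:
    for _ in range(_MAX_RESAMPLE):
        code = "3400" + "".join(str(d) for d in rng.integers(0, 10, size=9))
        if code not in used:
            used.add(code)
            return code
    raise GenerationError("exhausted the synthetic UCD code space")


def _sample_day(rng: np.random.Generator, period: Period) -> dt.date:
    return period.start + dt.timedelta(days=int(rng.integers(period.n_days)))


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Generate a synthetic cohort; deterministic for a given seed.

    Raises :class:`GenerationError` before producing anything if the planted
    counts cannot fit the cohort and periods.
    """
    _check_feasible(config)
    rng = np.random.default_rng(config.seed)

    # --- substances and codes (shared across rules naming the same substance)
    used_codes: set[str] = set()
    substance_codes: dict[str, tuple[str, ...]] = {}

    def codes_for(substance: str, n: int) -> tuple[str, ...]:
        if substance not in substance_codes:
            substance_codes[substance] = tuple(
                _new_code(rng, used_codes) for _ in range(n)
            )
        return substance_codes[substance]

    kb_rows: list[dict] = []
    dosage_map: dict[str, list[str]] = {}
    genotyping_map: dict[str, list[str]] = {}
    for spec in config.rules:
        sub_codes = codes_for(spec.substrate, spec.n_substrate_codes)
        perp_codes = (
            ()
            if spec.is_mutation
            else codes_for(spec.perpetrator, spec.n_perpetrator_codes)
        )
        kb_rows.append(
            {
                "cytochrome": spec.cytochrome,
                "substrate": spec.substrate,
                "relation": spec.relation,
                "perpetrator": spec.perpetrator,
                "substrate_ucds": " or ".join(sub_codes),
                "perpetrator_ucds": " or ".join(perp_codes),
            }
        )
        if spec.is_mutation:
            genotyping_map.setdefault(
                spec.perpetrator, [f"GENO-{spec.cytochrome}"]
            )
        if spec.dosage_coverage is not None:
            dosage_map.setdefault(spec.substrate, [f"DOS-{spec.substrate}"])
    rule_ids = [f"R{i + 1:04d}" for i in range(len(config.rules))]

    self_pair_ids: list[str] = []
    for i in range(config.n_self_pair_rules):
        substance = f"selfdrug{i + 1}"
        codes = codes_for(substance, 2)
        kb_rows.append(
            {
                "cytochrome": "CYP3A4",
                "substrate": substance,
                "relation": "p_inhib",
                "perpetrator": substance,
                "substrate_ucds": " or ".join(codes),
                "perpetrator_ucds": " or ".join(codes),
            }
        )
        self_pair_ids.append(f"R{len(kb_rows):04d}")

    nonformulary_ids: list[str] = []
    nonformulary_codes: set[str] = set()
    for i in range(config.n_nonformulary_rules):
        sub = tuple(_new_code(rng, used_codes) for _ in range(2))
        perp = tuple(_new_code(rng, used_codes) for _ in range(2))
        nonformulary_codes.update(sub + perp)
        kb_rows.append(
            {
                "cytochrome": "CYP2D6",
                "substrate": f"offdrug{i + 1}a",
                "relation": "p_induc",
                "perpetrator": f"offdrug{i + 1}b",
                "substrate_ucds": " or ".join(sub),
                "perpetrator_ucds": " or ".join(perp),
            }
        )
        nonformulary_ids.append(f"R{len(kb_rows):04d}")

    background_codes = [
        _new_code(rng, used_codes) for _ in range(config.n_background_codes)
    ]
    formulary = sorted(
        (used_codes - nonformulary_codes)
    )

    # --- cohort
    patient_ids = [f"P{i + 1:05d}" for i in range(config.n_patients)]
    sexes = ["F" if rng.random() < config.sex_ratio_f else "M"
             for _ in patient_ids]
    ref = config.period_dg.end
    ages = []
    for _ in patient_ids:
        for _ in range(_MAX_RESAMPLE):
            a = rng.normal(config.age_mean, config.age_sd)
            if config.age_min <= a <= config.age_max:
                ages.append(a)
                break
        else:
            raise GenerationError("age distribution truncation failed")
    birth_dates = [
        ref - dt.timedelta(days=int(a * 365.25)) for a in ages
    ]
    patients = pd.DataFrame(
        {"patient_id": patient_ids, "sex": sexes, "birth_date": birth_dates}
    )

    # --- planted events
    rx_rows: list[dict] = []
    lab_rows: list[dict] = []
    rx_n = 0
    lab_n = 0

    def add_rx(pid: str, day: dt.date, code: str) -> str:
        nonlocal rx_n
        rx_n += 1
        eid = f"RX{rx_n:06d}"
        rx_rows.append(
            {
                "event_id": eid,
                "patient_id": pid,
                "stay_id": f"S-{pid}",
                "day": day,
                "code": code,
                "unit": config.units[int(rng.integers(len(config.units)))],
            }
        )
        return eid

    def add_lab(pid: str, day: dt.date, analyte: str, kind: str,
                value: str, status: str) -> str:
        nonlocal lab_n
        lab_n += 1
        eid = f"LB{lab_n:06d}"
        lab_rows.append(
            {
                "event_id": eid,
                "patient_id": pid,
                "day": day,
                "analyte": analyte,
                "kind": kind,
                "value": value,
                "status": status,
            }
        )
        return eid

    occupied: set[tuple[str, dt.date]] = set()
    pool = list(patient_ids)
    truths: dict[str, RuleTruth] = {}
    for spec, rule_id in zip(config.rules, rule_ids):
        period = config.period_dg if spec.is_mutation else config.period_dd
        pick = rng.choice(len(pool), size=spec.n_patients, replace=False)
        rule_patients = [pool[i] for i in sorted(pick)]
        for i in sorted(pick, reverse=True):
            del pool[i]

        hit_days: list[tuple[str, dt.date]] = []
        for pid in rule_patients:
            for _ in range(_MAX_RESAMPLE):
                day = _sample_day(rng, period)
                if (pid, day) not in occupied:
                    break
            else:
                raise GenerationError("could not place a planted hit day")
            occupied.add((pid, day))
            hit_days.append((pid, day))
        for _ in range(spec.days - spec.n_patients):
            for _ in range(_MAX_RESAMPLE):
                pid = rule_patients[int(rng.integers(len(rule_patients)))]
                day = _sample_day(rng, period)
                if (pid, day) not in occupied:
                    break
            else:
                raise GenerationError("could not place an extra hit day")
            occupied.add((pid, day))
            hit_days.append((pid, day))

        sub_codes = substance_codes[spec.substrate]
        for pid, day in hit_days:
            add_rx(pid, day, sub_codes[int(rng.integers(len(sub_codes)))])
            if spec.is_mutation:
                add_lab(pid, day, genotyping_map[spec.perpetrator][0],
                        "genotyping", "", "unknown")
            else:
                perp_codes = substance_codes[spec.perpetrator]
                add_rx(pid, day,
                       perp_codes[int(rng.integers(len(perp_codes)))])
        for _ in range(spec.prescriptions - spec.days):
            pid, day = hit_days[int(rng.integers(len(hit_days)))]
            add_rx(pid, day, sub_codes[int(rng.integers(len(sub_codes)))])

        covered: list[str] = []
        statuses: dict[str, str] = {}
        if spec.dosage_coverage is not None:
            k = int(round(spec.dosage_coverage * spec.n_patients))
            chosen = rng.choice(len(rule_patients), size=k, replace=False)
            first_day = {}
            for pid, day in hit_days:
                if pid not in first_day or day < first_day[pid]:
                    first_day[pid] = day
            for i in sorted(chosen):
                pid = rule_patients[i]
                status = ("below", "in_range", "above")[int(rng.integers(3))]
                eid = add_lab(
                    pid, first_day[pid], dosage_map[spec.substrate][0],
                    "dosage", f"{rng.uniform(1, 20):.1f}", status,
                )
                covered.append(pid)
                statuses[eid] = status

        truths[rule_id] = RuleTruth(
            rule_id=rule_id,
            patients=sorted(rule_patients),
            hit_days=sorted((pid, d.isoformat()) for pid, d in hit_days),
            n_prescriptions=spec.prescriptions,
            covered_patients=sorted(covered),
            dosage_statuses=statuses,
        )

    # --- background noise (codes/analytes outside every rule: inert)
    for pid in patient_ids:
        for _ in range(int(rng.poisson(config.background_rx_per_patient))):
            add_rx(
                pid,
                _sample_day(rng, config.period_dg),
                background_codes[int(rng.integers(len(background_codes)))],
            )
        for _ in range(int(rng.poisson(config.background_lab_per_patient))):
            add_lab(
                pid,
                _sample_day(rng, config.period_dg),
                f"BG-LAB{int(rng.integers(5)) + 1}",
                "dosage",
                f"{rng.uniform(1, 20):.1f}",
                ("below", "in_range", "above", "unknown")[int(rng.integers(4))],
            )

    prescriptions = (
        pd.DataFrame(
            rx_rows,
            columns=["event_id", "patient_id", "stay_id", "day", "code", "unit"],
        )
        .sort_values(["patient_id", "day", "event_id"])
        .reset_index(drop=True)
    )
    labs = (
        pd.DataFrame(
            lab_rows,
            columns=["event_id", "patient_id", "day", "analyte", "kind",
                     "value", "status"],
        )
        .sort_values(["patient_id", "day", "event_id"])
        .reset_index(drop=True)
    )
    kb = pd.DataFrame(
        kb_rows,
        columns=["cytochrome", "substrate", "relation", "perpetrator",
                 "substrate_ucds", "perpetrator_ucds"],
    )
    analyte_map = AnalyteMap.from_dict(
        {"dosage": dosage_map, "genotyping": genotyping_map}
    )
    return SyntheticDataset(
        kb=kb,
        formulary=formulary,
        patients=patients,
        prescriptions=prescriptions,
        labs=labs,
        analyte_map=analyte_map,
        ground_truth=GroundTruth(
            rules=truths,
            self_pair_rule_ids=self_pair_ids,
            nonformulary_rule_ids=nonformulary_ids,
        ),
        config=config,
    )


def demo_profile(seed: int = 2021) -> SimulationConfig:
    """Shipped demo: a cohort whose planted counts echo a published hospital
    screening report — eight drug–drug rules with 50/25/21/20/13/12/12/12
    affected patients over a four-month window, and two pharmacogenetic
    surveillance rules (tacrolimus + CYP3A5 genotyping, 675 patients;
    clopidogrel + CYP2C19 genotyping, 804 patients) over 2019–2021 —
    so the demo report visually parallels a real deployment at magnitude.
    """
    dd = [
        ("CYP3A4", "paracetamol", "p_induc", "carbamazepine", 50, 55, 55, 0.3),
        ("CYP3A4", "atorvastine", "p_inhib", "ticagrelor", 25, 26, 26, None),
        ("CYP3A4", "paracetamol", "p_inhib", "verapamil", 21, 21, 21, None),
        ("CYP2B6", "tramadol", "p_inhib", "clopidogrel", 20, 20, 20, None),
        ("CYP3A4", "pantoprazole", "p_inhib", "ticagrelor", 13, 14, 14, None),
        ("CYP2D6", "oxycodone", "p_inhib", "paroxetine", 12, 12, 12, None),
        ("CYP2D6", "ondansetron", "p_inhib", "paroxetine", 12, 12, 12, None),
        ("CYP3A4", "paracetamol", "p_inhib", "ticagrelor", 12, 12, 12, None),
    ]
    dg = [
        ("CYP3A5", "tacrolimus", "mutation", "genotype cyp3a5",
         675, 1411, 3336, 0.6),
        ("CYP2C19", "clopidogrel", "mutation", "genotype cyp2c19",
         804, 823, 828, 0.5),
    ]
    rules = tuple(
        RuleSpec(
            cytochrome=c, substrate=s, relation=rel, perpetrator=p,
            n_patients=np_, n_days=nd, n_prescriptions=nrx,
            dosage_coverage=cov,
        )
        for c, s, rel, p, np_, nd, nrx, cov in dd + dg
    )
    return SimulationConfig(
        seed=seed,
        rules=rules,
        n_patients=2000,
        n_self_pair_rules=3,
        n_nonformulary_rules=2,
    )
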