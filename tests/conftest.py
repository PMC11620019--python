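import datetime as dt
import importlib.resources

import pandas as pd
import pytest

from cypscreen import (
    InteractionRule,
    Period,
    RuleSpec,
    SimulationConfig,
    demo_profile,
    generate,
)

DATA = importlib.resources.files("cypscreen") / "data"


@pytest.fixture(scope="session")
def example_rule() -> InteractionRule:
    """The shipped flecainide/norfloxacin worked example (13 + 12 codes)."""
    from cypscreen import load_rules

    return load_rules(str(DATA / "example_kb.tsv"))[0]


@pytest.fixture(scope="session")
def example_query_text() -> str:
    return (DATA / "example_query.txt").read_text().strip()


def make_rule(
    rule_id="R0001",
    cytochrome="CYP3A4",
    substrate="druga",
    relation="p_inhib",
    perpetrator="drugb",
    substrate_codes=("3400000000001",),
    perpetrator_codes=("3400000000002",),
) -> InteractionRule:
    return InteractionRule(
        rule_id=rule_id,
        cytochrome=cytochrome,
        substrate=substrate,
        relation=relation,
        perpetrator=perpetrator,
        substrate_codes=tuple(substrate_codes),
        perpetrator_codes=tuple(perpetrator_codes),
    )


def rx_frame(rows):
    """Prescription events from (event_id, patient, stay, day, code, unit)."""
    return pd.DataFrame(
        [
            {
                "event_id": e,
                "patient_id": p,
                "stay_id": s,
                "day": dt.date.fromisoformat(d),
                "code": c,
                "unit": u,
            }
            for e, p, s, d, c, u in rows
        ],
        columns=["event_id", "patient_id", "stay_id", "day", "code", "unit"],
    )


def lab_frame(rows):
    """Lab events from (event_id, patient, day, analyte, kind, value, status)."""
    return pd.DataFrame(
        [
            {
                "event_id": e,
                "patient_id": p,
                "day": dt.date.fromisoformat(d),
                "analyte": a,
                "kind": k,
                "value": v,
                "status": st,
            }
            for e, p, d, a, k, v, st in rows
        ],
        columns=["event_id", "patient_id", "day", "analyte", "kind", "value",
                 "status"],
    )


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A compact cohort: two drug-drug rules and one mutation rule."""
    defaults = dict(
        seed=seed,
        n_patients=40,
        period_dd=Period(dt.date(2021, 6, 1), dt.date(2021, 7, 31)),
        period_dg=Period(dt.date(2021, 1, 1), dt.date(2021, 7, 31)),
        rules=(
            RuleSpec("CYP3A4", "subx", "p_inhib", "perpx",
                     n_patients=8, n_days=10, n_prescriptions=12,
                     dosage_coverage=0.5),
            RuleSpec("CYP2D6", "suby", "p_induc", "perpy", n_patients=5),
            RuleSpec("CYP2C19", "subz", "mutation", "genotype z",
                     n_patients=6, n_days=9, n_prescriptions=11,
                     dosage_coverage=0.5),
        ),
        n_self_pair_rules=2,
        n_nonformulary_rules=1,
        background_rx_per_patient=1.5,
        background_lab_per_patient=0.5,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(small_config())


@pytest.fixture(scope="session")
def demo_dataset():
    """The shipped demo profile (planted counts echo a hospital deployment)."""
    return generate(demo_profile(seed=1234))
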