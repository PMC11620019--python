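"""Co-occurrence detection in EHR event streams and summary metrics.

A hit is one (rule, patient, day) where the substrate drug and the
perpetrator — another drug, or for mutation rules a genotyping act — occur
on the same calendar day for the same patient.  Same-day joining is used
uniformly for both rule kinds; the join key can optionally be tightened to
(patient, stay, day) for drug–drug rules.

Summaries reproduce the screening report metrics per rule:

* ``n_patients``      — distinct patients with ≥1 hit
* ``n_days``          — distinct (patient, day) pairs (hospitalization days)
* ``n_prescriptions`` — distinct matched substrate prescription events

which satisfy n_patients ≤ n_days and n_patients ≤ n_prescriptions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError
from .events import AnalyteMap, Period
from .kb import InteractionRule


@dataclass(frozen=True, order=True)
class InteractionHit:
    """One detected (rule, patient, day) co-occurrence.

    ``perpetrator_event_ids`` are prescription ids for drug–drug rules and
    lab-event ids for mutation rules.  Both lists are non-empty and all
    referenced events share the hit's patient and day.
    """

    rule_id: str
    patient_id: str
    day: dt.date
    substrate_event_ids: tuple[str, ...]
    perpetrator_event_ids: tuple[str, ...]


@dataclass(frozen=True)
class InteractionSummary:
    rule_id: str
    n_patients: int
    n_days: int
    n_prescriptions: int
    period: Period


def _ids_by_key(df: pd.DataFrame, keys: list[str]) -> dict[tuple, tuple[str, ...]]:
    if df.empty:
        return {}
    grouped = df.sort_values("event_id").groupby(keys)["event_id"]
    return {k if isinstance(k, tuple) else (k,): tuple(v) for k, v in grouped}


def detect(
    rules: Sequence[InteractionRule],
    prescriptions: pd.DataFrame,
    labs: pd.DataFrame | None = None,
    *,
    period: Period,
    analyte_map: AnalyteMap | None = None,
    join_on: str = "day",
) -> list[InteractionHit]:
    """Detect all rule co-occurrences within ``period``.

    Drug–drug rules match one substrate-code and one perpetrator-code
    prescription on the same patient-day (``join_on="stay_day"`` additionally
    requires the same stay).  Mutation rules match a substrate-code
    prescription with a genotyping lab event whose analyte is configured for
    the rule's genotype-test label; mutation rules always join at
    patient-day granularity (lab events carry no stay).

    Raises :class:`ConfigurationError` if a mutation rule is present but the
    analyte map lacks its genotype label (the rule is named in the message).
    """
    if join_on not in ("day", "stay_day"):
        raise ConfigurationError(f"join_on must be 'day' or 'stay_day', got {join_on!r}")
    p = prescriptions[
        (prescriptions["day"] >= period.start) & (prescriptions["day"] <= period.end)
    ]
    hits: list[InteractionHit] = []
    for rule in rules:
        sub = p[p["code"].isin(rule.substrate_codes)]
        if rule.is_mutation:
            if analyte_map is None:
                raise ConfigurationError(
                    f"mutation rule {rule.rule_id} ({rule.substrate} / "
                    f"{rule.perpetrator}) requires an analyte map"
                )
            analytes = analyte_map.genotyping_analytes(rule.perpetrator)
            if labs is None:
                raise ConfigurationError(
                    f"mutation rule {rule.rule_id}: no lab events supplied"
                )
            perp = labs[
                (labs["kind"] == "genotyping")
                & labs["analyte"].isin(analytes)
                & (labs["day"] >= period.start)
                & (labs["day"] <= period.end)
            ]
            keys = ["patient_id", "day"]
            sub_ids = _ids_by_key(sub, keys)
            perp_ids = _ids_by_key(perp, keys)
        else:
            perp = p[p["code"].isin(rule.perpetrator_codes)]
            keys = ["patient_id", "day"] if join_on == "day" else [
                "patient_id", "stay_id", "day"]
            sub_ids = _ids_by_key(sub, keys)
            perp_ids = _ids_by_key(perp, keys)
        for key in sub_ids.keys() & perp_ids.keys():
            patient_id, day = key[0], key[-1]
            hits.append(
                InteractionHit(
                    rule_id=rule.rule_id,
                    patient_id=patient_id,
                    day=day,
                    substrate_event_ids=sub_ids[key],
                    perpetrator_event_ids=perp_ids[key],
                )
            )
    hits.sort(key=lambda h: (h.rule_id, h.patient_id, h.day))
    return hits


def summarize(
    hits: Iterable[InteractionHit], *, period: Period
) -> list[InteractionSummary]:
    """Per-rule summary metrics over a hit list.

    ``n_prescriptions`` counts distinct matched substrate prescription
    events: a day with two substrate order lines contributes two, while the
    perpetrator side is not counted.
    """
    by_rule: dict[str, list[InteractionHit]] = {}
    for h in hits:
        by_rule.setdefault(h.rule_id, []).append(h)
    summaries = []
    for rule_id in sorted(by_rule):
        rhits = by_rule[rule_id]
        patients = {h.patient_id for h in rhits}
        days = {(h.patient_id, h.day) for h in rhits}
        rx = {e for h in rhits for e in h.substrate_event_ids}
        summaries.append(
            InteractionSummary(
                rule_id=rule_id,
                n_patients=len(patients),
                n_days=len(days),
                n_prescriptions=len(rx),
                period=period,
            )
        )
    return summaries


_METRICS = {
    "patients": lambda s: s.n_patients,
    "days": lambda s: s.n_days,
    "prescriptions": lambda s: s.n_prescriptions,
}


def rank_rules(
    summaries: Sequence[InteractionSummary],
    rules: Sequence[InteractionRule],
    *,
    by: str = "patients",
) -> list[InteractionSummary]:
    """Order summaries by a metric, descending; ties broken lexicographically
    by (cytochrome, substrate, perpetrator) so output order is deterministic.
    """
    if by not in _METRICS:
        raise ConfigurationError(
            f"rank metric must be one of {sorted(_METRICS)}, got {by!r}"
        )
    rule_index = {r.rule_id: r for r in rules}
    metric = _METRICS[by]

    def key(s: InteractionSummary):
        rule = rule_index.get(s.rule_id)
        tie = rule.sort_key if rule is not None else (s.rule_id, "", "")
        return (-metric(s), tie)

    return sorted(summaries, key=key)


def hits_to_frame(hits: Iterable[InteractionHit]) -> pd.DataFrame:
    """Hit list as a DataFrame (export layout; id lists space-joined)."""
    return pd.DataFrame(
        [
            {
                "rule_id": h.rule_id,
                "patient_id": h.patient_id,
                "day": h.day.isoformat(),
                "substrate_event_ids": " ".join(h.substrate_event_ids),
                "perpetrator_event_ids": " ".join(h.perpetrator_event_ids),
            }
            for h in hits
        ],
        columns=[
            "rule_id", "patient_id", "day",
            "substrate_event_ids", "perpetrator_event_ids",
        ],
    )


def summaries_to_frame(
    summaries: Sequence[InteractionSummary], rules: Sequence[InteractionRule]
) -> pd.DataFrame:
    """Summary table mirroring the screening-report column layout."""
    rule_index = {r.rule_id: r for r in rules}
    rows = []
    for s in summaries:
        r = rule_index[s.rule_id]
        rows.append(
            {
                "Cytochrome": r.cytochrome,
                "Substrate": r.substrate,
                "Type": r.relation,
                "Inhibitor or inducer": r.perpetrator,
                "Number of patients": s.n_patients,
                "Number of hospitalization days": s.n_days,
                "Number of prescriptions": s.n_prescriptions,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Cytochrome", "Substrate", "Type", "Inhibitor or inducer",
            "Number of patients", "Number of hospitalization days",
            "Number of prescriptions",
        ],
    )
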