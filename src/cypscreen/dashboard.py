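"""Dashboard panel aggregations for one interaction rule over one period.

Five panels, mirroring a per-interaction monitoring dashboard:

1. time series of affected patients (filterable by medical unit);
2. demographics of affected patients (sex, age bands);
3. breakdown of affected patients by medical unit;
4. pharmacology dosage coverage — the fraction of affected patients who had
   a blood-concentration assay of the substrate within the matching window;
5. dosage results by status (below / in range / above / unknown) over the
   matched assay events.

Panel 5 counts *events*, not patients: a patient assayed several times
contributes several bars.  This duplication is intentional and documented —
deduplication to each patient's first assay is available via
``dedupe_patient=True``.
"""

from __future__ import annotations

import base64
import datetime as dt
import io
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .errors import ConfigurationError, DashboardError
from .events import DOSAGE_STATUSES, AnalyteMap, Period
from .detect import InteractionHit
from .kb import InteractionRule

#: Default age bands: decades, half-open [lo, hi), last band capped at 120.
DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 10) for lo in range(0, 90, 10)
) + ((90, 120),)

DOSAGE_WINDOWS = ("same_day", "same_stay", "period")


class DashboardBundle(BaseModel):
    """All five panel datasets for one rule over one period (JSON-stable)."""

    rule_id: str
    cytochrome: str
    substrate: str
    relation: str
    perpetrator: str
    period: str
    n_patients: int = Field(ge=0)
    time_series: list[tuple[str, int]]
    sex_counts: dict[str, int]
    age_band_counts: dict[str, int]
    unit_breakdown: dict[str, int]
    dosage_coverage: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    dosage_by_status: dict[str, int]


def _unit_of_event(prescriptions: pd.DataFrame) -> dict[str, str]:
    return dict(zip(prescriptions["event_id"], prescriptions["unit"]))


def _hit_units(hit: InteractionHit, unit_of: dict[str, str]) -> set[str]:
    return {unit_of[e] for e in hit.substrate_event_ids if e in unit_of}


def _bin_label(day: dt.date, bin: str) -> str:
    if bin == "day":
        return day.isoformat()
    if bin == "week":
        year, week, _ = day.isocalendar()
        return f"{year}-W{week:02d}"
    if bin == "month":
        return f"{day.year}-{day.month:02d}"
    raise ConfigurationError(f"bin must be day, week or month, got {bin!r}")


def time_series(
    hits: Sequence[InteractionHit],
    prescriptions: pd.DataFrame,
    period: Period,
    *,
    bin: str = "month",
    unit_filter: str | None = None,
) -> list[tuple[str, int]]:
    """Distinct affected patients per time bin, zero bins included.

    A patient is counted once per bin (but may appear in several bins).  With
    ``unit_filter``, only hits whose substrate prescriptions include the unit
    count; an unknown unit label raises listing the known units.
    """
    unit_of = _unit_of_event(prescriptions)
    if unit_filter is not None:
        known = sorted(set(prescriptions["unit"]))
        if unit_filter not in known:
            raise DashboardError(
                f"unknown unit {unit_filter!r}; known units: {known}"
            )
    bins = {_bin_label(d, bin): set() for d in period.days()}
    for h in hits:
        if h.day not in period:
            continue
        if unit_filter is not None and unit_filter not in _hit_units(h, unit_of):
            continue
        bins[_bin_label(h.day, bin)].add(h.patient_id)
    return [(label, len(patients)) for label, patients in bins.items()]


def _age_at(birth: dt.date, on: dt.date) -> int:
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def demographics(
    hits: Sequence[InteractionHit],
    patients: pd.DataFrame,
    *,
    age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
) -> tuple[dict[str, int], dict[str, int]]:
    """(sex counts, age-band counts) over affected patients.

    Each affected patient counts once; age is taken at the patient's first
    hit date and assigned to the half-open band [lo, hi).  A hit whose
    patient is absent from the patient table raises naming the patient.
    """
    info = patients.set_index("patient_id")
    first_hit: dict[str, dt.date] = {}
    for h in hits:
        if h.patient_id not in first_hit or h.day < first_hit[h.patient_id]:
            first_hit[h.patient_id] = h.day
    sex_counts: dict[str, int] = {}
    band_counts: dict[str, int] = {f"[{lo},{hi})": 0 for lo, hi in age_bands}
    for pid, day in sorted(first_hit.items()):
        if pid not in info.index:
            raise DashboardError(f"patient {pid!r} not found in patient table")
        row = info.loc[pid]
        sex_counts[row["sex"]] = sex_counts.get(row["sex"], 0) + 1
        age = _age_at(row["birth_date"], day)
        for lo, hi in age_bands:
            if lo <= age < hi:
                band_counts[f"[{lo},{hi})"] += 1
                break
        else:
            raise DashboardError(
                f"patient {pid!r}: age {age} falls in no configured band"
            )
    return sex_counts, band_counts


def unit_breakdown(
    hits: Sequence[InteractionHit], prescriptions: pd.DataFrame
) -> dict[str, int]:
    """Distinct affected patients per medical unit.

    A patient hit in several units counts in each, so the column total may
    exceed the rule's patient count.
    """
    unit_of = _unit_of_event(prescriptions)
    per_unit: dict[str, set[str]] = {}
    for h in hits:
        for u in _hit_units(h, unit_of):
            per_unit.setdefault(u, set()).add(h.patient_id)
    return {u: len(p) for u, p in sorted(per_unit.items())}


def _stay_ranges(prescriptions: pd.DataFrame) -> dict[str, tuple[dt.date, dt.date]]:
    ranges: dict[str, tuple[dt.date, dt.date]] = {}
    for stay, grp in prescriptions.groupby("stay_id")["day"]:
        ranges[stay] = (grp.min(), grp.max())
    return ranges


def matched_dosage_events(
    hits: Sequence[InteractionHit],
    labs: pd.DataFrame,
    rule: InteractionRule,
    analyte_map: AnalyteMap,
    *,
    prescriptions: pd.DataFrame,
    window: str = "same_stay",
    period: Period | None = None,
) -> pd.DataFrame:
    """Dosage lab events of the rule's substrate matched to affected patients.

    The matching window is ``same_day`` (assay on a hit day), ``same_stay``
    (assay within the day span of a stay containing a substrate hit event —
    concentration monitoring usually extends beyond the co-prescription day),
    or ``period`` (anywhere in the analysis period).
    """
    if window not in DOSAGE_WINDOWS:
        raise ConfigurationError(
            f"dosage window must be one of {DOSAGE_WINDOWS}, got {window!r}"
        )
    analytes = analyte_map.dosage_analytes(rule.substrate)
    dosages = labs[(labs["kind"] == "dosage") & labs["analyte"].isin(analytes)]
    affected = {h.patient_id for h in hits}
    dosages = dosages[dosages["patient_id"].isin(affected)]
    if dosages.empty:
        return dosages
    if window == "same_day":
        hit_days = {(h.patient_id, h.day) for h in hits}
        mask = [
            (r.patient_id, r.day) in hit_days for r in dosages.itertuples()
        ]
        return dosages[mask]
    if window == "period":
        if period is None:
            raise ConfigurationError("window='period' requires a period")
        return dosages[(dosages["day"] >= period.start)
                       & (dosages["day"] <= period.end)]
    # same_stay: lab day within the span of a stay holding a substrate event
    stay_of_event = dict(zip(prescriptions["event_id"], prescriptions["stay_id"]))
    ranges = _stay_ranges(prescriptions)
    spans: dict[str, list[tuple[dt.date, dt.date]]] = {}
    for h in hits:
        for e in h.substrate_event_ids:
            stay = stay_of_event.get(e)
            if stay is not None and stay in ranges:
                spans.setdefault(h.patient_id, []).append(ranges[stay])
    mask = [
        any(lo <= r.day <= hi for lo, hi in spans.get(r.patient_id, []))
        for r in dosages.itertuples()
    ]
    return dosages[mask]


def dosage_coverage(
    hits: Sequence[InteractionHit],
    labs: pd.DataFrame,
    rule: InteractionRule,
    analyte_map: AnalyteMap,
    *,
    prescriptions: pd.DataFrame,
    window: str = "same_stay",
    period: Period | None = None,
) -> float | None:
    """Fraction of affected patients with ≥1 matched dosage assay.

    ``None`` (rendered "n/a") when there are no affected patients — an
    undefined ratio is not zero coverage.
    """
    affected = {h.patient_id for h in hits}
    if not affected:
        return None
    matched = matched_dosage_events(
        hits, labs, rule, analyte_map,
        prescriptions=prescriptions, window=window, period=period,
    )
    covered = set(matched["patient_id"]) if not matched.empty else set()
    return len(covered) / len(affected)


def dosage_by_status(
    hits: Sequence[InteractionHit],
    labs: pd.DataFrame,
    rule: InteractionRule,
    analyte_map: AnalyteMap,
    *,
    prescriptions: pd.DataFrame,
    window: str = "same_stay",
    period: Period | None = None,
    dedupe_patient: bool = False,
) -> dict[str, int]:
    """Counts of matched dosage events by status.

    Each matched event counts once; with ``dedupe_patient=True`` only each
    patient's first (earliest day, then event id) assay is kept.
    """
    matched = matched_dosage_events(
        hits, labs, rule, analyte_map,
        prescriptions=prescriptions, window=window, period=period,
    )
    if matched.empty:
        return {}
    if dedupe_patient:
        matched = (
            matched.sort_values(["day", "event_id"])
            .groupby("patient_id", as_index=False)
            .first()
        )
    counts: dict[str, int] = {}
    for status in matched["status"]:
        status = status if status in DOSAGE_STATUSES else "unknown"
        counts[status] = counts.get(status, 0) + 1
    return {s: counts[s] for s in DOSAGE_STATUSES if s in counts}


def build_bundle(
    rule: InteractionRule,
    hits: Sequence[InteractionHit],
    *,
    prescriptions: pd.DataFrame,
    labs: pd.DataFrame,
    patients: pd.DataFrame,
    analyte_map: AnalyteMap,
    period: Period,
    bin: str = "month",
    window: str = "same_stay",
    age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
    dedupe_patient: bool = False,
) -> DashboardBundle:
    """Assemble the five panels for one rule."""
    rhits = [h for h in hits if h.rule_id == rule.rule_id]
    sex_counts, band_counts = demographics(rhits, patients, age_bands=age_bands)
    try:
        coverage = dosage_coverage(
            rhits, labs, rule, analyte_map,
            prescriptions=prescriptions, window=window, period=period,
        )
        statuses = dosage_by_status(
            rhits, labs, rule, analyte_map,
            prescriptions=prescriptions, window=window, period=period,
            dedupe_patient=dedupe_patient,
        )
    except ConfigurationError:
        # No dosage assay configured for this substrate: panels 4–5 are empty.
        coverage, statuses = None, {}
    return DashboardBundle(
        rule_id=rule.rule_id,
        cytochrome=rule.cytochrome,
        substrate=rule.substrate,
        relation=rule.relation,
        perpetrator=rule.perpetrator,
        period=str(period),
        n_patients=len({h.patient_id for h in rhits}),
        time_series=time_series(rhits, prescriptions, period, bin=bin),
        sex_counts=sex_counts,
        age_band_counts=band_counts,
        unit_breakdown=unit_breakdown(rhits, prescriptions),
        dosage_coverage=coverage,
        dosage_by_status=statuses,
    )


def export_bundle(bundle: DashboardBundle, path: str | Path,
                  *, format: str = "json") -> Path:
    """Write a bundle as schema-stable JSON or a self-contained HTML report."""
    path = Path(path)
    try:
        if format == "json":
            path.write_text(bundle.model_dump_json(indent=2) + "\n")
        elif format == "html":
            path.write_text(render_html(bundle))
        else:
            raise ConfigurationError(f"format must be json or html, got {format!r}")
    except OSError as exc:
        raise DashboardError(f"cannot write {path}: {exc}") from exc
    return path


def load_bundle(path: str | Path) -> DashboardBundle:
    """Inverse of the JSON export (validates against the bundle schema)."""
    return DashboardBundle.model_validate_json(Path(path).read_text())


def bundle_json_schema() -> dict:
    """JSON schema of the bundle export format."""
    return DashboardBundle.model_json_schema()


def _fig_to_img(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<img src="data:image/png;base64,{data}"/>'


def render_html(bundle: DashboardBundle) -> str:
    """Self-contained HTML page with the five panels rendered as charts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{bundle.cytochrome} {bundle.substrate}/{bundle.perpetrator}</title>"
        "</head><body>",
        f"<h1>{bundle.cytochrome}: {bundle.substrate} "
        f"({bundle.relation}) {bundle.perpetrator}</h1>",
        f"<p>Period {bundle.period} — {bundle.n_patients} affected patients.</p>",
    ]

    def bar(title, labels, values, rotate=False):
        fig, ax = plt.subplots(figsize=(6, 2.4))
        ax.bar(range(len(labels)), values, color="#4878a8")
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90 if rotate else 0, fontsize=7)
        ax.set_title(title, fontsize=9)
        return _fig_to_img(fig)

    ts_labels = [t for t, _ in bundle.time_series]
    ts_values = [c for _, c in bundle.time_series]
    if len(ts_labels) > 60:  # day bins over a long period: thin the axis labels
        step = len(ts_labels) // 60 + 1
        shown = [l if i % step == 0 else "" for i, l in enumerate(ts_labels)]
    else:
        shown = ts_labels
    parts.append("<h2>Patients over time</h2>")
    parts.append(bar("affected patients per bin", shown, ts_values, rotate=True))
    parts.append("<h2>Demographics</h2>")
    parts.append(bar("by sex", list(bundle.sex_counts), list(bundle.sex_counts.values())))
    parts.append(bar("by age band", list(bundle.age_band_counts),
                     list(bundle.age_band_counts.values()), rotate=True))
    parts.append("<h2>Medical units</h2>")
    parts.append(bar("patients by unit", list(bundle.unit_breakdown),
                     list(bundle.unit_breakdown.values()), rotate=True))
    cov = ("n/a" if bundle.dosage_coverage is None
           else f"{100 * bundle.dosage_coverage:.1f}%")
    parts.append(f"<h2>Dosage coverage</h2><p style='font-size:2em'>{cov}</p>")
    parts.append("<h2>Dosage results by status</h2>")
    if bundle.dosage_by_status:
        parts.append(bar("matched assays by status", list(bundle.dosage_by_status),
                         list(bundle.dosage_by_status.values())))
    else:
        parts.append("<p>no matched assays</p>")
    parts.append("</body></html>")
    return "\n".join(parts)
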