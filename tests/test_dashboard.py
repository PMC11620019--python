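"""Dashboard panel aggregations: conservation, coverage, exports."""

import datetime as dt
import tempfile

import pandas as pd
import pytest

from cypscreen import (
    AnalyteMap,
    DashboardError,
    InteractionHit,
    Period,
    build_bundle,
    demographics,
    detect,
    dosage_by_status,
    dosage_coverage,
    export_bundle,
    load_bundle,
    load_rules,
    time_series,
    unit_breakdown,
)
from cypscreen.dashboard import DashboardBundle, bundle_json_schema, render_html
from cypscreen.simulate import generate

from .conftest import lab_frame, make_rule, rx_frame, small_config

PERIOD = Period(dt.date(2021, 6, 1), dt.date(2021, 9, 30))


def hit(rule_id="R0001", patient="P1", day="2021-06-10",
        sub_ids=("E1",), perp_ids=("E2",)):
    return InteractionHit(rule_id, patient, dt.date.fromisoformat(day),
                          tuple(sub_ids), tuple(perp_ids))


def patients_frame(rows):
    return pd.DataFrame(
        [{"patient_id": p, "sex": s, "birth_date": dt.date.fromisoformat(b)}
         for p, s, b in rows],
        columns=["patient_id", "sex", "birth_date"],
    )


class TestTimeSeries:
    RX = rx_frame([
        ("E1", "P1", "S1", "2021-06-10", "3400000000001", "ICU"),
        ("E3", "P1", "S1", "2021-07-02", "3400000000001", "CARDIO"),
    ])

    def test_patient_in_two_months_counts_in_both_bins(self):
        hits = [hit(day="2021-06-10"), hit(day="2021-07-02", sub_ids=("E3",))]
        series = dict(time_series(hits, self.RX, PERIOD, bin="month"))
        assert series == {"2021-06": 1, "2021-07": 1, "2021-08": 0, "2021-09": 0}

    def test_empty_hits_give_all_zero_series(self):
        series = time_series([], self.RX, PERIOD, bin="month")
        assert [c for _, c in series] == [0, 0, 0, 0]

    def test_day_bins_span_the_whole_period(self):
        series = time_series([], self.RX, PERIOD, bin="day")
        assert len(series) == PERIOD.n_days

    def test_unit_filter_restricts_and_unknown_unit_raises(self):
        hits = [hit(day="2021-06-10"), hit(day="2021-07-02", sub_ids=("E3",))]
        filtered = dict(time_series(hits, self.RX, PERIOD, bin="month",
                                    unit_filter="ICU"))
        assert filtered["2021-06"] == 1 and filtered["2021-07"] == 0
        with pytest.raises(DashboardError, match="CARDIO"):
            time_series(hits, self.RX, PERIOD, unit_filter="NOWHERE")

    def test_unit_filtered_series_is_binwise_below_unfiltered(self, small_dataset):
        ds = small_dataset
        rules = _active_rules(ds)
        hits = detect(rules, ds.prescriptions, ds.labs,
                      period=ds.config.period_dd, analyte_map=ds.analyte_map)
        full = time_series(hits, ds.prescriptions, ds.config.period_dd, bin="week")
        for unit in ds.config.units:
            part = time_series(hits, ds.prescriptions, ds.config.period_dd,
                               bin="week", unit_filter=unit)
            assert all(c <= f for (_, c), (_, f) in zip(part, full))

    def test_per_day_bins_match_brute_force_recount(self, small_dataset):
        ds = small_dataset
        rules = _active_rules(ds)
        hits = detect(rules, ds.prescriptions, ds.labs,
                      period=ds.config.period_dd, analyte_map=ds.analyte_map)
        series = dict(time_series(hits, ds.prescriptions,
                                  ds.config.period_dd, bin="day"))
        for day in ds.config.period_dd.days():
            expected = len({h.patient_id for h in hits if h.day == day})
            assert series[day.isoformat()] == expected


class TestDemographics:
    def test_sex_counts(self):
        pts = patients_frame([("P1", "F", "1950-01-01"), ("P2", "M", "1960-01-01")])
        hits = [hit(patient="P1"), hit(patient="P2")]
        sex, _ = demographics(hits, pts)
        assert sex == {"F": 1, "M": 1}

    def test_age_band_is_half_open_at_first_hit(self):
        pts = patients_frame([("P1", "F", "1960-01-01")])
        _, bands = demographics([hit(patient="P1", day="2021-06-01")], pts,
                                age_bands=[(0, 60), (60, 120)])
        assert bands == {"[0,60)": 0, "[60,120)": 1}

    def test_affected_patient_counted_once_despite_many_hits(self):
        pts = patients_frame([("P1", "F", "1950-01-01")])
        hits = [hit(day="2021-06-10"), hit(day="2021-07-02")]
        sex, bands = demographics(hits, pts)
        assert sum(sex.values()) == 1 and sum(bands.values()) == 1

    def test_missing_patient_record_names_the_patient(self):
        pts = patients_frame([("P1", "F", "1950-01-01")])
        with pytest.raises(DashboardError, match="P2"):
            demographics([hit(patient="P2")], pts)

    def test_band_totals_equal_patient_total_on_random_cohort(self, small_dataset):
        ds = small_dataset
        rules = _active_rules(ds, mutation=None)
        for rule in rules:
            period = (ds.config.period_dg if rule.is_mutation
                      else ds.config.period_dd)
            hits = detect([rule], ds.prescriptions, ds.labs, period=period,
                          analyte_map=ds.analyte_map)
            n = len({h.patient_id for h in hits})
            sex, bands = demographics(hits, ds.patients)
            assert sum(sex.values()) == n
            assert sum(bands.values()) == n


class TestUnitBreakdown:
    def test_patient_hit_in_two_units_counts_in_both(self):
        rx = rx_frame([
            ("E1", "P1", "S1", "2021-06-10", "c", "A"),
            ("E3", "P1", "S1", "2021-06-11", "c", "B"),
        ])
        hits = [hit(day="2021-06-10"), hit(day="2021-06-11", sub_ids=("E3",))]
        assert unit_breakdown(hits, rx) == {"A": 1, "B": 1}

    def test_empty_hits_give_empty_map(self):
        assert unit_breakdown([], rx_frame([])) == {}

    def test_matches_per_unit_recount(self, small_dataset):
        ds = small_dataset
        rules = _active_rules(ds)
        hits = detect(rules, ds.prescriptions, ds.labs,
                      period=ds.config.period_dd, analyte_map=ds.analyte_map)
        got = unit_breakdown(hits, ds.prescriptions)
        unit_of = dict(zip(ds.prescriptions["event_id"], ds.prescriptions["unit"]))
        expected: dict[str, set] = {}
        for h in hits:
            for e in h.substrate_event_ids:
                expected.setdefault(unit_of[e], set()).add(h.patient_id)
        assert got == {u: len(p) for u, p in expected.items()}


RULE = make_rule(substrate="subx", substrate_codes=("3400000000001",),
                 perpetrator_codes=("3400000000002",))
AMAP = AnalyteMap.from_dict({"dosage": {"subx": ["DOS-1"]}})


class TestDosagePanels:
    def _cohort(self):
        rx = rx_frame([
            (f"E{i}", f"P{i}", f"S-P{i}", "2021-06-10", "3400000000001", "ICU")
            for i in range(1, 5)
        ])
        hits = [hit(patient=f"P{i}", sub_ids=(f"E{i}",)) for i in range(1, 5)]
        labs = lab_frame([
            ("L1", "P1", "2021-06-10", "DOS-1", "dosage", "5.0", "in_range"),
        ])
        return rx, hits, labs

    def test_quarter_coverage(self):
        rx, hits, labs = self._cohort()
        cov = dosage_coverage(hits, labs, RULE, AMAP, prescriptions=rx,
                              window="same_day")
        assert cov == 0.25

    def test_no_affected_patients_is_missing_not_zero(self):
        cov = dosage_coverage([], lab_frame([]), RULE, AMAP,
                              prescriptions=rx_frame([]))
        assert cov is None

    def test_unmapped_substrate_is_configuration_error(self):
        from cypscreen import ConfigurationError

        rx, hits, labs = self._cohort()
        with pytest.raises(ConfigurationError, match="unmapped"):
            dosage_coverage(hits, labs,
                            make_rule(substrate="unmapped",
                                      substrate_codes=("3400000000001",)),
                            AMAP, prescriptions=rx)

    def test_status_counts(self):
        rx, hits, _ = self._cohort()
        labs = lab_frame([
            ("L1", "P1", "2021-06-10", "DOS-1", "dosage", "2.0", "below"),
            ("L2", "P2", "2021-06-10", "DOS-1", "dosage", "5.0", "in_range"),
            ("L3", "P3", "2021-06-10", "DOS-1", "dosage", "6.0", "in_range"),
        ])
        counts = dosage_by_status(hits, labs, RULE, AMAP, prescriptions=rx,
                                  window="same_day")
        assert counts == {"below": 1, "in_range": 2}

    def test_no_matched_dosages_give_empty_counts(self):
        rx, hits, _ = self._cohort()
        assert dosage_by_status(hits, lab_frame([]), RULE, AMAP,
                                prescriptions=rx) == {}

    def test_same_stay_window_reaches_beyond_hit_day(self):
        rx = rx_frame([
            ("E1", "P1", "S1", "2021-06-10", "3400000000001", "ICU"),
            ("E9", "P1", "S1", "2021-06-20", "3400999999999", "ICU"),
        ])
        hits = [hit(patient="P1")]
        labs = lab_frame([
            ("L1", "P1", "2021-06-15", "DOS-1", "dosage", "5.0", "above"),
        ])
        assert dosage_coverage(hits, labs, RULE, AMAP, prescriptions=rx,
                               window="same_day") == 0.0
        assert dosage_coverage(hits, labs, RULE, AMAP, prescriptions=rx,
                               window="same_stay") == 1.0

    def test_dedupe_patient_keeps_first_assay_only(self):
        rx, hits, _ = self._cohort()
        labs = lab_frame([
            ("L1", "P1", "2021-06-10", "DOS-1", "dosage", "2.0", "below"),
            ("L2", "P1", "2021-06-10", "DOS-1", "dosage", "9.0", "above"),
        ])
        dup = dosage_by_status(hits, labs, RULE, AMAP, prescriptions=rx,
                               window="same_day")
        dedup = dosage_by_status(hits, labs, RULE, AMAP, prescriptions=rx,
                                 window="same_day", dedupe_patient=True)
        assert sum(dup.values()) == 2
        assert dedup == {"below": 1}

    def test_planted_coverage_fraction_recovered_exactly(self, small_dataset):
        ds = small_dataset
        for rule in _active_rules(ds, mutation=None):
            spec = next(s for s in ds.config.rules
                        if s.substrate == rule.substrate
                        and s.perpetrator == rule.perpetrator)
            if spec.dosage_coverage is None:
                continue
            period = (ds.config.period_dg if rule.is_mutation
                      else ds.config.period_dd)
            hits = detect([rule], ds.prescriptions, ds.labs, period=period,
                          analyte_map=ds.analyte_map)
            for window in ("same_day", "same_stay", "period"):
                cov = dosage_coverage(
                    hits, ds.labs, rule, ds.analyte_map,
                    prescriptions=ds.prescriptions, window=window,
                    period=period)
                assert cov == pytest.approx(spec.dosage_coverage)

    def test_status_totals_equal_matched_event_count(self, small_dataset):
        ds = small_dataset
        for rule in _active_rules(ds, mutation=None):
            period = (ds.config.period_dg if rule.is_mutation
                      else ds.config.period_dd)
            hits = detect([rule], ds.prescriptions, ds.labs, period=period,
                          analyte_map=ds.analyte_map)
            truth = ds.ground_truth.rules[rule.rule_id]
            try:
                counts = dosage_by_status(
                    hits, ds.labs, rule, ds.analyte_map,
                    prescriptions=ds.prescriptions, window="same_day")
            except Exception:
                continue  # substrate without a configured assay
            assert sum(counts.values()) == len(truth.dosage_statuses)


class TestBundleExport:
    def _bundle(self, ds, rule):
        period = ds.config.period_dg if rule.is_mutation else ds.config.period_dd
        hits = detect([rule], ds.prescriptions, ds.labs, period=period,
                      analyte_map=ds.analyte_map)
        return build_bundle(rule, hits, prescriptions=ds.prescriptions,
                            labs=ds.labs, patients=ds.patients,
                            analyte_map=ds.analyte_map, period=period)

    def test_json_round_trip(self, small_dataset, tmp_path):
        rule = _active_rules(small_dataset, mutation=None)[0]
        bundle = self._bundle(small_dataset, rule)
        path = export_bundle(bundle, tmp_path / "b.json", format="json")
        assert load_bundle(path) == bundle

    def test_empty_hits_bundle_is_valid(self, tmp_path):
        rx = rx_frame([])
        bundle = build_bundle(
            RULE, [], prescriptions=rx, labs=lab_frame([]),
            patients=patients_frame([]), analyte_map=AMAP, period=PERIOD)
        assert bundle.n_patients == 0
        assert bundle.dosage_coverage is None
        path = export_bundle(bundle, tmp_path / "empty.json")
        assert load_bundle(path).n_patients == 0

    def test_shipped_schema_file_matches_model(self):
        import importlib.resources
        import json

        shipped = json.loads(
            (importlib.resources.files("cypscreen") / "data"
             / "bundle.schema.json").read_text())
        assert shipped == json.loads(
            json.dumps(bundle_json_schema(), sort_keys=True))

    def test_random_bundles_validate_against_schema(self):
        """Export then re-validate 50 bundles through the shipped schema model."""
        schema = bundle_json_schema()
        assert schema["title"] == "DashboardBundle"
        for seed in range(5):
            ds = generate(small_config(seed=200 + seed))
            for rule in _active_rules(ds, mutation=None):
                bundle = self._bundle(ds, rule)
                revalidated = DashboardBundle.model_validate_json(
                    bundle.model_dump_json())
                assert revalidated == bundle

    def test_html_report_contains_all_five_panels(self, small_dataset):
        rule = _active_rules(small_dataset)[0]
        html = render_html(self._bundle(small_dataset, rule))
        for heading in ("Patients over time", "Demographics", "Medical units",
                        "Dosage coverage", "Dosage results by status"):
            assert heading in html
        assert "data:image/png;base64," in html


def _active_rules(ds, mutation=False):
    """Load the dataset's KB and keep planted rules (optionally by kind)."""
    with tempfile.TemporaryDirectory() as td:
        rules = load_rules(ds.write(td)["kb"])
    rules = [r for r in rules if r.rule_id in ds.ground_truth.rules]
    if mutation is None:
        return rules
    return [r for r in rules if r.is_mutation == mutation]
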