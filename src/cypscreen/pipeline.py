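"""End-to-end orchestration: validate → filter → queries → detect → report.

One call produces, in order, the KB validation report, the filtered KB with
stage counts, the query manifest, the hit and summary tables (drug–drug and
drug–genotype kept strictly separate, as clinical reviewers request), the
dashboard bundles for the top-N rules of each kind, and a machine-readable
run report.  The analysis path contains no randomness: re-running on the
same inputs reproduces every output byte-for-byte.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import dashboard as dash
from . import kb as kbmod
from .detect import (
    detect as _detect,
    hits_to_frame,
    rank_rules,
    summaries_to_frame,
    summarize,
)
from .errors import ConfigurationError
from .events import (
    AnalyteMap,
    Period,
    load_labs,
    load_patients,
    load_prescriptions,
)
from .query import build_query


@dataclass(frozen=True)
class RunConfig:
    """Paths, periods and options for one pipeline run."""

    kb: Path
    formulary: Path
    prescriptions: Path
    labs: Path
    patients: Path
    analyte_map: Path | None
    period_dd: Period
    period_dg: Period
    out_dir: Path
    join_on: str = "day"
    top_n: int = 10
    rank_by: str = "patients"
    dashboard_format: str = "json"
    time_bin: str = "month"
    dosage_window: str = "same_stay"
    dedupe_patient: bool = False

    def validate(self) -> None:
        for name in ("kb", "formulary", "prescriptions", "labs", "patients"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} file not found: {p}")
        if self.analyte_map is not None and not Path(self.analyte_map).exists():
            raise ConfigurationError(f"analyte map not found: {self.analyte_map}")


def _config_hash(config: RunConfig) -> str:
    payload = {k: str(v) for k, v in vars(config).items()}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable account of one run (written as run_report.json)."""

    config_hash: str
    version: str
    kb_rows: int = 0
    kb_issues: int = 0
    self_pairs_removed: int = 0
    rules_after_self_filter: int = 0
    rules_after_formulary: int = 0
    combinations_before_formulary: int = 0
    combinations_after_formulary: int = 0
    n_queries: int = 0
    n_hits_drug_drug: int = 0
    n_hits_drug_genotype: int = 0
    outputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(vars(self))


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage and write all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=_config_hash(config), version=__version__)

    # stage 1: KB validation
    issues = kbmod.validate_kb(config.kb)
    kbmod.write_validation_report(issues, out / "kb_validation.jsonl")
    report.kb_issues = len(issues)
    fatal = [i for i in issues if i.issue in ("missing_column", "malformed_code")]
    if fatal:
        raise ConfigurationError(
            f"stage validate-kb: {len(fatal)} fatal issue(s), first: {fatal[0]}"
        )
    rules = kbmod.load_rules(config.kb)
    report.kb_rows = len(rules)

    # stage 2: self-pair removal and formulary filtering
    kept, removed = kbmod.remove_self_interactions(rules)
    report.self_pairs_removed = len(removed)
    report.rules_after_self_filter = len(kept)
    report.combinations_before_formulary = kbmod.count_code_combinations(kept)
    formulary = kbmod.load_formulary(config.formulary)
    active = kbmod.filter_to_formulary(kept, formulary)
    report.rules_after_formulary = len(active)
    report.combinations_after_formulary = kbmod.count_code_combinations(active)
    kbmod.write_rules(active, out / "kb_filtered.tsv")

    # stage 3: query generation (drug–drug rules only)
    dd_rules = [r for r in active if not r.is_mutation]
    dg_rules = [r for r in active if r.is_mutation]
    with (out / "queries.txt").open("w") as qf, \
            (out / "query_manifest.tsv").open("w") as mf:
        mf.write("rule_id\tcytochrome\tsubstrate\trelation\tperpetrator\n")
        for r in dd_rules:
            qf.write(build_query(r).text + "\n")
            mf.write(
                f"{r.rule_id}\t{r.cytochrome}\t{r.substrate}\t"
                f"{r.relation}\t{r.perpetrator}\n"
            )
    report.n_queries = len(dd_rules)

    # stage 4: detection
    prescriptions = load_prescriptions(config.prescriptions)
    labs = load_labs(config.labs)
    patients = load_patients(config.patients)
    analyte_map = (
        AnalyteMap.from_yaml(config.analyte_map)
        if config.analyte_map is not None
        else None
    )
    if dg_rules and analyte_map is None:
        raise ConfigurationError(
            f"stage detect: mutation rule {dg_rules[0].rule_id} "
            f"({dg_rules[0].substrate} / {dg_rules[0].perpetrator}) present "
            "but no analyte map supplied"
        )
    dd_hits = _detect(
        dd_rules, prescriptions, labs,
        period=config.period_dd, analyte_map=analyte_map,
        join_on=config.join_on,
    )
    dg_hits = _detect(
        dg_rules, prescriptions, labs,
        period=config.period_dg, analyte_map=analyte_map,
    )
    report.n_hits_drug_drug = len(dd_hits)
    report.n_hits_drug_genotype = len(dg_hits)
    hits_to_frame(dd_hits).to_csv(
        out / "hits_drug_drug.tsv", sep="\t", index=False)
    hits_to_frame(dg_hits).to_csv(
        out / "hits_drug_genotype.tsv", sep="\t", index=False)

    # stage 5: summaries, ranked (drug–drug and drug–genotype separately)
    dd_sum = rank_rules(
        summarize(dd_hits, period=config.period_dd), dd_rules,
        by=config.rank_by,
    )
    dg_sum = rank_rules(
        summarize(dg_hits, period=config.period_dg), dg_rules,
        by=config.rank_by,
    )
    summaries_to_frame(dd_sum, dd_rules).to_csv(
        out / "summary_drug_drug.tsv", sep="\t", index=False)
    summaries_to_frame(dg_sum, dg_rules).to_csv(
        out / "summary_drug_genotype.tsv", sep="\t", index=False)

    # stage 6: dashboards for the top-N rules of each kind
    dash_dir = out / "dashboards"
    dash_dir.mkdir(exist_ok=True)
    rule_index = {r.rule_id: r for r in active}
    for summaries, hits, period in (
        (dd_sum[: config.top_n], dd_hits, config.period_dd),
        (dg_sum[: config.top_n], dg_hits, config.period_dg),
    ):
        for s in summaries:
            if analyte_map is None:
                continue
            bundle = dash.build_bundle(
                rule_index[s.rule_id], hits,
                prescriptions=prescriptions, labs=labs, patients=patients,
                analyte_map=analyte_map, period=period,
                bin=config.time_bin, window=config.dosage_window,
                dedupe_patient=config.dedupe_patient,
            )
            ext = "html" if config.dashboard_format == "html" else "json"
            dash.export_bundle(
                bundle, dash_dir / f"{s.rule_id}.{ext}",
                format=config.dashboard_format,
            )

    report.outputs = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        for p in sorted(out.glob("*"))
        if p.is_file()
    }
    (out / "run_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return report
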