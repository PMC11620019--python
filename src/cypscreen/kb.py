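"""Cytochrome interaction knowledge base: loading, validation and filtering.

The knowledge base is a flat table exported from a terminology source.  Each
row pairs a cytochrome isoform with a substrate substance and a perpetrator —
an inhibitor (``p_inhib``), an inducer (``p_induc``), or, for pharmacogenetic
surveillance rules, a genotyping act (``mutation``).  Drug presentations are
identified by UCD codes (unité commune de dispensation), 13-digit decimal
identifiers.

Typical flow::

    rules = load_rules("kb.tsv")
    kept, removed = remove_self_interactions(rules)
    active = filter_to_formulary(kept, load_formulary("formulary.txt"))
    n_pairs = count_code_combinations(active)
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, KBValidationError, SchemaError

UCD_CODE_RE = re.compile(r"^\d{13}$")

#: Relation vocabulary: perpetrator inhibits the isoform, induces it, or the
#: "perpetrator" is a genotyping act on the isoform gene.
RELATIONS = ("p_inhib", "p_induc", "mutation")

#: Literal separator between codes inside a code-list cell.
DEFAULT_CODE_SEPARATOR = " or "

REQUIRED_COLUMNS = (
    "cytochrome",
    "substrate",
    "relation",
    "perpetrator",
    "substrate_ucds",
    "perpetrator_ucds",
)


def canonical_label(label: str) -> str:
    """Canonical form of a substance label: whitespace-trimmed, case-folded."""
    return label.strip().casefold()


@dataclass(frozen=True)
class InteractionRule:
    """One knowledge-base row.

    ``substrate_codes`` and ``perpetrator_codes`` are ordered, duplicate-free
    tuples of 13-digit UCD code strings.  For ``relation == "mutation"`` the
    perpetrator is a genotype-test label and ``perpetrator_codes`` may be
    empty (the matching lab analyte is supplied separately via the analyte
    map, since genotyping acts are not drug dispensations).
    """

    rule_id: str
    cytochrome: str
    substrate: str
    relation: str
    perpetrator: str
    substrate_codes: tuple[str, ...]
    perpetrator_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise KBValidationError(
                f"rule {self.rule_id}: unknown relation {self.relation!r} "
                f"(expected one of {RELATIONS})"
            )
        for side, codes in (
            ("substrate", self.substrate_codes),
            ("perpetrator", self.perpetrator_codes),
        ):
            if len(set(codes)) != len(codes):
                raise KBValidationError(
                    f"rule {self.rule_id}: duplicate codes in {side} list"
                )
            for c in codes:
                if not UCD_CODE_RE.match(c):
                    raise KBValidationError(
                        f"rule {self.rule_id}: malformed UCD code {c!r} in {side} list"
                    )

    @property
    def is_mutation(self) -> bool:
        return self.relation == "mutation"

    @property
    def sort_key(self) -> tuple[str, str, str]:
        """Deterministic tie-break key: (cytochrome, substrate, perpetrator)."""
        return (self.cytochrome, self.substrate, self.perpetrator)


@dataclass(frozen=True)
class Formulary:
    """The institutional formulary: the set of UCD codes dispensed locally."""

    codes: frozenset[str]

    def __post_init__(self) -> None:
        bad = sorted(c for c in self.codes if not UCD_CODE_RE.match(c))
        if bad:
            raise KBValidationError(f"malformed formulary code(s): {bad[:5]}")

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class ValidationIssue:
    """One problem found while reading a KB file (JSON-lines report record)."""

    row: int
    column: str
    value: str
    issue: str

    def to_json(self) -> str:
        return json.dumps(
            {"row": self.row, "column": self.column, "value": self.value,
             "issue": self.issue},
            ensure_ascii=False,
        )


def _split_codes(cell: str, separator: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(tok.strip() for tok in cell.split(separator))


def load_rules(
    path: str | Path,
    *,
    delimiter: str = "\t",
    code_separator: str = DEFAULT_CODE_SEPARATOR,
) -> list[InteractionRule]:
    """Load interaction rules from a delimited file, one rule per row.

    Rows are preserved 1:1 (duplicates are NOT collapsed here; use
    :func:`validate_kb` to surface them).  Substance labels are canonicalized
    (trimmed, case-folded).  Rule ids are assigned from the 1-based data row
    number as ``R0001``, ``R0002``, ...

    Raises
    ------
    SchemaError
        if a required column is missing.
    KBValidationError
        if a code cell contains a non-13-digit token (message carries the row
        number and offending value).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {missing}; found {header}"
            )
        rules: list[InteractionRule] = []
        for i, row in enumerate(reader, start=1):
            rule_id = f"R{i:04d}"
            sub_codes = _split_codes(row["substrate_ucds"] or "", code_separator)
            perp_codes = _split_codes(row["perpetrator_ucds"] or "", code_separator)
            for col, codes in (("substrate_ucds", sub_codes),
                               ("perpetrator_ucds", perp_codes)):
                for c in codes:
                    if not UCD_CODE_RE.match(c):
                        raise KBValidationError(
                            f"{path}: row {i}, column {col}: malformed UCD code {c!r}"
                        )
            try:
                rules.append(
                    InteractionRule(
                        rule_id=rule_id,
                        cytochrome=row["cytochrome"].strip(),
                        substrate=canonical_label(row["substrate"]),
                        relation=row["relation"].strip(),
                        perpetrator=canonical_label(row["perpetrator"]),
                        substrate_codes=sub_codes,
                        perpetrator_codes=perp_codes,
                    )
                )
            except KBValidationError as exc:
                raise KBValidationError(f"{path}: row {i}: {exc}") from None
    return rules


def validate_kb(
    path: str | Path,
    *,
    delimiter: str = "\t",
    code_separator: str = DEFAULT_CODE_SEPARATOR,
) -> list[ValidationIssue]:
    """Collect all validation issues in a KB file without raising.

    Reported issues: missing columns, malformed codes, unknown relation
    values, duplicate codes within a cell, empty substrate code lists, and
    exact duplicate rows.
    """
    path = Path(path)
    issues: list[ValidationIssue] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                issues.append(ValidationIssue(0, col, "", "missing_column"))
        if issues:
            return issues
        seen: dict[tuple, int] = {}
        for i, row in enumerate(reader, start=1):
            key = tuple(row.get(c, "") for c in REQUIRED_COLUMNS)
            if key in seen:
                issues.append(
                    ValidationIssue(i, "*", "", f"duplicate_of_row_{seen[key]}")
                )
            else:
                seen[key] = i
            if row["relation"].strip() not in RELATIONS:
                issues.append(
                    ValidationIssue(i, "relation", row["relation"], "unknown_relation")
                )
            for col in ("substrate_ucds", "perpetrator_ucds"):
                codes = _split_codes(row[col] or "", code_separator)
                for c in codes:
                    if not UCD_CODE_RE.match(c):
                        issues.append(ValidationIssue(i, col, c, "malformed_code"))
                if len(set(codes)) != len(codes):
                    issues.append(ValidationIssue(i, col, "", "duplicate_codes"))
            if not _split_codes(row["substrate_ucds"] or "", code_separator):
                issues.append(
                    ValidationIssue(i, "substrate_ucds", "", "empty_code_list")
                )
    return issues


def write_validation_report(issues: Iterable[ValidationIssue],
                            path: str | Path) -> None:
    """Write issues as JSON lines, one object per issue."""
    with Path(path).open("w") as fh:
        for issue in issues:
            fh.write(issue.to_json() + "\n")


def remove_self_interactions(
    rules: Sequence[InteractionRule],
) -> tuple[list[InteractionRule], list[InteractionRule]]:
    """Partition rules into (kept, removed) where removed rows name the same
    molecule as both substrate and perpetrator.

    Labels are compared in canonical form; order is preserved on both sides
    and ``kept + removed`` is exactly the input.
    """
    kept: list[InteractionRule] = []
    removed: list[InteractionRule] = []
    for rule in rules:
        if canonical_label(rule.substrate) == canonical_label(rule.perpetrator):
            removed.append(rule)
        else:
            kept.append(rule)
    return kept, removed


def filter_to_formulary(
    rules: Sequence[InteractionRule], formulary: Formulary
) -> list[InteractionRule]:
    """Restrict every rule's code lists to the formulary.

    Code order is preserved.  A rule is dropped when its substrate side
    empties, or when its perpetrator side empties and the rule is not a
    mutation rule (mutation perpetrators are lab acts, not drugs).

    Raises :class:`ConfigurationError` on an empty formulary so that "no
    formulary supplied" is never silently read as "no overlap".
    """
    if len(formulary) == 0:
        raise ConfigurationError("empty formulary: no UCD codes supplied")
    surviving: list[InteractionRule] = []
    for rule in rules:
        sub = tuple(c for c in rule.substrate_codes if c in formulary)
        perp = tuple(c for c in rule.perpetrator_codes if c in formulary)
        if not sub:
            continue
        if not perp and not rule.is_mutation:
            continue
        surviving.append(replace(rule, substrate_codes=sub, perpetrator_codes=perp))
    return surviving


def count_code_combinations(rules: Sequence[InteractionRule]) -> int:
    """Total number of (substrate code, perpetrator code) pairs over the KB.

    This is the KB's combination metric: the substance-pair count multiplied
    out over each pair's dispensing-code declinations.
    """
    return sum(
        len(r.substrate_codes) * len(r.perpetrator_codes) for r in rules
    )


def load_formulary(path: str | Path) -> Formulary:
    """Read a formulary file: one UCD code per line, ``#`` starts a comment."""
    codes: set[str] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            codes.add(line)
    return Formulary(frozenset(codes))


def write_rules(
    rules: Sequence[InteractionRule],
    path: str | Path,
    *,
    delimiter: str = "\t",
    code_separator: str = DEFAULT_CODE_SEPARATOR,
) -> None:
    """Write rules back out in the KB file format (inverse of load_rules)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(REQUIRED_COLUMNS)
        for r in rules:
            writer.writerow(
                [
                    r.cytochrome,
                    r.substrate,
                    r.relation,
                    r.perpetrator,
                    code_separator.join(r.substrate_codes),
                    code_separator.join(r.perpetrator_codes),
                ]
            )
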