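"""Boolean co-prescription queries in the two-clause textual dialect.

A drug–drug rule renders as::

    (SUB1 or SUB2 or ...) and (PERP1 or PERP2 or ...)

where each atom is a 13-digit UCD code.  The dialect is deliberately frozen —
lowercase ``or``/``and``, one pair of parentheses per clause, no nesting —
because the rendered string is the exchange format for downstream warehouse
queries, and round-tripping must be exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set

from .errors import ConfigurationError, QueryParseError
from .kb import UCD_CODE_RE, InteractionRule


@dataclass(frozen=True)
class CooccurrenceQuery:
    """Conjunction of two disjunctive clauses over UCD codes."""

    substrate_clause: tuple[str, ...]
    perpetrator_clause: tuple[str, ...]

    @property
    def text(self) -> str:
        """Rendered query string in the fixed dialect."""
        return (
            "(" + " or ".join(self.substrate_clause) + ") and ("
            + " or ".join(self.perpetrator_clause) + ")"
        )


def build_query(rule: InteractionRule) -> CooccurrenceQuery:
    """Render a drug–drug rule as a co-occurrence query.

    Clause order preserves the KB code order.  Mutation rules (lab-act
    perpetrator, empty drug-code list) are not renderable as two-drug
    queries and raise :class:`ConfigurationError`.
    """
    if not rule.substrate_codes or not rule.perpetrator_codes:
        raise ConfigurationError(
            f"rule {rule.rule_id} ({rule.substrate}/{rule.perpetrator}): "
            "both code lists must be non-empty to build a two-drug query"
        )
    return CooccurrenceQuery(rule.substrate_codes, rule.perpetrator_codes)


def _parse_clause(text: str, pos: int) -> tuple[tuple[str, ...], int]:
    if pos >= len(text) or text[pos] != "(":
        raise QueryParseError("expected '('", pos)
    pos += 1
    codes: list[str] = []
    while True:
        end = pos
        while end < len(text) and text[end].isdigit():
            end += 1
        atom = text[pos:end]
        if not UCD_CODE_RE.match(atom):
            raise QueryParseError(f"expected 13-digit code, got {atom!r}", pos)
        codes.append(atom)
        pos = end
        if text.startswith(" or ", pos):
            pos += 4
            continue
        if pos < len(text) and text[pos] == ")":
            return tuple(codes), pos + 1
        raise QueryParseError("expected ' or ' or ')'", min(pos, len(text)))


def parse_query(text: str) -> CooccurrenceQuery:
    """Parse dialect text back into clause lists (inverse of rendering).

    Raises :class:`QueryParseError` with the character offset of the first
    offending position for unbalanced parentheses, stray tokens, or atoms
    that are not 13-digit codes.
    """
    substrate, pos = _parse_clause(text, 0)
    if not text.startswith(" and ", pos):
        raise QueryParseError("expected ' and ' between clauses", pos)
    perpetrator, pos = _parse_clause(text, pos + 5)
    if pos != len(text):
        raise QueryParseError("trailing characters after query", pos)
    return CooccurrenceQuery(substrate, perpetrator)


def evaluate(query: CooccurrenceQuery, present_codes: Set[str] | Iterable[str]) -> bool:
    """True iff both clauses are satisfied by the given set of codes.

    Monotone in ``present_codes``: adding codes can only flip False→True.
    """
    present = set(present_codes)
    return bool(present.intersection(query.substrate_clause)) and bool(
        present.intersection(query.perpetrator_clause)
    )
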