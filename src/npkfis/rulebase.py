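"""Fuzzy rule base: generation from agronomic postulates and a text DSL.

The rule base encodes standard fertility-management heuristics:

1. phosphorus application is unnecessary (and should be limited) when soil
   phosphorus is already high;
2. when phosphorus is low the recommended rate must satisfy immediate crop
   needs;
3. crops need potassium to make use of soil nitrogen;
4. even at optimum soil potassium some extra is applied to cover crop
   removal — so the potassium recommendation is never NIL;
5. the soil fixes its own nitrogen (nitrogen-fixing bacteria), so no extra
   nitrogen is needed when its concentration is high.

These postulates fix, per nutrient, an inverse dose-response from the
measured level to the required level (LOW->HIGH, ADEQUATE->AVERAGE,
HIGH->LOW, EXCESSIVE->NIL, except potassium where EXCESSIVE->LOW), and a
soil-fertility score equal to the worst per-nutrient adequacy (a deficient
nutrient caps fertility at LOW; an excessive one caps it at AVERAGE).  The
complete base is the Cartesian product of the 4 levels over the 3 inputs:
64 rules, every input combination covered exactly once, AND-connected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional

from .errors import RuleParseError, RuleValidationError
from .membership import InputLevel, OutputLevel

__all__ = [
    "ANTECEDENT_VARS",
    "CONSEQUENT_VARS",
    "FuzzyRule",
    "consequent_for",
    "fertility_consequent",
    "generate_rule_base",
    "parse_rules",
    "serialize_rules",
    "validate_rule_base",
]

ANTECEDENT_VARS = ("N", "P", "K")
CONSEQUENT_VARS = ("R.N", "R.P", "R.K", "S.F")

# Inverse dose-response maps (postulates 1-5). None encodes NIL.
_REQ_NP: dict[InputLevel, Optional[OutputLevel]] = {
    InputLevel.LOW: OutputLevel.HIGH,
    InputLevel.ADEQUATE: OutputLevel.AVERAGE,
    InputLevel.HIGH: OutputLevel.LOW,
    InputLevel.EXCESSIVE: None,
}
_REQ_K: dict[InputLevel, OutputLevel] = {
    InputLevel.LOW: OutputLevel.HIGH,
    InputLevel.ADEQUATE: OutputLevel.AVERAGE,
    InputLevel.HIGH: OutputLevel.LOW,
    InputLevel.EXCESSIVE: OutputLevel.LOW,  # postulate 4: never NIL
}
# Adequacy score a nutrient level contributes to soil fertility.
_ADEQUACY: dict[InputLevel, OutputLevel] = {
    InputLevel.LOW: OutputLevel.LOW,
    InputLevel.ADEQUATE: OutputLevel.HIGH,
    InputLevel.HIGH: OutputLevel.HIGH,
    InputLevel.EXCESSIVE: OutputLevel.AVERAGE,
}


@dataclass(frozen=True)
class FuzzyRule:
    """One AND-connected rule: input levels -> output levels (or NIL=None).

    The antecedent names exactly the three measured nutrients and the
    consequent exactly the four outputs; R.K and S.F are never NIL.
    """

    antecedent: tuple[tuple[str, InputLevel], ...]
    consequent: tuple[tuple[str, Optional[OutputLevel]], ...]
    connective: str = "AND"

    def __post_init__(self) -> None:
        if tuple(k for k, _ in self.antecedent) != ANTECEDENT_VARS:
            raise RuleValidationError(
                f"antecedent must name exactly {ANTECEDENT_VARS}, got "
                f"{tuple(k for k, _ in self.antecedent)}"
            )
        if tuple(k for k, _ in self.consequent) != CONSEQUENT_VARS:
            raise RuleValidationError(
                f"consequent must name exactly {CONSEQUENT_VARS}, got "
                f"{tuple(k for k, _ in self.consequent)}"
            )
        cons = dict(self.consequent)
        if cons["R.K"] is None:
            raise RuleValidationError("R.K consequent may never be NIL (postulate 4)")
        if cons["S.F"] is None:
            raise RuleValidationError("S.F consequent may never be NIL")

    @property
    def inputs(self) -> dict[str, InputLevel]:
        return dict(self.antecedent)

    @property
    def outputs(self) -> dict[str, Optional[OutputLevel]]:
        return dict(self.consequent)


def fertility_consequent(
    n: InputLevel, p: InputLevel, k: InputLevel
) -> OutputLevel:
    """Soil-fertility class implied by three crisp nutrient levels: the
    minimum per-nutrient adequacy (LOW < AVERAGE < HIGH)."""
    return min((_ADEQUACY[lvl] for lvl in (n, p, k)), key=lambda o: o.order)


def consequent_for(
    n: InputLevel, p: InputLevel, k: InputLevel
) -> tuple[Optional[OutputLevel], Optional[OutputLevel], OutputLevel, OutputLevel]:
    """Deterministic consequent (R.N, R.P, R.K, S.F) for an input-level triple."""
    for lvl in (n, p, k):
        if not isinstance(lvl, InputLevel):
            raise RuleValidationError(f"unknown input level {lvl!r}")
    return _REQ_NP[n], _REQ_NP[p], _REQ_K[k], fertility_consequent(n, p, k)


def make_rule(n: InputLevel, p: InputLevel, k: InputLevel) -> FuzzyRule:
    r_n, r_p, r_k, s_f = consequent_for(n, p, k)
    return FuzzyRule(
        antecedent=(("N", n), ("P", p), ("K", k)),
        consequent=(("R.N", r_n), ("R.P", r_p), ("R.K", r_k), ("S.F", s_f)),
    )


def generate_rule_base() -> list[FuzzyRule]:
    """All 64 rules: the Cartesian product of 4 levels over the 3 inputs."""
    return [make_rule(n, p, k) for n, p, k in product(InputLevel, repeat=3)]


def validate_rule_base(rules: Iterable[FuzzyRule]) -> None:
    """Check completeness, uniqueness, connective and the postulates.

    Raises :class:`RuleValidationError` on the first violation.
    """
    rules = list(rules)
    seen: dict[tuple, int] = {}
    for i, rule in enumerate(rules, start=1):
        if rule.connective != "AND":
            raise RuleValidationError(
                f"rule {i}: connective {rule.connective!r} not supported "
                "(the default system is AND-only)"
            )
        key = tuple(lvl for _, lvl in rule.antecedent)
        if key in seen:
            raise RuleValidationError(
                f"rules {seen[key]} and {i} share antecedent {key}"
            )
        seen[key] = i
    missing = [c for c in product(InputLevel, repeat=3) if c not in seen]
    if missing:
        raise RuleValidationError(
            f"rule base incomplete: {len(missing)} uncovered input combinations "
            f"(first: {missing[0]})"
        )
    for i, rule in enumerate(rules, start=1):
        ins, outs = rule.inputs, rule.outputs
        if ins["P"] in (InputLevel.HIGH, InputLevel.EXCESSIVE) and outs["R.P"] not in (
            OutputLevel.LOW,
            None,
        ):
            raise RuleValidationError(f"rule {i} violates postulate 1 (P high)")
        if ins["P"] is InputLevel.LOW and outs["R.P"] is not OutputLevel.HIGH:
            raise RuleValidationError(f"rule {i} violates postulate 2 (P low)")
        if outs["R.K"] is None:
            raise RuleValidationError(f"rule {i} violates postulate 4 (R.K NIL)")
        if ins["N"] in (InputLevel.HIGH, InputLevel.EXCESSIVE) and outs["R.N"] not in (
            OutputLevel.LOW,
            None,
        ):
            raise RuleValidationError(f"rule {i} violates postulate 5 (N high)")


# ---------------------------------------------------------------------------
# Rule DSL
#
#   IF N is L AND P is A AND K is H THEN R.N is M AND R.P is H AND R.K is L AND S.F is M
#
# Case-insensitive; '#' starts a comment; blank lines ignored.
# ---------------------------------------------------------------------------

_LINE_RE = re.compile(r"^\s*IF\s+(?P<ante>.+?)\s+THEN\s+(?P<cons>.+?)\s*$", re.IGNORECASE)
_CLAUSE_RE = re.compile(r"^\s*(?P<var>[A-Za-z][\w.]*)\s+is\s+(?P<val>[A-Za-z]+)\s*$", re.IGNORECASE)
_SPLIT_RE = re.compile(r"\s+(AND|OR)\s+", re.IGNORECASE)

_IN_CODES = {lvl.value: lvl for lvl in InputLevel}
_OUT_CODES: dict[str, Optional[OutputLevel]] = {lvl.value: lvl for lvl in OutputLevel}
_OUT_CODES["NIL"] = None


def _parse_clauses(text: str, lineno: int) -> tuple[list[tuple[str, str]], set[str]]:
    parts = _SPLIT_RE.split(text)
    clauses = parts[0::2]
    connectives = {c.upper() for c in parts[1::2]}
    out = []
    for clause in clauses:
        m = _CLAUSE_RE.match(clause)
        if not m:
            raise RuleParseError(f"malformed clause {clause!r}", lineno)
        out.append((m.group("var").upper(), m.group("val").upper()))
    return out, connectives


def parse_rules(text: str) -> list[FuzzyRule]:
    """Parse DSL text into rules.

    Malformed lines raise :class:`RuleParseError` with the line number;
    duplicate antecedents raise :class:`RuleValidationError`.  OR is parsed
    (recorded on the rule) but rejected by the system validator.
    """
    rules: list[FuzzyRule] = []
    seen: dict[tuple, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINE_RE.match(line)
        if not m:
            raise RuleParseError("expected 'IF ... THEN ...'", lineno)
        ante_clauses, ante_conn = _parse_clauses(m.group("ante"), lineno)
        cons_clauses, cons_conn = _parse_clauses(m.group("cons"), lineno)
        connective = "OR" if "OR" in (ante_conn | cons_conn) else "AND"

        ante: dict[str, InputLevel] = {}
        for var, val in ante_clauses:
            if var not in ANTECEDENT_VARS:
                raise RuleParseError(f"unknown input variable {var!r}", lineno)
            if var in ante:
                raise RuleParseError(f"input {var} repeated", lineno)
            if val not in _IN_CODES:
                raise RuleParseError(f"unknown input level {val!r} for {var}", lineno)
            ante[var] = _IN_CODES[val]
        cons: dict[str, Optional[OutputLevel]] = {}
        for var, val in cons_clauses:
            if var not in CONSEQUENT_VARS:
                raise RuleParseError(f"unknown output variable {var!r}", lineno)
            if var in cons:
                raise RuleParseError(f"output {var} repeated", lineno)
            if val not in _OUT_CODES:
                raise RuleParseError(f"unknown output level {val!r} for {var}", lineno)
            cons[var] = _OUT_CODES[val]
        missing_a = [v for v in ANTECEDENT_VARS if v not in ante]
        if missing_a:
            raise RuleParseError(f"incomplete antecedent: missing {missing_a}", lineno)
        missing_c = [v for v in CONSEQUENT_VARS if v not in cons]
        if missing_c:
            raise RuleParseError(f"incomplete consequent: missing {missing_c}", lineno)

        key = tuple(ante[v] for v in ANTECEDENT_VARS)
        if key in seen:
            raise RuleValidationError(
                f"line {lineno}: duplicate antecedent (first at line {seen[key]})"
            )
        seen[key] = lineno
        try:
            rules.append(
                FuzzyRule(
                    antecedent=tuple((v, ante[v]) for v in ANTECEDENT_VARS),
                    consequent=tuple((v, cons[v]) for v in CONSEQUENT_VARS),
                    connective=connective,
                )
            )
        except RuleValidationError as exc:
            raise RuleValidationError(f"line {lineno}: {exc}") from exc
    return rules


def serialize_rules(rules: Iterable[FuzzyRule]) -> str:
    """Render rules in the DSL, one per line (round-trips with parse_rules)."""
    lines = [
        "# Fuzzy fertilizer-recommendation rules.",
        "# Levels: inputs L/A/H/E; outputs L/M/H, NIL = no contribution.",
    ]
    for rule in rules:
        ante = f" {rule.connective} ".join(
            f"{v} is {lvl.value}" for v, lvl in rule.antecedent
        )
        cons = " AND ".join(
            f"{v} is {'NIL' if lvl is None else lvl.value}" for v, lvl in rule.consequent
        )
        lines.append(f"IF {ante} THEN {cons}")
    return "\n".join(lines) + "\n"
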