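"""Parameterized primitive checks and the custom rule-set loader.

User-defined formats are declared from a *closed* vocabulary of primitive
checks rather than arbitrary code, so a format document fully determines
validation behavior:

========================================  =====================================
primitive                                 parameters
========================================  =====================================
``required-header``                       ``header``, optional ``position``
                                          (first/second/third/last)
``unique-values-in-column``               ``column``
``character-class``                       ``allowed`` (string of characters),
                                          optional ``column`` (default: all
                                          cells), ``case_insensitive``
``fixed-length-column``                   ``column``, optional ``length``
                                          (default: modal length, ties broken
                                          toward the smaller length)
``non-empty``                             optional ``column``
``no-leading-trailing-whitespace``        optional ``column``
``datetime-format``                       ``column``, optional ``pattern``
                                          (strftime), ``calendar_aware``
``numeric-range``                         ``column``, ``minimum``, ``maximum``
========================================  =====================================

Documents are YAML (JSON is a YAML subset, so either works)::

    format_name: my-format
    dialect: csv
    rules:
      - id: id_unique
        check: unique-values-in-column
        column: ID
        severity: error

Empty cells are skipped by every primitive except ``non-empty``: emptiness
is one finding, not many, and a blank cell should not also be reported as
e.g. a length violation.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Mapping, Sequence

import yaml

from .errors import RulesetSpecError
from .grid import CellAddress, SheetGrid
from .rules import ALL_CELLS, Finding, Rule, RuleSet, Severity

_POSITIONS = {"first": 1, "second": 2, "third": 3}


def _as_severity(value: object, default: Severity) -> Severity:
    if value is None:
        return default
    return Severity(str(value))


# ---------------------------------------------------------------------------
# Datetime template
# ---------------------------------------------------------------------------

_FIELD_PATTERNS = {
    "%Y": r"\d{4}",
    "%m": r"\d{2}",
    "%d": r"\d{2}",
    "%H": r"\d{2}",
    "%M": r"\d{2}",
    "%S": r"\d{2}",
}
_FIELD_HUMAN = {
    "%Y": "YYYY",
    "%m": "MM",
    "%d": "DD",
    "%H": "hh",
    "%M": "mm",
    "%S": "ss",
}


@dataclass(frozen=True)
class DatetimeFormatSpec:
    """A strict, zero-padded datetime template.

    ``pattern`` is an strftime-style template built from %Y %m %d %H %M %S
    and literal text; the default renders as ``YYYY-MM-DD hh:mm:ss``.
    A value must match the template *shape* exactly (field order, widths,
    zero padding). When ``calendar_aware`` is set, the value must also name
    a real calendar date and time-of-day (Feb 30 or hour 25 are rejected;
    leap years follow the Gregorian rules).
    """

    pattern: str = "%Y-%m-%d %H:%M:%S"
    calendar_aware: bool = True

    def _template_regex(self) -> "re.Pattern[str]":
        parts: list[str] = []
        i = 0
        while i < len(self.pattern):
            token = self.pattern[i : i + 2]
            if token in _FIELD_PATTERNS:
                parts.append(_FIELD_PATTERNS[token])
                i += 2
            else:
                parts.append(re.escape(self.pattern[i]))
                i += 1
        return re.compile("".join(parts))

    def human_template(self) -> str:
        """The template with fields spelled out, e.g. ``YYYY-MM-DD hh:mm:ss``."""
        out = self.pattern
        for token, human in _FIELD_HUMAN.items():
            out = out.replace(token, human)
        return out

    def problem(self, value: str) -> str | None:
        """Why *value* is invalid, or ``None`` if it is accepted."""
        if self._template_regex().fullmatch(value) is None:
            return f"does not match the expected format {self.human_template()}"
        if self.calendar_aware:
            try:
                datetime.strptime(value, self.pattern)
            except ValueError:
                return "names an impossible calendar date or time"
        return None

    def render(self, dt: datetime) -> str:
        """Render a datetime back to the template text."""
        return dt.strftime(self.pattern)


# ---------------------------------------------------------------------------
# Primitive factories
# ---------------------------------------------------------------------------

def required_header(
    rule_id: str,
    *,
    header: str,
    position: str | None = None,
    severity: Severity = Severity.ERROR,
    description: str | None = None,
) -> Rule:
    """Sheet-scope rule: a header cell named *header* must exist.

    ``position`` pins it to a slot (``first``/``second``/``third``/``last``);
    without it the header may appear anywhere in row 1.
    """
    if position is not None and position not in (*_POSITIONS, "last"):
        raise RulesetSpecError(
            f"position must be one of first/second/third/last, got {position!r}"
        )

    def check(grid: SheetGrid, data_rows: Sequence[int]) -> list[Finding]:
        hdr = grid.cells[0]
        if position is None:
            if header not in hdr:
                return [((CellAddress(1, 1),), f"required header {header!r} is missing")]
            return []
        col = grid.n_cols if position == "last" else _POSITIONS[position]
        found = hdr[col - 1] if col <= len(hdr) else ""
        if found != header:
            return [
                (
                    (CellAddress(1, col),),
                    f"{position} header must be {header!r}, found {found!r}",
                )
            ]
        return []

    return Rule(
        rule_id=rule_id,
        description=description or f"header {header!r} must be present"
        + (f" in {position} position" if position else ""),
        default_severity=severity,
        scope="sheet",
        applies_to=None,
        check=check,
    )


def unique_values_in_column(
    rule_id: str,
    *,
    column: str | int,
    severity: Severity = Severity.ERROR,
    description: str | None = None,
) -> Rule:
    """Column-scope rule: non-empty values must be unique.

    Each repeated value yields one message addressing every member of the
    duplicate group. Empty cells are excluded (emptiness is a separate
    finding).
    """

    def check(cells: Sequence[tuple[CellAddress, str]]) -> list[Finding]:
        groups: dict[str, list[CellAddress]] = defaultdict(list)
        for addr, value in cells:
            if value.strip():
                groups[value].append(addr)
        return [
            (tuple(addrs), f"duplicate value {value!r}; values must be unique")
            for value, addrs in groups.items()
            if len(addrs) > 1
        ]

    return Rule(
        rule_id=rule_id,
        description=description or f"values in column {column!r} must be unique",
        default_severity=severity,
        scope="column",
        applies_to=column,
        check=check,
    )


def character_class(
    rule_id: str,
    *,
    allowed: str | frozenset[str],
    column: str | int = ALL_CELLS,
    case_insensitive: bool = False,
    severity: Severity = Severity.WARNING,
    description: str | None = None,
) -> Rule:
    """Cell-scope rule: every character must belong to *allowed*.

    The finding names the offending characters. With ``case_insensitive``
    the value is uppercased before the membership test (the convention for
    nucleotide sequences).
    """
    allowed_set = frozenset("".join(allowed).upper() if case_insensitive else allowed)

    def check(addr: CellAddress, value: str) -> list[Finding]:
        if not value:
            return []
        v = value.upper() if case_insensitive else value
        bad = set(v) - allowed_set
        if bad:
            listed = ", ".join(repr(c) for c in sorted(bad))
            return [((addr,), f"invalid character(s): {listed}")]
        return []

    return Rule(
        rule_id=rule_id,
        description=description or "characters must belong to the allowed class",
        default_severity=severity,
        scope="cell",
        applies_to=column,
        check=check,
    )


def fixed_length_column(
    rule_id: str,
    *,
    column: str | int,
    length: int | None = None,
    value_filter: Callable[[str], bool] | None = None,
    severity: Severity = Severity.ERROR,
    description: str | None = None,
) -> Rule:
    """Column-scope rule: values must share one length.

    Without an explicit ``length`` the expected length is the modal length
    of the column's (filtered, non-empty) values; a tie is broken toward
    the smaller length so the rule is deterministic. ``value_filter``
    restricts both the modal computation and the flagged cells to values
    satisfying the predicate — e.g. well-formed DNA barcodes — so cells
    that already violate a character rule do not skew the modal length.
    """

    def check(cells: Sequence[tuple[CellAddress, str]]) -> list[Finding]:
        eligible = [
            (addr, value)
            for addr, value in cells
            if value and (value_filter is None or value_filter(value))
        ]
        if not eligible:
            return []
        if length is not None:
            expected = length
        else:
            counts = Counter(len(v) for _, v in eligible)
            best = max(counts.values())
            expected = min(L for L, c in counts.items() if c == best)
        return [
            (
                (addr,),
                f"length {len(value)} differs from the expected length {expected}",
            )
            for addr, value in eligible
            if len(value) != expected
        ]

    return Rule(
        rule_id=rule_id,
        description=description or f"values in column {column!r} must share one length",
        default_severity=severity,
        scope="column",
        applies_to=column,
        check=check,
    )


def non_empty(
    rule_id: str,
    *,
    column: str | int = ALL_CELLS,
    severity: Severity = Severity.WARNING,
    description: str | None = None,
) -> Rule:
    """Cell-scope rule: flags empty or whitespace-only cells."""

    def check(addr: CellAddress, value: str) -> list[Finding]:
        if not value.strip():
            return [((addr,), "cell is empty")]
        return []

    return Rule(
        rule_id=rule_id,
        description=description or "cell must not be empty",
        default_severity=severity,
        scope="cell",
        applies_to=column,
        check=check,
    )


def no_leading_trailing_whitespace(
    rule_id: str,
    *,
    column: str | int = ALL_CELLS,
    severity: Severity = Severity.WARNING,
    description: str | None = None,
) -> Rule:
    """Cell-scope rule: flags values that differ from their trimmed form.

    Whitespace-only cells are left to the ``non-empty`` primitive.
    """

    def check(addr: CellAddress, value: str) -> list[Finding]:
        stripped = value.strip()
        if stripped and stripped != value:
            return [((addr,), "leading and/or trailing whitespace")]
        return []

    return Rule(
        rule_id=rule_id,
        description=description or "cell must have no leading/trailing whitespace",
        default_severity=severity,
        scope="cell",
        applies_to=column,
        check=check,
    )


def datetime_format(
    rule_id: str,
    *,
    column: str | int,
    pattern: str = "%Y-%m-%d %H:%M:%S",
    calendar_aware: bool = True,
    severity: Severity = Severity.ERROR,
    description: str | None = None,
) -> Rule:
    """Cell-scope rule: values must be datetimes in a fixed template."""
    spec = DatetimeFormatSpec(pattern=pattern, calendar_aware=calendar_aware)

    def check(addr: CellAddress, value: str) -> list[Finding]:
        if not value.strip():
            return []
        problem = spec.problem(value)
        if problem is not None:
            return [((addr,), f"invalid datetime {value!r}: {problem}")]
        return []

    return Rule(
        rule_id=rule_id,
        description=description
        or f"column {column!r} must hold datetimes shaped {spec.human_template()}",
        default_severity=severity,
        scope="cell",
        applies_to=column,
        check=check,
    )


def numeric_range(
    rule_id: str,
    *,
    column: str | int,
    minimum: float,
    maximum: float,
    severity: Severity = Severity.ERROR,
    description: str | None = None,
) -> Rule:
    """Cell-scope rule: values must parse as numbers within a closed interval."""

    def check(addr: CellAddress, value: str) -> list[Finding]:
        if not value.strip():
            return []
        try:
            x = float(value)
        except ValueError:
            return [((addr,), f"value {value!r} is not numeric")]
        if not (minimum <= x <= maximum):
            return [
                ((addr,), f"value {value!r} outside the range [{minimum}, {maximum}]")
            ]
        return []

    return Rule(
        rule_id=rule_id,
        description=description
        or f"column {column!r} must be numeric in [{minimum}, {maximum}]",
        default_severity=severity,
        scope="cell",
        applies_to=column,
        check=check,
    )


#: the closed vocabulary available to custom format documents
PRIMITIVES: Mapping[str, Callable[..., Rule]] = {
    "required-header": required_header,
    "unique-values-in-column": unique_values_in_column,
    "character-class": character_class,
    "fixed-length-column": fixed_length_column,
    "non-empty": non_empty,
    "no-leading-trailing-whitespace": no_leading_trailing_whitespace,
    "datetime-format": datetime_format,
    "numeric-range": numeric_range,
}

# value_filter is callable-only, never settable from a document
_DOC_FORBIDDEN_PARAMS = {"value_filter"}
_DECL_META_KEYS = {"id", "check", "severity", "description"}


def load_custom_ruleset(spec_text: str) -> RuleSet:
    """Build a :class:`RuleSet` from a YAML/JSON format document.

    Raises :class:`~sheetcheck.errors.RulesetSpecError` — naming the path of
    the offending declaration, e.g. ``rules[2].check`` — for unknown
    primitives, missing parameters or a malformed document.
    """
    try:
        doc = yaml.safe_load(spec_text)
    except yaml.YAMLError as exc:
        raise RulesetSpecError(f"malformed rule-set document: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise RulesetSpecError("rule-set document must be a mapping")
    format_name = doc.get("format_name")
    if not isinstance(format_name, str) or not format_name:
        raise RulesetSpecError("format_name: must be a non-empty string")
    dialect = doc.get("dialect")
    if dialect not in ("tsv", "csv"):
        raise RulesetSpecError(f"dialect: must be 'tsv' or 'csv', got {dialect!r}")
    decls = doc.get("rules", [])
    if not isinstance(decls, list):
        raise RulesetSpecError("rules: must be a list of rule declarations")

    rules: list[Rule] = []
    seen_ids: set[str] = set()
    for i, decl in enumerate(decls):
        path = f"rules[{i}]"
        if not isinstance(decl, Mapping):
            raise RulesetSpecError(f"{path}: declaration must be a mapping")
        name = decl.get("check")
        if name not in PRIMITIVES:
            raise RulesetSpecError(
                f"{path}.check: unknown check primitive {name!r}; "
                f"available: {sorted(PRIMITIVES)}"
            )
        rule_id = decl.get("id")
        if not isinstance(rule_id, str) or not rule_id:
            raise RulesetSpecError(f"{path}.id: must be a non-empty string")
        if rule_id in seen_ids:
            raise RulesetSpecError(f"{path}.id: duplicate rule id {rule_id!r}")
        seen_ids.add(rule_id)
        params = {
            str(k).replace("-", "_"): v
            for k, v in decl.items()
            if k not in _DECL_META_KEYS
        }
        forbidden = _DOC_FORBIDDEN_PARAMS & set(params)
        if forbidden:
            raise RulesetSpecError(
                f"{path}: parameter(s) {sorted(forbidden)} not allowed in documents"
            )
        try:
            severity = _as_severity(decl.get("severity"), Severity.ERROR)
        except ValueError as exc:
            raise RulesetSpecError(f"{path}.severity: {exc}") from exc
        factory = PRIMITIVES[name]
        try:
            rule = factory(
                rule_id,
                severity=severity,
                description=decl.get("description"),
                **params,
            )
        except TypeError as exc:
            raise RulesetSpecError(f"{path}: bad parameters for {name!r}: {exc}") from exc
        rules.append(rule)

    return RuleSet(
        format_name=format_name,
        dialect=dialect,
        rules=tuple(rules),
        comment_prefix=doc.get("comment_prefix"),
    )


def load_overrides(text: str) -> dict[str, object]:
    """Parse a YAML/JSON rule-override document into a plain mapping.

    The result feeds :func:`sheetcheck.rules.configure`, which validates
    rule ids and values against the target rule set.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RulesetSpecError(f"malformed overrides document: {exc}") from exc
    if doc is None:
        return {}
    if not isinstance(doc, Mapping):
        raise RulesetSpecError("overrides document must map rule ids to overrides")
    return dict(doc)
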