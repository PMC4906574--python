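"""Validation rule engine: rules, rule sets, reports.

A :class:`RuleSet` is an ordered collection of independent, pure
:class:`Rule` objects. Applying one to a :class:`~sheetcheck.grid.SheetGrid`
produces a :class:`ValidationReport` whose messages carry spreadsheet-style
cell addresses, a severity (``error`` outranks ``warning``) and the
human-readable reason a cell is invalid.

Design notes
------------
* Rules never mutate the grid and never observe each other; the report of a
  full rule set equals the union of single-rule runs. This independence is
  what makes rule-count scaling benchmarks meaningful.
* A finding may span several addresses (e.g. a pair of duplicate sample
  identifiers is *one* message addressing both cells); the per-cell index
  fans such messages out to each member cell.
* Severity belongs to the rule, with a per-run override mechanism
  (:func:`configure`) so users can relax stringency — e.g. disable the
  duplicate-barcode error when merging several studies into one sheet —
  without touching rule logic.
* Message order is rule order, then row-major address order, so exported
  reports are byte-stable for fixed inputs.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Callable, Iterable, Mapping, Sequence

from .errors import AddressBoundsError, ConfigurationError, SheetcheckError
from .grid import CellAddress, SheetGrid

#: selector meaning "every data cell in the sheet"
ALL_CELLS = "all"

#: pseudo rule id used for the empty-grid report
EMPTY_SHEET_RULE = "sheet_nonempty"


class Severity(str, enum.Enum):
    """Two validation severities; ``error`` outranks ``warning``."""

    ERROR = "error"
    WARNING = "warning"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


# A finding is (addresses, reason). The engine attaches severity and rule id.
Finding = tuple[tuple[CellAddress, ...], str]

SheetCheck = Callable[[SheetGrid, Sequence[int]], Iterable[Finding]]
ColumnCheck = Callable[[Sequence[tuple[CellAddress, str]]], Iterable[Finding]]
CellCheck = Callable[[CellAddress, str], Iterable[Finding]]


@dataclass(frozen=True)
class Rule:
    """One named, pure check with a scope and a default severity.

    ``scope`` decides the check signature the engine dispatches to:

    ``sheet``
        ``check(grid, data_rows)`` — sees the whole grid (header rules,
        cross-column rules).
    ``column``
        ``check(cells)`` with ``cells = [(address, value), ...]`` for the
        resolved column, header excluded (uniqueness, uniform length).
    ``cell``
        ``check(address, value)`` called once per data cell in scope
        (character classes, emptiness, whitespace).

    ``applies_to`` selects columns for column/cell scope: a header name,
    a 1-based positional index, or :data:`ALL_CELLS`. A named column absent
    from the grid simply skips the rule (the presence of required headers
    is itself enforced by sheet-scope rules).
    """

    rule_id: str
    description: str
    default_severity: Severity
    scope: str  # "sheet" | "column" | "cell"
    applies_to: str | int | None
    check: Callable

    def __post_init__(self) -> None:
        if self.scope not in ("sheet", "column", "cell"):
            raise SheetcheckError(f"unknown rule scope {self.scope!r}")


@dataclass(frozen=True)
class Override:
    """Per-run adjustment of one rule: disable it or change its severity."""

    disabled: bool = False
    severity: Severity | None = None


@dataclass(frozen=True)
class RuleSet:
    """An ordered, configurable collection of rules defining a format.

    ``comment_prefix``: when set, rows after the header whose first cell
    starts with this prefix are treated as comment rows and excluded from
    column- and cell-scope rules (the QIIME mapping convention uses ``#``).
    """

    format_name: str
    dialect: str
    rules: tuple[Rule, ...]
    overrides: Mapping[str, Override] = field(default_factory=dict)
    comment_prefix: str | None = None

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SheetcheckError(f"duplicate rule ids in rule set: {sorted(dupes)}")
        unknown = set(self.overrides) - set(ids)
        if unknown:
            raise ConfigurationError(
                f"overrides reference unknown rule ids {sorted(unknown)}; "
                f"valid ids: {sorted(ids)}"
            )

    @property
    def rule_ids(self) -> tuple[str, ...]:
        return tuple(r.rule_id for r in self.rules)

    def is_disabled(self, rule_id: str) -> bool:
        ov = self.overrides.get(rule_id)
        return ov.disabled if ov is not None else False

    def effective_severity(self, rule: Rule) -> Severity:
        ov = self.overrides.get(rule.rule_id)
        if ov is not None and ov.severity is not None:
            return ov.severity
        return rule.default_severity


@dataclass(frozen=True)
class ValidationMessage:
    """One reason attached to one or more cell addresses."""

    addresses: tuple[CellAddress, ...]
    severity: Severity
    reason: str
    rule_id: str

    def __post_init__(self) -> None:
        if not self.addresses:
            raise SheetcheckError("a validation message must address at least one cell")


@dataclass(frozen=True)
class ValidationReport:
    """The full outcome of validating one grid against one rule set.

    ``summary`` counts are derived from the message list: the number of
    distinct invalid cells, how many of those carry at least one error,
    how many carry warnings only (the two partition the invalid cells),
    and a per-rule message tally.
    """

    format_name: str
    messages: tuple[ValidationMessage, ...]
    n_rows: int
    n_cols: int

    @cached_property
    def per_cell_index(self) -> dict[CellAddress, tuple[ValidationMessage, ...]]:
        index: dict[CellAddress, list[ValidationMessage]] = {}
        for msg in self.messages:
            for addr in msg.addresses:
                index.setdefault(addr, []).append(msg)
        return {a: tuple(ms) for a, ms in index.items()}

    @cached_property
    def invalid_addresses(self) -> frozenset[CellAddress]:
        return frozenset(self.per_cell_index)

    @cached_property
    def summary(self) -> dict:
        error_cells = {
            a
            for a, msgs in self.per_cell_index.items()
            if any(m.severity is Severity.ERROR for m in msgs)
        }
        per_rule: dict[str, int] = {}
        for msg in self.messages:
            per_rule[msg.rule_id] = per_rule.get(msg.rule_id, 0) + 1
        return {
            "total_invalid_cells": len(self.per_cell_index),
            "error_cells": len(error_cells),
            "warning_only_cells": len(self.per_cell_index) - len(error_cells),
            "messages_per_rule": per_rule,
        }

    @property
    def has_errors(self) -> bool:
        return any(m.severity is Severity.ERROR for m in self.messages)

    @property
    def has_warnings(self) -> bool:
        return any(m.severity is Severity.WARNING for m in self.messages)

    def _check_bounds(self, addr: CellAddress) -> None:
        if addr.row > max(self.n_rows, 1) or addr.column > max(self.n_cols, 1):
            raise AddressBoundsError(
                f"address {addr.a1} outside the validated "
                f"{self.n_rows}x{self.n_cols} grid"
            )

    def messages_for_cell(self, addr: CellAddress) -> tuple[ValidationMessage, ...]:
        """All messages touching *addr*, in report order; empty for clean cells."""
        self._check_bounds(addr)
        return self.per_cell_index.get(addr, ())

    def cell_status(self, addr: CellAddress) -> str:
        """``"error"``, ``"warning"`` or ``"clean"`` — highest severity wins."""
        msgs = self.messages_for_cell(addr)
        if any(m.severity is Severity.ERROR for m in msgs):
            return "error"
        if msgs:
            return "warning"
        return "clean"


def messages_for_cell(
    report: ValidationReport, addr: CellAddress
) -> tuple[ValidationMessage, ...]:
    """Functional alias for :meth:`ValidationReport.messages_for_cell`."""
    return report.messages_for_cell(addr)


def cell_status(report: ValidationReport, addr: CellAddress) -> str:
    """Functional alias for :meth:`ValidationReport.cell_status`."""
    return report.cell_status(addr)


def _resolve_column(grid: SheetGrid, selector: str | int) -> int | None:
    if isinstance(selector, int):
        return selector if 1 <= selector <= grid.n_cols else None
    for i, h in enumerate(grid.cells[0]):
        if h == selector:
            return i + 1
    return None


def _data_row_indices(grid: SheetGrid, ruleset: RuleSet) -> list[int]:
    prefix = ruleset.comment_prefix
    rows = []
    for r in range(2, grid.n_rows + 1):
        if prefix and grid.cells[r - 1][0].startswith(prefix):
            continue
        rows.append(r)
    return rows


def _run_rule(grid: SheetGrid, data_rows: Sequence[int], rule: Rule) -> list[Finding]:
    if rule.scope == "sheet":
        return list(rule.check(grid, data_rows))
    if rule.scope == "column":
        col = _resolve_column(grid, rule.applies_to)
        if col is None:
            return []
        cells = [(CellAddress(r, col), grid.cells[r - 1][col - 1]) for r in data_rows]
        return list(rule.check(cells))
    # cell scope
    if rule.applies_to == ALL_CELLS:
        cols: Sequence[int] = range(1, grid.n_cols + 1)
    else:
        col = _resolve_column(grid, rule.applies_to)
        if col is None:
            return []
        cols = (col,)
    out: list[Finding] = []
    check = rule.check
    for r in data_rows:
        row = grid.cells[r - 1]
        for c in cols:
            out.extend(check(CellAddress(r, c), row[c - 1]))
    return out


def validate(grid: SheetGrid, ruleset: RuleSet) -> ValidationReport:
    """Apply every enabled rule of *ruleset* to *grid*.

    The report is deterministic for fixed inputs: messages appear in rule
    order, and within one rule in row-major order of their first address.
    An empty grid yields a single sheet-scope "no content" error.
    """
    if grid.n_rows == 0:
        msg = ValidationMessage(
            addresses=(CellAddress(1, 1),),
            severity=Severity.ERROR,
            reason="sheet has no content",
            rule_id=EMPTY_SHEET_RULE,
        )
        return ValidationReport(ruleset.format_name, (msg,), 0, 0)

    data_rows = _data_row_indices(grid, ruleset)
    messages: list[ValidationMessage] = []
    for rule in ruleset.rules:
        if ruleset.is_disabled(rule.rule_id):
            continue
        severity = ruleset.effective_severity(rule)
        findings = [
            (tuple(sorted(addrs)), reason)
            for addrs, reason in _run_rule(grid, data_rows, rule)
        ]
        findings.sort(key=lambda f: f[0])
        for addrs, reason in findings:
            messages.append(ValidationMessage(addrs, severity, reason, rule.rule_id))
    return ValidationReport(ruleset.format_name, tuple(messages), grid.n_rows, grid.n_cols)


def _normalize_override(rule_id: str, value: object) -> Override:
    if isinstance(value, Override):
        return value
    if isinstance(value, str):
        if value == "disabled":
            return Override(disabled=True)
        if value in ("error", "warning"):
            return Override(severity=Severity(value))
        raise ConfigurationError(
            f"override for {rule_id!r} must be 'disabled', 'error' or 'warning'; "
            f"got {value!r}"
        )
    if isinstance(value, Mapping):
        sev = value.get("severity")
        return Override(
            disabled=bool(value.get("disabled", False)),
            severity=Severity(sev) if sev is not None else None,
        )
    raise ConfigurationError(f"unsupported override value for {rule_id!r}: {value!r}")


def configure(ruleset: RuleSet, overrides: Mapping[str, object]) -> RuleSet:
    """Return a new RuleSet with *overrides* merged in; the original is unchanged.

    Accepted override values per rule id: the strings ``"disabled"``,
    ``"error"`` or ``"warning"``, a mapping with ``disabled`` and/or
    ``severity`` keys, or an :class:`Override`. Unknown rule ids raise
    :class:`~sheetcheck.errors.ConfigurationError` listing the valid ids.
    """
    valid = set(ruleset.rule_ids)
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown rule ids {sorted(unknown)}; valid ids: {sorted(valid)}"
        )
    merged = dict(ruleset.overrides)
    for rule_id, value in overrides.items():
        merged[rule_id] = _normalize_override(rule_id, value)
    return replace(ruleset, overrides=merged)


# ---------------------------------------------------------------------------
# Report export / import
# ---------------------------------------------------------------------------

def report_to_dict(report: ValidationReport) -> dict:
    """The JSON-ready form of a report (addresses in A1 notation)."""
    return {
        "format_name": report.format_name,
        "grid": {"n_rows": report.n_rows, "n_cols": report.n_cols},
        "messages": [
            {
                "addresses": [a.a1 for a in m.addresses],
                "severity": m.severity.value,
                "reason": m.reason,
                "rule_id": m.rule_id,
            }
            for m in report.messages
        ],
        "summary": report.summary,
    }


def report_to_json(report: ValidationReport, indent: int | None = 2) -> str:
    """Serialize *report* to a JSON document."""
    return json.dumps(report_to_dict(report), indent=indent)


def report_from_json(text: str) -> ValidationReport:
    """Reconstruct a :class:`ValidationReport` from :func:`report_to_json` output."""
    doc = json.loads(text)
    messages = tuple(
        ValidationMessage(
            addresses=tuple(CellAddress.from_a1(a) for a in m["addresses"]),
            severity=Severity(m["severity"]),
            reason=m["reason"],
            rule_id=m["rule_id"],
        )
        for m in doc["messages"]
    )
    return ValidationReport(
        format_name=doc["format_name"],
        messages=messages,
        n_rows=doc["grid"]["n_rows"],
        n_cols=doc["grid"]["n_cols"],
    )


def report_to_text(report: ValidationReport) -> str:
    """A human-readable rendering of *report* (summary plus one line per message)."""
    s = report.summary
    lines = [
        f"Format:        {report.format_name}",
        f"Grid:          {report.n_rows} rows x {report.n_cols} columns",
        f"Invalid cells: {s['total_invalid_cells']} "
        f"(with errors: {s['error_cells']}, warnings only: {s['warning_only_cells']})",
    ]
    if report.messages:
        lines.append("")
        addr_width = max(
            len(", ".join(a.a1 for a in m.addresses)) for m in report.messages
        )
        rule_width = max(len(m.rule_id) for m in report.messages)
        for m in report.messages:
            addrs = ", ".join(a.a1 for a in m.addresses)
            lines.append(
                f"{addrs:<{addr_width}}  {m.severity.value:<7}  "
                f"{m.rule_id:<{rule_width}}  {m.reason}"
            )
    return "\n".join(lines) + "\n"
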