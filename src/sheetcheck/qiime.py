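"""Built-in rule set for the QIIME sample metadata mapping file format.

A QIIME mapping file is a TSV whose header row starts with ``#SampleID``,
continues with ``BarcodeSequence`` and ``LinkerPrimerSequence``, and ends
with ``Description``. Sample identifiers must be unique and restricted to
alphanumerics plus period; barcodes are unambiguous DNA (A/C/G/T) of one
fixed length, unique per sample; linker primers use the full IUPAC
nucleotide alphabet, with commas separating multiple primers. Rows after
the header whose first cell starts with ``#`` are comments and are skipped.

Rule ids (stable public identifiers for override documents and reports):

====================================  ========  ==================================
rule id                               severity  what it flags
====================================  ========  ==================================
``header_first_sampleid``             error     first header is not ``#SampleID``
``header_last_description``           error     last header is not ``Description``
``header_duplicates``                 error     repeated header names
``sampleid_nonempty``                 error     empty sample identifier
``sampleid_characters``               error     id characters outside [a-zA-Z0-9.]
``sampleid_unique``                   error     duplicate sample identifiers
``barcode_characters``                error     barcode characters outside ACGT
``barcode_uniform_length``            error     barcode length differs from modal
``barcode_unique``                    error     duplicate barcode sequences
``primer_characters``                 error     non-IUPAC primer components
``cell_empty``                        warning   any empty data cell
``cell_leading_trailing_whitespace``  warning   untrimmed data cell
``cell_invalid_characters``           warning   characters outside the text class
====================================  ========  ==================================

The free-text character class is not part of the format specification
proper; the default here (alphanumerics, space and ``+ - % . / : , ; _ =``)
matches common QIIME-era metadata conventions and is configurable.

Only *format* compliance is checked: a QIIME mapping file places no
constraints on, say, a ``Date_Time`` metadata column, so invalid datetimes
pass QIIME validation (the SRGD format, by contrast, checks them).
"""

from __future__ import annotations

import string
from collections import defaultdict
from typing import Sequence

from .grid import CellAddress, SheetGrid
from .primitives import (
    character_class,
    fixed_length_column,
    no_leading_trailing_whitespace,
    non_empty,
    required_header,
    unique_values_in_column,
)
from .rules import (
    ALL_CELLS,
    Finding,
    Rule,
    RuleSet,
    Severity,
    ValidationMessage,
)

QIIME_FORMAT_NAME = "qiime-mapping"

SAMPLE_ID_HEADER = "#SampleID"
BARCODE_HEADER = "BarcodeSequence"
PRIMER_HEADER = "LinkerPrimerSequence"
DESCRIPTION_HEADER = "Description"

#: sample identifiers: alphanumerics plus period
SAMPLE_ID_CHARS = frozenset(string.ascii_letters + string.digits + ".")

#: unambiguous DNA, the barcode alphabet
DNA_CHARS = frozenset("ACGT")

#: IUPAC nucleotide codes, the primer alphabet (degenerate bases included)
IUPAC_DNA_CHARS = frozenset("ACGTRYSWKMBDHVN")

#: default free-text class for generic metadata cells
DEFAULT_TEXT_CHARS = frozenset(string.ascii_letters + string.digits + " +-%./:,;_=")

#: characters outside every class above — the error injector draws from
#: this pool so injected "invalid character" corruptions are detectable in
#: any column. ``#`` is deliberately absent: inserted at the start of a
#: first-column cell it would turn the row into a comment row.
FORBIDDEN_CHARS = "$?!*&@^~|"


def is_unambiguous_dna(value: str) -> bool:
    """True when *value* is non-empty and spells only A/C/G/T (any case)."""
    return bool(value) and set(value.upper()) <= DNA_CHARS


def _check_header_duplicates(grid: SheetGrid, data_rows: Sequence[int]) -> list[Finding]:
    groups: dict[str, list[CellAddress]] = defaultdict(list)
    for col, name in enumerate(grid.cells[0], start=1):
        if name.strip():
            groups[name].append(CellAddress(1, col))
    return [
        (tuple(addrs), f"duplicate header {name!r}")
        for name, addrs in groups.items()
        if len(addrs) > 1
    ]


def _primer_findings(addr: CellAddress, value: str) -> list[Finding]:
    # Comma separates multiple primers; each component must be non-empty
    # IUPAC nucleotide text.
    findings: list[Finding] = []
    for i, component in enumerate(value.split(","), start=1):
        if component == "":
            findings.append(((addr,), f"primer component {i} is empty"))
            continue
        bad = set(component.upper()) - IUPAC_DNA_CHARS
        if bad:
            listed = ", ".join(repr(c) for c in sorted(bad))
            findings.append(
                (
                    (addr,),
                    f"primer component {i} contains non-IUPAC character(s): {listed}",
                )
            )
    return findings


def _primer_rule(severity: Severity = Severity.ERROR) -> Rule:
    def check(addr: CellAddress, value: str) -> list[Finding]:
        if not value.strip():
            return []  # emptiness is cell_empty's finding
        return _primer_findings(addr, value)

    return Rule(
        rule_id="primer_characters",
        description="linker primer components must be IUPAC nucleotide sequences",
        default_severity=severity,
        scope="cell",
        applies_to=PRIMER_HEADER,
        check=check,
    )


def build_qiime_ruleset(
    *,
    text_chars: frozenset[str] = DEFAULT_TEXT_CHARS,
    skip_comment_rows: bool = True,
) -> RuleSet:
    """The complete QIIME mapping-file rule set (TSV dialect).

    ``text_chars`` customizes the free-text class used by the generic
    ``cell_invalid_characters`` warning; ``skip_comment_rows`` controls
    whether post-header rows beginning with ``#`` are excluded from
    validation (the QIIME convention).
    """
    rules = (
        required_header(
            "header_first_sampleid", header=SAMPLE_ID_HEADER, position="first"
        ),
        required_header(
            "header_last_description", header=DESCRIPTION_HEADER, position="last"
        ),
        Rule(
            rule_id="header_duplicates",
            description="header names must be unique",
            default_severity=Severity.ERROR,
            scope="sheet",
            applies_to=None,
            check=_check_header_duplicates,
        ),
        non_empty(
            "sampleid_nonempty", column=SAMPLE_ID_HEADER, severity=Severity.ERROR
        ),
        character_class(
            "sampleid_characters",
            column=SAMPLE_ID_HEADER,
            allowed=SAMPLE_ID_CHARS,
            severity=Severity.ERROR,
            description="sample identifiers may contain alphanumerics and period only",
        ),
        unique_values_in_column("sampleid_unique", column=SAMPLE_ID_HEADER),
        character_class(
            "barcode_characters",
            column=BARCODE_HEADER,
            allowed=DNA_CHARS,
            case_insensitive=True,
            severity=Severity.ERROR,
            description="barcodes must be unambiguous DNA (A/C/G/T)",
        ),
        fixed_length_column(
            "barcode_uniform_length",
            column=BARCODE_HEADER,
            value_filter=is_unambiguous_dna,
            description="barcodes must share one fixed length",
        ),
        unique_values_in_column("barcode_unique", column=BARCODE_HEADER),
        _primer_rule(),
        non_empty("cell_empty", column=ALL_CELLS),
        no_leading_trailing_whitespace(
            "cell_leading_trailing_whitespace", column=ALL_CELLS
        ),
        character_class(
            "cell_invalid_characters", column=ALL_CELLS, allowed=text_chars
        ),
    )
    return RuleSet(
        format_name=QIIME_FORMAT_NAME,
        dialect="tsv",
        rules=rules,
        comment_prefix="#" if skip_comment_rows else None,
    )


# ---------------------------------------------------------------------------
# Direct column/cell check entry points
# ---------------------------------------------------------------------------

def _messages(findings: list[Finding], severity: Severity, rule_id: str):
    return [
        ValidationMessage(tuple(sorted(addrs)), severity, reason, rule_id)
        for addrs, reason in findings
    ]


def check_barcode_column(
    values: Sequence[tuple[CellAddress, str]],
) -> list[ValidationMessage]:
    """Run the three barcode checks over one column's (address, value) pairs.

    Flags characters outside A/C/G/T per cell, lengths differing from the
    modal length of the well-formed barcodes, and duplicate groups (one
    multi-address message per repeated value). Empty cells are left to the
    generic emptiness rule.
    """
    ruleset = build_qiime_ruleset()
    by_id = {r.rule_id: r for r in ruleset.rules}
    out: list[ValidationMessage] = []
    for rule_id in ("barcode_characters", "barcode_uniform_length", "barcode_unique"):
        rule = by_id[rule_id]
        if rule.scope == "column":
            findings = list(rule.check(values))
        else:
            findings = [f for addr, v in values for f in rule.check(addr, v)]
        out.extend(_messages(findings, rule.default_severity, rule_id))
    return out


def check_primer_cell(addr: CellAddress, value: str) -> list[ValidationMessage]:
    """Check one linker-primer cell; one message per problem component."""
    if not value.strip():
        return []
    return _messages(_primer_findings(addr, value), Severity.ERROR, "primer_characters")


def check_generic_cell(
    addr: CellAddress,
    value: str,
    char_class: frozenset[str] = DEFAULT_TEXT_CHARS,
) -> list[ValidationMessage]:
    """Run the three generic cell checks (empty, whitespace, characters)."""
    out: list[ValidationMessage] = []
    if not value.strip():
        out.append(
            ValidationMessage((addr,), Severity.WARNING, "cell is empty", "cell_empty")
        )
        return out
    if value != value.strip():
        out.append(
            ValidationMessage(
                (addr,),
                Severity.WARNING,
                "leading and/or trailing whitespace",
                "cell_leading_trailing_whitespace",
            )
        )
    bad = set(value) - char_class
    if bad:
        listed = ", ".join(repr(c) for c in sorted(bad))
        out.append(
            ValidationMessage(
                (addr,),
                Severity.WARNING,
                f"invalid character(s): {listed}",
                "cell_invalid_characters",
            )
        )
    return out
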