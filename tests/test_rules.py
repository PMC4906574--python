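"""Rule engine: reports, configuration, and engine-level invariants."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheetcheck import (
    ALL_CELLS,
    AddressBoundsError,
    CellAddress,
    ConfigurationError,
    RuleSet,
    Severity,
    SheetGrid,
    configure,
    report_from_json,
    report_to_json,
    report_to_text,
    validate,
)
from sheetcheck.primitives import (
    character_class,
    no_leading_trailing_whitespace,
    non_empty,
    unique_values_in_column,
)

from conftest import make_qiime_grid


def generic_ruleset(overrides=None):
    """A small format used for engine-level tests: one unique column plus
    the three generic cell checks."""
    return RuleSet(
        format_name="generic-test",
        dialect="tsv",
        rules=(
            unique_values_in_column("id_unique", column="ID"),
            non_empty("cell_empty"),
            no_leading_trailing_whitespace("cell_whitespace"),
            character_class(
                "cell_chars", allowed=frozenset("abcdefghijklmnopqrstuvwxyz0123456789 ")
            ),
        ),
        overrides=overrides or {},
    )


def make_grid(rows):
    return SheetGrid(cells=tuple(tuple(r) for r in rows), source_dialect="tsv")


class TestValidate:
    def test_duplicate_ids_yield_one_multi_address_error(self, qiime_ruleset):
        # identical sample identifiers in spreadsheet rows 3 and 5
        grid = make_qiime_grid(
            [
                ("s1", "ACGT", "ACGT", "d1"),
                ("dup", "AAAA", "ACGT", "d2"),
                ("s3", "CCCC", "ACGT", "d3"),
                ("dup", "GGGG", "ACGT", "d4"),
            ]
        )
        report = validate(grid, qiime_ruleset)
        dup = [m for m in report.messages if m.rule_id == "sampleid_unique"]
        assert len(dup) == 1
        assert [a.a1 for a in dup[0].addresses] == ["A3", "A5"]
        assert dup[0].severity is Severity.ERROR

    def test_all_rules_disabled_yields_empty_report(self, qiime_ruleset):
        grid = make_qiime_grid([("dup", "ACGT", "ACGT", "d"), ("dup", "ACGT", "ACGT", "d")])
        disabled = configure(
            qiime_ruleset, {rid: "disabled" for rid in qiime_ruleset.rule_ids}
        )
        assert validate(grid, disabled).messages == ()

    def test_single_corrupted_cell_is_the_only_invalid_cell(self, qiime_ruleset):
        grid = make_qiime_grid(
            [("s1", "ACGT", "ACGT", "d1 "), ("s2", "TTTT", "ACGT", "d2")]
        )
        report = validate(grid, qiime_ruleset)
        assert {a.a1 for a in report.invalid_addresses} == {"D2"}

    def test_empty_grid_reports_no_content(self, qiime_ruleset):
        report = validate(SheetGrid(cells=()), qiime_ruleset)
        assert len(report.messages) == 1
        assert report.messages[0].severity is Severity.ERROR
        assert "no content" in report.messages[0].reason

    def test_missing_header_skips_column_rules_without_crash(self, qiime_ruleset):
        grid = make_grid([("Wrong", "Header"), ("dup", "x"), ("dup", "y")])
        report = validate(grid, qiime_ruleset)
        # header rules fire as sheet-scope errors ...
        assert {"header_first_sampleid", "header_last_description"} <= {
            m.rule_id for m in report.messages
        }
        # ... and the column rules bound to the absent headers stay silent
        assert "sampleid_unique" not in {m.rule_id for m in report.messages}

    def test_comment_rows_excluded_from_data_rules(self, qiime_ruleset):
        grid = make_qiime_grid(
            [("s1", "ACGT", "ACGT", "d1"), ("#a comment row!", "", "", "")]
        )
        assert validate(grid, qiime_ruleset).messages == ()

    def test_message_order_is_rule_order_then_row_major(self):
        grid = make_grid([("ID", "V"), ("", "x "), (" y", "")])
        report = validate(grid, generic_ruleset())
        keys = [(m.rule_id, m.addresses[0].a1) for m in report.messages]
        assert keys == [
            ("cell_empty", "A2"),
            ("cell_empty", "B3"),
            ("cell_whitespace", "B2"),
            ("cell_whitespace", "A3"),
        ]


class TestReportQueries:
    @pytest.fixture()
    def dup_report(self, qiime_ruleset):
        grid = make_qiime_grid(
            [
                ("dup", "ACGT", "ACGT", "d1"),
                (" b$d", "TTTT", "ACGT", "d2"),
                ("dup", "CCCC", "ACGT", "d3"),
            ]
        )
        return validate(grid, qiime_ruleset)

    def test_clean_cell_has_no_messages(self, dup_report):
        assert dup_report.messages_for_cell(CellAddress.from_a1("D2")) == ()
        assert dup_report.cell_status(CellAddress.from_a1("D2")) == "clean"

    def test_duplicate_member_sees_the_shared_message(self, dup_report):
        msgs = dup_report.messages_for_cell(CellAddress.from_a1("A2"))
        assert [m.rule_id for m in msgs] == ["sampleid_unique"]

    def test_cell_with_several_findings_returns_all(self, dup_report):
        # " b$d": bad characters for an id, leading whitespace, invalid char
        msgs = dup_report.messages_for_cell(CellAddress.from_a1("A3"))
        assert {m.rule_id for m in msgs} == {
            "sampleid_characters",
            "cell_leading_trailing_whitespace",
            "cell_invalid_characters",
        }

    def test_error_outranks_warning(self, dup_report):
        assert dup_report.cell_status(CellAddress.from_a1("A3")) == "error"

    def test_warning_only_cell(self, qiime_ruleset):
        grid = make_qiime_grid([("s1", "ACGT", "ACGT", " d1")])
        report = validate(grid, qiime_ruleset)
        assert report.cell_status(CellAddress.from_a1("D2")) == "warning"

    def test_out_of_bounds_address_raises(self, dup_report):
        with pytest.raises(AddressBoundsError):
            dup_report.messages_for_cell(CellAddress(99, 99))
        with pytest.raises(AddressBoundsError):
            dup_report.cell_status(CellAddress(1, 99))


class TestConfigure:
    def test_empty_overrides_is_identity(self, qiime_ruleset):
        grid = make_qiime_grid([("s1", "ACGT", "ACGT", "d"), ("s2", "ACGT", "ACGT", "d")])
        assert validate(grid, configure(qiime_ruleset, {})) == validate(
            grid, qiime_ruleset
        )

    def test_disable_duplicate_barcode_silences_only_that_rule(self, qiime_ruleset):
        grid = make_qiime_grid([("s1", "ACGT", "ACGT", "d"), ("s2", "ACGT", "ACGT", "d")])
        before = validate(grid, qiime_ruleset)
        assert {m.rule_id for m in before.messages} == {"barcode_unique"}
        after = validate(grid, configure(qiime_ruleset, {"barcode_unique": "disabled"}))
        assert after.messages == ()

    def test_severity_demotion_keeps_addresses(self, qiime_ruleset):
        grid = make_qiime_grid([("s1", "ACGT", "ACGT", "d"), ("s2", "ACGT", "ACGT", "d")])
        demoted = configure(qiime_ruleset, {"barcode_unique": "warning"})
        before = validate(grid, qiime_ruleset).messages[0]
        after = validate(grid, demoted).messages[0]
        assert after.addresses == before.addresses
        assert after.reason == before.reason
        assert after.severity is Severity.WARNING

    def test_original_ruleset_unchanged(self, qiime_ruleset):
        configure(qiime_ruleset, {"barcode_unique": "disabled"})
        assert not qiime_ruleset.is_disabled("barcode_unique")

    def test_unknown_rule_id_lists_valid_ids(self, qiime_ruleset):
        with pytest.raises(ConfigurationError, match="sampleid_unique"):
            configure(qiime_ruleset, {"frobnicate": "disabled"})

    def test_disabling_never_increases_invalid_cells(self, qiime_ruleset):
        grid = make_qiime_grid(
            [("dup", "ACGT", "ACGT", " d"), ("dup", "ACGT", "XY", "d$")]
        )
        full = validate(grid, qiime_ruleset)
        for rid in qiime_ruleset.rule_ids:
            partial = validate(grid, configure(qiime_ruleset, {rid: "disabled"}))
            assert partial.invalid_addresses <= full.invalid_addresses
            # findings of the other rules are untouched
            assert [m for m in partial.messages] == [
                m for m in full.messages if m.rule_id != rid
            ]


# hypothesis strategy: small ragged grids over a telling alphabet
_cell = st.text(alphabet="ab 1.$\t", max_size=5)
_grids = st.lists(
    st.tuples(_cell, _cell, _cell), min_size=1, max_size=8
).map(lambda rows: SheetGrid(cells=(("ID", "V", "W"),) + tuple(rows)))


class TestEngineProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(grid=_grids)
    def test_determinism(self, grid):
        ruleset = generic_ruleset()
        assert validate(grid, ruleset) == validate(grid, ruleset)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(grid=_grids)
    def test_union_property(self, grid):
        """The multiset of findings equals the union of single-rule runs."""
        ruleset = generic_ruleset()
        full = Counter(validate(grid, ruleset).messages)
        union = Counter()
        for rid in ruleset.rule_ids:
            solo = configure(
                ruleset, {other: "disabled" for other in ruleset.rule_ids if other != rid}
            )
            union.update(validate(grid, solo).messages)
        assert full == union

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(grid=_grids)
    def test_summary_rederivable_from_messages(self, grid):
        report = validate(grid, generic_ruleset())
        cells = {a for m in report.messages for a in m.addresses}
        error_cells = {
            a
            for m in report.messages
            if m.severity is Severity.ERROR
            for a in m.addresses
        }
        per_rule = Counter(m.rule_id for m in report.messages)
        assert report.summary == {
            "total_invalid_cells": len(cells),
            "error_cells": len(error_cells),
            "warning_only_cells": len(cells - error_cells),
            "messages_per_rule": dict(per_rule),
        }
        # error cells and warning-only cells partition the invalid cells
        assert (
            report.summary["error_cells"] + report.summary["warning_only_cells"]
            == report.summary["total_invalid_cells"]
        )


class TestReportExport:
    def test_json_round_trip(self, qiime_ruleset):
        grid = make_qiime_grid(
            [("dup", "ACGT", "ACGT", " d"), ("dup", "TTTT", "ACGT", "d")]
        )
        report = validate(grid, qiime_ruleset)
        restored = report_from_json(report_to_json(report))
        assert restored == report
        assert restored.summary == report.summary

    def test_text_rendering_mentions_addresses_and_counts(self, qiime_ruleset):
        grid = make_qiime_grid([("dup", "ACGT", "ACGT", "d"), ("dup", "TTTT", "ACGT", "d")])
        text = report_to_text(validate(grid, qiime_ruleset))
        assert "A2, A3" in text
        assert "Invalid cells: 2" in text
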