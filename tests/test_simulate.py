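"""Simulated mapping sheets and ground-truth error injection."""

import pytest

from sheetcheck import (
    CapacityError,
    CorruptionRecord,
    ERROR_TYPES,
    ParameterError,
    SimulationSpec,
    generate_valid_sheet,
    introduce_errors,
    load_corruption_log,
    save_corruption_log,
    validate,
)
from sheetcheck.qiime import DNA_CHARS


class TestGenerateValidSheet:
    def test_geometry_header_plus_rows(self):
        grid = generate_valid_sheet(SimulationSpec(n_rows=1000, seed=7))
        assert grid.n_rows == 1001
        assert grid.n_cols == 24

    def test_minimal_sheet(self, qiime_ruleset):
        grid = generate_valid_sheet(SimulationSpec(n_rows=1, seed=0))
        assert grid.n_rows == 2
        assert validate(grid, qiime_ruleset).messages == ()

    def test_seeded_determinism(self):
        spec = SimulationSpec(n_rows=40, seed=123)
        assert generate_valid_sheet(spec) == generate_valid_sheet(spec)

    def test_different_seeds_differ(self):
        a = generate_valid_sheet(SimulationSpec(n_rows=40, seed=1))
        b = generate_valid_sheet(SimulationSpec(n_rows=40, seed=2))
        assert a != b

    def test_column_plan(self):
        grid = generate_valid_sheet(SimulationSpec(n_rows=30, seed=5))
        ids = [row[0] for row in grid.cells[1:]]
        barcodes = [row[1] for row in grid.cells[1:]]
        primers = {row[2] for row in grid.cells[1:]}
        assert len(set(ids)) == 30  # unique sample identifiers
        assert len(set(barcodes)) == 30  # unique barcodes ...
        assert {len(b) for b in barcodes} == {12}  # ... of one fixed length
        assert all(set(b) <= DNA_CHARS for b in barcodes)
        assert len(primers) == 1  # one shared linker primer
        # unique-value columns have full variance; constant columns none
        for col in range(3, 13):
            assert len({row[col] for row in grid.cells[1:]}) == 30
        for col in range(13, 23):
            assert len({row[col] for row in grid.cells[1:]}) == 1

    def test_capacity_error_names_minimal_length(self):
        with pytest.raises(CapacityError, match="minimal sufficient length is 3"):
            generate_valid_sheet(SimulationSpec(n_rows=20, seed=0, barcode_length=2))

    def test_layout_mismatch_rejected(self):
        with pytest.raises(ParameterError, match="layout"):
            SimulationSpec(n_rows=5, n_cols=20)


class TestIntroduceErrors:
    def test_rate_zero_identity(self):
        grid = generate_valid_sheet(SimulationSpec(n_rows=20, seed=3))
        corrupted, records = introduce_errors(grid, 0.0, 9)
        assert corrupted == grid
        assert records == []

    @pytest.mark.parametrize(
        "n_rows,rate", [(10, 0.05), (100, 0.1), (1000, 0.05), (37, 0.013)]
    )
    def test_corruption_count_follows_rounding_formula(self, n_rows, rate):
        grid = generate_valid_sheet(SimulationSpec(n_rows=n_rows, seed=4))
        _, records = introduce_errors(grid, rate, 17)
        expected = int(rate * n_rows * 24 + 0.5)  # round half up
        assert len(records) == expected
        assert len({r.address for r in records}) == expected  # distinct cells

    def test_header_never_corrupted(self):
        grid = generate_valid_sheet(SimulationSpec(n_rows=10, seed=5))
        corrupted, records = introduce_errors(grid, 1.0, 21)
        assert corrupted.cells[0] == grid.cells[0]
        assert all(r.address.row >= 2 for r in records)

    def test_input_grid_unmodified(self):
        grid = generate_valid_sheet(SimulationSpec(n_rows=10, seed=6))
        before = grid.cells
        introduce_errors(grid, 0.5, 22)
        assert grid.cells == before

    def test_operators_apply_their_documented_transformation(self):
        grid = generate_valid_sheet(SimulationSpec(n_rows=50, seed=8))
        corrupted, records = introduce_errors(grid, 0.3, 23)
        assert {r.error_type for r in records} <= set(ERROR_TYPES)
        for r in records:
            new = corrupted.value_at(r.address)
            assert grid.value_at(r.address) == r.original_value
            if r.error_type == "empty":
                assert new == ""
            elif r.error_type == "whitespace":
                assert new != new.strip() and new.strip() == r.original_value
            else:
                assert len(new) == len(r.original_value) + 1
                assert new != r.original_value

    def test_seeded_determinism(self):
        grid = generate_valid_sheet(SimulationSpec(n_rows=30, seed=9))
        a = introduce_errors(grid, 0.2, 77)
        b = introduce_errors(grid, 0.2, 77)
        assert a == b

    def test_rate_out_of_range_rejected(self):
        grid = generate_valid_sheet(SimulationSpec(n_rows=5, seed=0))
        with pytest.raises(ParameterError):
            introduce_errors(grid, 1.5, 0)

    def test_corruption_preserves_uniqueness_of_id_and_barcode_columns(self):
        """Whitespace/invalid-char variants never collide two previously
        unique values, so no spurious duplicate findings can arise."""
        for seed in range(5):
            grid = generate_valid_sheet(SimulationSpec(n_rows=80, seed=seed))
            corrupted, _ = introduce_errors(grid, 0.25, seed + 31)
            for col in (0, 1):
                values = [r[col] for r in corrupted.cells[1:] if r[col].strip()]
                assert len(values) == len(set(values))

    def test_invalid_record_type_rejected(self):
        from sheetcheck import CellAddress

        with pytest.raises(ParameterError):
            CorruptionRecord(CellAddress(2, 1), "typo", "x")


class TestCorruptionLog:
    def test_json_round_trip(self, tmp_path):
        grid = generate_valid_sheet(SimulationSpec(n_rows=15, seed=2))
        _, records = introduce_errors(grid, 0.2, 44)
        path = tmp_path / "log.json"
        save_corruption_log(records, str(path))
        assert load_corruption_log(str(path)) == records
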