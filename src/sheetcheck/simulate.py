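"""Simulated QIIME mapping-file data and ground-truth error injection.

Two seeded operations drive all testing and benchmarking:

:func:`generate_valid_sheet`
    Builds a "typical" valid QIIME mapping sheet: a header row plus
    ``n_rows`` sample rows over exactly 24 columns — unique sample
    identifiers, unique fixed-length DNA barcodes, one shared 16S linker
    primer, several columns of unique values (simulating continuous
    metadata), several constant columns (no variance) and a description
    column. The result validates clean under the full QIIME rule set.

:func:`introduce_errors`
    Corrupts ``round(error_rate x data cells)`` distinct, uniformly chosen
    data cells (the header is never touched). Each corrupted cell receives
    one of three operators, chosen uniformly: make the cell empty,
    prepend/append whitespace, or insert an invalid character drawn from a
    pool outside every column's character class. Every corruption is
    detectable by construction, and a :class:`CorruptionRecord` logs the
    address, operator and original value — the exact ground truth a
    detection test or benchmark needs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, ParameterError
from .grid import CellAddress, SheetGrid
from .qiime import (
    BARCODE_HEADER,
    DESCRIPTION_HEADER,
    FORBIDDEN_CHARS,
    PRIMER_HEADER,
    SAMPLE_ID_HEADER,
)

#: the three corruption operators
ERROR_TYPES = ("empty", "whitespace", "invalid_chars")

#: the 515F 16S rRNA primer, a commonly used linker primer (note the
#: degenerate IUPAC base M)
DEFAULT_PRIMER = "GTGCCAGCMGCCGCGGTAA"

# constant-column vocabulary: study descriptors without variance
_CONSTANT_TOKENS = (
    "stool",
    "human",
    "IlluminaMiSeq",
    "V4",
    "515F806R",
    "ExtractionKitA",
    "FrozenMinus80",
    "2015",
    "RunOne",
    "ControlStudy",
)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated sheet.

    The default layout follows the benchmark geometry: 24 columns split as
    sample id, barcode, primer, 10 unique-value metadata columns, 10
    constant columns and a description; 12-base barcodes (the Golay-code
    length common in 16S studies).
    """

    n_rows: int
    n_cols: int = 24
    n_unique_cols: int = 10
    n_constant_cols: int = 10
    barcode_length: int = 12
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ParameterError(f"n_rows must be >= 1, got {self.n_rows}")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ParameterError(
                f"error_rate must lie in [0, 1], got {self.error_rate}"
            )
        fixed = 3 + self.n_unique_cols + self.n_constant_cols + 1
        if fixed != self.n_cols:
            raise ParameterError(
                f"layout mismatch: 3 fixed + {self.n_unique_cols} unique + "
                f"{self.n_constant_cols} constant + description = {fixed} "
                f"columns, but n_cols = {self.n_cols}"
            )


@dataclass(frozen=True)
class CorruptionRecord:
    """Ground truth for one injected error."""

    address: CellAddress
    error_type: str
    original_value: str

    def __post_init__(self) -> None:
        if self.error_type not in ERROR_TYPES:
            raise ParameterError(
                f"error_type must be one of {ERROR_TYPES}, got {self.error_type!r}"
            )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def minimal_barcode_length(n_rows: int) -> int:
    """Smallest barcode length whose 4^L alphabet covers *n_rows* barcodes."""
    length = 1
    while 4**length < n_rows:
        length += 1
    return length


def _unique_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n > 4**length:
        raise CapacityError(
            f"cannot draw {n} unique barcodes of length {length} "
            f"(alphabet holds {4**length}); minimal sufficient length is "
            f"{minimal_barcode_length(n)}"
        )
    alphabet = "ACGT"
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draws = rng.integers(0, 4, size=(n - len(out), length))
        for row in draws:
            bc = "".join(alphabet[k] for k in row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def generate_valid_sheet(spec: SimulationSpec) -> SheetGrid:
    """Generate a valid simulated QIIME mapping sheet (TSV dialect).

    Deterministic per ``spec.seed``: identical specs yield identical grids.
    Unique-value columns hold monotone decimal values with a random
    fractional part (the integer part is the row index, so uniqueness is
    guaranteed); constant columns repeat one randomly chosen token.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows

    header = (
        [SAMPLE_ID_HEADER, BARCODE_HEADER, PRIMER_HEADER]
        + [f"Metadata{i}" for i in range(1, spec.n_unique_cols + 1)]
        + [f"Constant{i}" for i in range(1, spec.n_constant_cols + 1)]
        + [DESCRIPTION_HEADER]
    )

    sample_ids = [f"S{i:06d}" for i in range(1, n + 1)]
    barcodes = _unique_barcodes(rng, n, spec.barcode_length)
    unique_cols = [
        [f"{i + frac:.6f}" for i, frac in enumerate(rng.random(n))]
        for _ in range(spec.n_unique_cols)
    ]
    constant_values = [
        str(rng.choice(_CONSTANT_TOKENS)) for _ in range(spec.n_constant_cols)
    ]
    descriptions = [f"Simulated.sample.{i}" for i in range(1, n + 1)]

    rows = [tuple(header)]
    for i in range(n):
        row = (
            [sample_ids[i], barcodes[i], DEFAULT_PRIMER]
            + [col[i] for col in unique_cols]
            + constant_values
            + [descriptions[i]]
        )
        rows.append(tuple(row))
    return SheetGrid(cells=tuple(rows), source_dialect="tsv")


def introduce_errors(
    grid: SheetGrid, error_rate: float, seed: int
) -> tuple[SheetGrid, list[CorruptionRecord]]:
    """Corrupt a copy of *grid* at the requested cell-level error rate.

    Exactly ``round(error_rate x n_data_cells)`` distinct data cells
    (header row excluded) are chosen uniformly; each receives one operator
    chosen uniformly from :data:`ERROR_TYPES`. Operators are guaranteed
    detectable: the empty operator blanks a non-empty cell, the whitespace
    operator pads a non-empty trimmed value, and the invalid-character
    operator inserts a character from :data:`~sheetcheck.qiime.FORBIDDEN_CHARS`
    (outside every column class). A cell that is already blank — possible
    only if *grid* is not a valid generated sheet — falls back to the
    invalid-character operator so the corruption stays detectable.

    Returns the corrupted grid (the input is unmodified) and the
    row-major-ordered ground-truth log.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ParameterError(f"error_rate must lie in [0, 1], got {error_rate}")
    if grid.n_rows < 2:
        raise ParameterError("grid must hold a header row and at least one data row")

    n_data_cells = (grid.n_rows - 1) * grid.n_cols
    n_corrupt = _round_half_up(error_rate * n_data_cells)
    if n_corrupt == 0:
        return grid, []

    rng = np.random.default_rng(seed)
    flat = rng.choice(n_data_cells, size=n_corrupt, replace=False)
    cells = [list(row) for row in grid.cells]
    records: list[CorruptionRecord] = []

    for f in sorted(flat.tolist()):
        row = 2 + f // grid.n_cols
        col = 1 + f % grid.n_cols
        original = cells[row - 1][col - 1]
        op = ERROR_TYPES[int(rng.integers(0, 3))]
        if not original.strip() and op != "invalid_chars":
            op = "invalid_chars"
        if op == "empty":
            corrupted = ""
        elif op == "whitespace":
            mode = int(rng.integers(0, 3))  # leading, trailing, or both
            corrupted = (
                " " + original
                if mode == 0
                else original + " "
                if mode == 1
                else " " + original + " "
            )
        else:
            ch = FORBIDDEN_CHARS[int(rng.integers(0, len(FORBIDDEN_CHARS)))]
            pos = int(rng.integers(0, len(original) + 1))
            corrupted = original[:pos] + ch + original[pos:]
        cells[row - 1][col - 1] = corrupted
        records.append(CorruptionRecord(CellAddress(row, col), op, original))

    corrupted_grid = SheetGrid(
        cells=tuple(tuple(r) for r in cells), source_dialect=grid.source_dialect
    )
    return corrupted_grid, records


def simulate_sheet(spec: SimulationSpec) -> tuple[SheetGrid, list[CorruptionRecord]]:
    """Generate a valid sheet and apply ``spec.error_rate`` in one step.

    The injector is seeded independently of the generator (``seed + 1``,
    kept below 2^31) so the corruption pattern does not replay the
    generator's draws.
    """
    grid = generate_valid_sheet(spec)
    return introduce_errors(grid, spec.error_rate, (spec.seed + 1) % (2**31))


# ---------------------------------------------------------------------------
# Ground-truth log persistence
# ---------------------------------------------------------------------------

def save_corruption_log(records: list[CorruptionRecord], path: str) -> None:
    """Write the ground-truth log as JSON (A1 addresses)."""
    doc = [
        {
            "address": r.address.a1,
            "error_type": r.error_type,
            "original_value": r.original_value,
        }
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_corruption_log(path: str) -> list[CorruptionRecord]:
    """Read a ground-truth log written by :func:`save_corruption_log`."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return [
        CorruptionRecord(
            address=CellAddress.from_a1(d["address"]),
            error_type=d["error_type"],
            original_value=d["original_value"],
        )
        for d in doc
    ]
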