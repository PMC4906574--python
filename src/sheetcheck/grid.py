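"""Rectangular text grid parsed from delimited files, with A1 addressing.

The validator operates on an in-memory stand-in for a spreadsheet: a
rectangular grid of *raw* string cells. Values are stored verbatim — no
trimming, no type coercion — because whitespace rules must see the original
text. Two dialects are supported:

``tsv``
    The QIIME mapping-file convention: tabs are hard delimiters, there is
    no quoting mechanism.
``csv``
    Standard CSV quoting rules (a quoted field may contain commas and
    newlines).

Cells are addressed 1-based, header row = 1, column A = 1, and rendered in
spreadsheet A1 notation with bijective base-26 column letters
(A..Z, AA, AB, ...).
"""

from __future__ import annotations

import csv as _csv
import io
import re
from dataclasses import dataclass
from typing import Iterable

from .errors import AddressParseError, EncodingError, SheetcheckError

DIALECTS = ("tsv", "csv")

_A1_RE = re.compile(r"^([A-Z]+)([0-9]+)$")


def column_to_letters(column: int) -> str:
    """Render a 1-based column index as bijective base-26 letters (1 -> A)."""
    if column < 1:
        raise ValueError(f"column must be >= 1, got {column}")
    letters = []
    n = column
    while n > 0:
        n, rem = divmod(n - 1, 26)
        letters.append(chr(ord("A") + rem))
    return "".join(reversed(letters))


def letters_to_column(letters: str) -> int:
    """Inverse of :func:`column_to_letters` (A -> 1, Z -> 26, AA -> 27)."""
    if not letters or not letters.isalpha():
        raise AddressParseError(f"invalid column letters: {letters!r}")
    n = 0
    for ch in letters.upper():
        n = n * 26 + (ord(ch) - ord("A") + 1)
    return n


@dataclass(frozen=True, order=True)
class CellAddress:
    """1-based (row, column) cell position; header row is row 1, A = 1.

    Ordering is row-major: addresses sort by row, then column, matching
    the top-to-bottom, left-to-right reading order of a sheet.
    """

    row: int
    column: int

    def __post_init__(self) -> None:
        if self.row < 1 or self.column < 1:
            raise ValueError(
                f"cell addresses are 1-based; got row={self.row}, column={self.column}"
            )

    @property
    def a1(self) -> str:
        """The address in A1 notation, e.g. ``O46``."""
        return f"{column_to_letters(self.column)}{self.row}"

    @classmethod
    def from_a1(cls, label: str) -> "CellAddress":
        """Parse an A1-notation label such as ``"A3"`` or ``"AB10"``."""
        m = _A1_RE.match(label.strip().upper())
        if m is None:
            raise AddressParseError(
                f"malformed A1 label {label!r}: expected letters then digits"
            )
        row = int(m.group(2))
        if row < 1:
            raise AddressParseError(f"malformed A1 label {label!r}: row must be >= 1")
        return cls(row=row, column=letters_to_column(m.group(1)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.a1


def address_to_a1(addr: CellAddress) -> str:
    """Render *addr* in A1 notation ((46, 15) -> ``"O46"``)."""
    return addr.a1


def a1_to_address(label: str) -> CellAddress:
    """Parse an A1-notation label into a :class:`CellAddress`."""
    return CellAddress.from_a1(label)


@dataclass(frozen=True)
class SheetGrid:
    """A rectangular grid of raw text cells.

    Invariants: every row holds exactly ``n_cols`` entries (short rows are
    padded with empty strings at parse time) and values are verbatim from
    the source file.
    """

    cells: tuple[tuple[str, ...], ...]
    source_dialect: str = "tsv"

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def contains(self, addr: CellAddress) -> bool:
        return addr.row <= self.n_rows and addr.column <= self.n_cols

    def value_at(self, addr: CellAddress) -> str:
        if not self.contains(addr):
            raise SheetcheckError(
                f"address {addr.a1} outside {self.n_rows}x{self.n_cols} grid"
            )
        return self.cells[addr.row - 1][addr.column - 1]


def _decode(data: bytes) -> str:
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise EncodingError(
            f"input is not valid UTF-8: undecodable byte at offset {exc.start}"
        ) from exc


def _split_rows(text: str, dialect: str) -> list[list[str]]:
    # Normalize line endings so \r\n files parse identically on every platform.
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    if dialect == "tsv":
        lines = text.split("\n")
        if lines and lines[-1] == "":  # trailing newline, not an empty row
            lines.pop()
        return [line.split("\t") for line in lines]
    reader = _csv.reader(io.StringIO(text))
    return [row for row in reader]


def parse_delimited(text: str | bytes, dialect: str = "tsv") -> SheetGrid:
    """Parse delimited text into a rectangular :class:`SheetGrid`.

    Short rows are padded with empty strings; rows that are entirely empty
    at the *bottom* of the file are dropped (trailing blank lines are file
    artifacts), while interior blank rows are kept as validatable content.

    Parameters
    ----------
    text:
        The file content. ``bytes`` are decoded as UTF-8; undecodable
        input raises :class:`~sheetcheck.errors.EncodingError` naming the
        byte offset.
    dialect:
        ``"tsv"`` (no quoting, tabs are hard delimiters) or ``"csv"``
        (standard quoting rules).
    """
    if dialect not in DIALECTS:
        raise SheetcheckError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if isinstance(text, bytes):
        text = _decode(text)
    rows = _split_rows(text, dialect)
    # Drop trailing all-empty rows.
    while rows and all(cell == "" for cell in rows[-1]):
        rows.pop()
    if not rows:
        return SheetGrid(cells=(), source_dialect=dialect)
    width = max(len(r) for r in rows)
    padded = tuple(tuple(r) + ("",) * (width - len(r)) for r in rows)
    return SheetGrid(cells=padded, source_dialect=dialect)


def to_delimited(grid: SheetGrid) -> str:
    """Serialize *grid* back to delimited text in its source dialect."""
    if grid.source_dialect == "tsv":
        return "".join("\t".join(row) + "\n" for row in grid.cells)
    buf = io.StringIO()
    writer = _csv.writer(buf, lineterminator="\n")
    writer.writerows(grid.cells)
    return buf.getvalue()


def read_sheet(path: str, dialect: str = "tsv") -> SheetGrid:
    """Read and parse a delimited file from *path*."""
    with open(path, "rb") as fh:
        return parse_delimited(fh.read(), dialect)


def write_sheet(grid: SheetGrid, path: str) -> None:
    """Write *grid* to *path* in its source dialect."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(to_delimited(grid))


def iter_addresses(grid: SheetGrid) -> Iterable[CellAddress]:
    """Yield every address of *grid* in row-major order."""
    for r in range(1, grid.n_rows + 1):
        for c in range(1, grid.n_cols + 1):
            yield CellAddress(r, c)
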