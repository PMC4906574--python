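# Methods

## Validation model

A sheet is a rectangular grid of raw text cells parsed from a delimited
file. Values are kept verbatim — no trimming, no type coercion — because
several rules are *about* the raw text (leading/trailing whitespace would
be invisible after normalization). Short rows are padded with empty
strings rather than rejected: exported spreadsheets are routinely ragged,
and a validator must be able to address every cell of the fixed-width
grid the user sees. Trailing all-empty rows are dropped as file artifacts;
*interior* blank rows are kept, because a blank row in the middle of a
table is user content a validator should flag, not a parsing detail.
The two dialects are pinned down exactly: `tsv` treats tabs as hard
delimiters with no quoting (the QIIME mapping convention), `csv` follows
standard quoting rules. Input is UTF-8; undecodable bytes fail fast with
the byte offset. Restricting content to ASCII, when wanted, is a
character-class rule, not a parse-time rejection.

Cells are addressed 1-based (header row = 1) and rendered in A1 notation
with bijective base-26 column letters; parsing and rendering are exact
inverses, which a property test quantifies over random addresses.

A rule is a named, pure check with a scope:

* **sheet** — sees the whole grid (header position/duplication rules);
* **column** — sees one resolved column's `(address, value)` pairs
  (uniqueness, uniform length);
* **cell** — sees one data cell at a time (character classes, emptiness,
  whitespace, datetimes, numeric ranges).

Rules are independent and never short-circuit one another, so the
multiset of findings from a full rule set equals the union over
single-rule runs (asserted as a property test), disabling a rule can only
remove its own findings, and the rule-count benchmark measures a real
per-rule cost. Severity is a property of the rule with a per-run override
(disable / demote / promote), which is the entire stringency-configuration
mechanism. Message order is rule order, then row-major order of each
finding's first address, so exported reports are byte-stable.

A cell's status is its highest-severity finding. The report summary counts
*distinct invalid cells*; cells carrying only warnings are included in
that count (they are highlighted to the user just as error cells are),
and "cells with ≥ 1 error" / "cells with warnings only" partition it.
This counting choice is an interpretation — one could instead count only
error cells — and is centralized in the report summary.

An empty grid (no rows after trailing-blank removal) yields a single
sheet-scope "no content" error rather than a crash; a rule bound to a
header absent from the grid is skipped silently, with the *presence* of
required headers enforced by dedicated sheet-scope rules.

## Built-in formats

**QIIME mapping (TSV).** Header layout (`#SampleID` first,
`BarcodeSequence`, `LinkerPrimerSequence`, …, `Description` last) follows
the QIIME mapping-file specification. Sample identifiers allow
alphanumerics plus period; barcodes are unambiguous DNA (A/C/G/T), unique,
and of one shared length; primers use the full IUPAC nucleotide alphabet
with commas separating multiple primers. Nucleotide checks uppercase
before testing membership, since sequence case is conventionally
insignificant. Rows after the header starting with `#` are comment rows,
excluded from data rules (a constructor flag disables this). Three generic
warnings apply to every data cell: empty, untrimmed, and characters
outside a free-text class. That class is not fixed by any published
specification; the default (alphanumerics, space and `+ - % . / : , ; _ =`)
matches common QIIME-era metadata conventions and is a documented,
configurable parameter rather than recovered ground truth. The same caveat
applies to the severity assignments.

Two deliberate details in the barcode rules:

* *Modal length.* The expected barcode length is the modal length of the
  column, with ties broken toward the smaller length (deterministic). The
  mode is computed over *well-formed* barcodes only (non-empty, pure
  A/C/G/T): a cell with stray whitespace or a foreign character already
  carries a character finding, and letting such cells vote on the modal
  length could mis-flag valid barcodes when corruption is heavy.
* *Duplicates.* Uniqueness rules ignore empty cells (emptiness is its own
  finding; a column with two blanks should not also report "duplicate
  empty value"). Each repeated value produces one message addressing every
  member of the group, mirroring how linked findings are displayed
  together.

**SRGD (CSV).** The format's defining constraint is that `Date_Time` must
hold valid datetimes in one specific template. The template here is a
configurable `DatetimeFormatSpec` defaulting to zero-padded
`YYYY-MM-DD hh:mm:ss`; validation first checks the template shape exactly
(field order, widths, padding) and then, when `calendar_aware` is set,
that the value names a real Gregorian date and time-of-day (Feb 30 and
hour 25 are rejected; leap years handled). Every accepted value
round-trips through a render step to identical text — the strictness
property that makes the template a format rather than a suggestion. The
remaining rules — required `Individual_ID`, unique record identifiers,
latitude in [−90, 90] and longitude in [−180, 180] (closed intervals,
boundaries valid) — are reconstructed from SRGD usage in the
geneGIS/Wildbook ecosystem rather than from a published column inventory,
and are individually disableable for that reason. Missing optional columns
(coordinates) are not findings.

## Simulator and error injector

The generator emulates "typical" valid mapping data at the benchmark
geometry: a header plus *n* sample rows over exactly 24 columns — sample
id, barcode, primer, 10 unique-value columns (simulating continuous
metadata), 10 constant columns (no variance), description. Defaults:
12-base barcodes (the Golay-code length common in 16S studies), the 515F
16S linker primer `GTGCCAGCMGCCGCGGTAA` in every primer cell (its
degenerate `M` also exercises the IUPAC path), unique-value columns of the
form `i.ffffff` (integer part = row index guarantees uniqueness; the
fractional part is random), constant columns drawn from a small vocabulary
of study descriptors. The 24-column split between unique-value and
constant columns is not published; 10/10 is this package's documented
default and is configurable. Requesting more rows than 4^length barcodes
exist fails with the minimal sufficient length. All draws come from one
seeded generator, so identical specifications yield identical grids.

The injector corrupts `round(rate × data cells)` distinct, uniformly
chosen data cells (round-half-up, so the count is exact and testable; the
header is never corrupted). "Error rate" therefore counts *cells*, one
operator per cell — matching the "percentage of invalid cells" framing —
not findings. Each corruption is one of three operators chosen uniformly:

* **empty** — replace the value with the empty string;
* **whitespace** — prepend and/or append a space (three sub-modes);
* **invalid characters** — insert one character from a documented
  forbidden pool (`$?!*&@^~|`) at a random position.

Every operator is detectable by construction against the full QIIME rule
set: generated values are non-empty and trimmed, the forbidden pool lies
outside every column's character class (and deliberately excludes `#`,
which at the start of a first-column cell would turn the row into a
comment row and hide it from validation), and a whitespace- or
symbol-bearing variant of a unique value cannot collide with any other
cell. Consequently the set of reported invalid cells equals the set of
corrupted addresses exactly — the detection-equality property the test
suite asserts across row counts {10, 100, 1000}, rates {0.01, 0.05, 0.25}
and 20 seeds per combination. On the off-spec input of a cell that is
already blank, the injector falls back to the invalid-character operator
so the corruption remains detectable.

What the simulator does *not* emulate: real metadata's heterogeneous
column types, missing-data conventions, near-duplicate identifiers,
encoding mishaps, or correlated errors (a dragged spreadsheet fill, a
column shifted by one). Passing the detection-equality tests shows the
rule set is sound and complete against these three injected error types
on well-structured sheets — not that it catches every way a real sheet
can be wrong.

## Benchmarks

Two harnesses time complete validations with `time.perf_counter`,
excluding generation and corruption. Row scaling generates a fresh sheet
per (rows × rate × replicate) point; rule scaling validates one fixed
valid 1000×24 sheet under N identical copies of the invalid-characters
rule, so each added rule has the same cost and the per-rule overhead is
isolated. Timings are reported as tidy TSV and never asserted against
absolute reference values — walltime is hardware-bound. The asserted
claims are shape only: median runtime (over 3 replicates) is
non-decreasing in rows and in rule count, and the log-log slope of
runtime vs rows over {10², 10³, 10⁴} stays at or below ~1.5, i.e.
near-linear. The default test problem sizes (10⁴ rows, 16 rules) keep the
full suite fast while spanning two decades on the row axis.

## Numerical and degenerate-input choices

* Rounding of the corruption count is half-up (`floor(x + 0.5)`), chosen
  over banker's rounding so documented examples like
  `round(0.05 × 24 000) = 1 200` hold exactly.
* Modal-length ties break toward the smaller length.
* Coordinate intervals are closed; `nan` fails the range check (it
  compares false), non-numeric text is its own finding.
* Empty cells are skipped by every primitive except `non-empty`, so one
  blank cell yields one finding, not a cascade.
* Seeds are plain integers; derived seeds (e.g. the injector's
  `seed + 1`) are reduced mod 2³¹.
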