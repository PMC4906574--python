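# sheetcheck

Cell-level validation of tabular bioinformatics metadata files.

Human-generated sample metadata is the input everything downstream depends
on, and it is usually compiled in spreadsheets by several people — study
coordinators, clinicians, lab technicians — most of whom never see the
format specification of the analysis software. `sheetcheck` validates two
widely used tabular formats cell by cell and reports every problem with a
spreadsheet-style address (`A3`, `O46`), a severity and a reason, so the
person who typed the value can find and fix it:

* the **QIIME sample metadata mapping file** (TSV): unique sample
  identifiers, unique fixed-length DNA barcodes (A/C/G/T), IUPAC linker
  primer sequences, positional header requirements, and generic cell
  hygiene (emptiness, stray whitespace, invalid characters);
* the **Spatially Referenced Genetic Data** format (SRGD.csv, used in the
  geneGIS/Wildbook ecosystem): unique record identifiers, strictly
  formatted calendar-aware `Date_Time` values, latitude/longitude ranges.

Validation is format-specific by design: a QIIME mapping file places no
constraint on a `Date_Time` metadata column, so an impossible datetime
passes QIIME validation and fails SRGD validation of the same sheet.

## The rule engine

A format is an ordered `RuleSet` of independent, pure, named rules. Each
rule has a scope (sheet, column or cell), a default severity (`error`
outranks `warning`) and a check; a finding may span several cells (a
duplicate pair is *one* message addressing both members). Because rules
never observe each other, the report of a full rule set equals the union
of single-rule runs, and stringency is configurable per run: any rule can
be disabled or demoted to a warning (e.g. allow duplicate barcodes when
merging several studies into one sheet) without touching rule logic.

Custom formats are declared in YAML/JSON from a closed vocabulary of
parameterized primitives (`required-header`, `unique-values-in-column`,
`character-class`, `fixed-length-column`, `non-empty`,
`no-leading-trailing-whitespace`, `datetime-format`, `numeric-range`), so
a document fully determines validation behavior.

A seeded simulator generates "typical" valid mapping sheets (n rows × 24
columns: sample id, barcode, primer, 10 unique-value metadata columns, 10
constant columns, description) and injects errors at a chosen rate —
`round(rate × data cells)` distinct cells, each hit by one of three
operators (empty the cell, pad with whitespace, insert an invalid
character) — logging exact ground truth for detection tests and scaling
benchmarks.

## Worked example

`map.tsv`, a small mapping file with two duplicate sample identifiers, two
duplicate barcodes and one untrimmed description:

```
#SampleID	BarcodeSequence	LinkerPrimerSequence	Description
PC.354	AGCACGAGCCTA	GTGCCAGCMGCCGCGGTAA	fecal1
PC.355	AACTCGTCGATG	GTGCCAGCMGCCGCGGTAA	fecal2
PC.354	ACAGACCACTCA	GTGCCAGCMGCCGCGGTAA	fecal3
PC.356	ACAGACCACTCA	GTGCCAGCMGCCGCGGTAA	 fecal4
```

```text
$ sheetcheck validate map.tsv
Format:        qiime-mapping
Grid:          5 rows x 4 columns
Invalid cells: 5 (with errors: 4, warnings only: 1)

A2, A4  error    sampleid_unique                   duplicate value 'PC.354'; values must be unique
B4, B5  error    barcode_unique                    duplicate value 'ACAGACCACTCA'; values must be unique
D5      warning  cell_leading_trailing_whitespace  leading and/or trailing whitespace
```

Five cells are invalid: the duplicate-identifier pair `A2`/`A4`, the
duplicate-barcode pair `B4`/`B5` (each pair is one linked message), and
`D5`, whose leading space is a warning. The exit status is 1 because
errors are present; `--disable barcode_unique` or an overrides document
would relax that rule, and `--output json` emits the same report as a
machine-readable document.

The same library surface is available in Python:

```python
from sheetcheck import build_qiime_ruleset, read_sheet, validate

report = validate(read_sheet("map.tsv"), build_qiime_ruleset())
report.summary["total_invalid_cells"]   # 5
report.cell_status(CellAddress.from_a1("A2"))  # "error"
```

Other subcommands: `sheetcheck simulate` writes a simulated sheet plus its
JSON ground-truth corruption log; `sheetcheck benchmark-rows` and
`sheetcheck benchmark-rules` run the two scaling benchmarks (runtime vs
rows at fixed 24 columns, and runtime vs number of applied rules on a
fixed valid 1000×24 sheet) and emit tidy TSV timing tables.

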