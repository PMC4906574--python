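"""Built-in rule set for the Spatially Referenced Genetic Data (SRGD) format.

SRGD (also written SRGD.csv) is a CSV format linking individual genetic
records to a location and a collection date-time, used in the
geneGIS/Wildbook ecosystem for mark-recapture and photo-identification
studies. The format requires each record to carry an identifier and a
``Date_Time`` value in one specific, fixed template; latitude and longitude,
when present, must be decimal degrees within the usual closed intervals.

Rule ids:

====================================  ========  ==================================
rule id                               severity  what it flags
====================================  ========  ==================================
``header_individual_id``              error     missing ``Individual_ID`` header
``header_date_time``                  error     missing ``Date_Time`` header
``record_id_unique``                  error     duplicate record identifiers
``datetime_valid``                    error     malformed or impossible datetimes
``latitude_range``                    error     latitude not numeric in [-90, 90]
``longitude_range``                   error     longitude not numeric in [-180, 180]
``cell_empty``                        warning   any empty data cell
``cell_leading_trailing_whitespace``  warning   untrimmed data cell
====================================  ========  ==================================

The published format description fixes the datetime *requirement* but the
template itself is configurable here (default ``YYYY-MM-DD hh:mm:ss``,
calendar-aware); the identifier and coordinate rules are reconstructed
conventions of SRGD usage and are individually disableable. Missing
*optional* columns (Latitude/Longitude) are not findings; missing required
headers are sheet-scope errors and skip the rules that depend on them.
"""

from __future__ import annotations

from .grid import CellAddress
from .primitives import (
    DatetimeFormatSpec,
    datetime_format,
    no_leading_trailing_whitespace,
    non_empty,
    numeric_range,
    required_header,
    unique_values_in_column,
)
from .rules import ALL_CELLS, RuleSet, Severity, ValidationMessage

__all__ = [
    "SRGD_FORMAT_NAME",
    "ID_HEADER",
    "DATETIME_HEADER",
    "LATITUDE_HEADER",
    "LONGITUDE_HEADER",
    "DatetimeFormatSpec",
    "DEFAULT_DATETIME_SPEC",
    "build_srgd_ruleset",
    "check_datetime_cell",
]

SRGD_FORMAT_NAME = "srgd"

ID_HEADER = "Individual_ID"
DATETIME_HEADER = "Date_Time"
LATITUDE_HEADER = "Latitude"
LONGITUDE_HEADER = "Longitude"

DEFAULT_DATETIME_SPEC = DatetimeFormatSpec()


def build_srgd_ruleset(
    *, datetime_spec: DatetimeFormatSpec = DEFAULT_DATETIME_SPEC
) -> RuleSet:
    """The complete SRGD rule set (CSV dialect)."""
    rules = (
        required_header("header_individual_id", header=ID_HEADER),
        required_header("header_date_time", header=DATETIME_HEADER),
        unique_values_in_column(
            "record_id_unique",
            column=ID_HEADER,
            description="record identifiers must be unique",
        ),
        datetime_format(
            "datetime_valid",
            column=DATETIME_HEADER,
            pattern=datetime_spec.pattern,
            calendar_aware=datetime_spec.calendar_aware,
        ),
        numeric_range(
            "latitude_range", column=LATITUDE_HEADER, minimum=-90.0, maximum=90.0
        ),
        numeric_range(
            "longitude_range", column=LONGITUDE_HEADER, minimum=-180.0, maximum=180.0
        ),
        non_empty("cell_empty", column=ALL_CELLS),
        no_leading_trailing_whitespace(
            "cell_leading_trailing_whitespace", column=ALL_CELLS
        ),
    )
    return RuleSet(format_name=SRGD_FORMAT_NAME, dialect="csv", rules=rules)


def check_datetime_cell(
    addr: CellAddress,
    value: str,
    spec: DatetimeFormatSpec = DEFAULT_DATETIME_SPEC,
) -> list[ValidationMessage]:
    """Check one ``Date_Time`` cell against *spec*.

    Distinguishes a template mismatch (wrong shape or field order) from a
    well-shaped value naming an impossible calendar date or time.
    """
    if not value.strip():
        return []
    problem = spec.problem(value)
    if problem is None:
        return []
    return [
        ValidationMessage(
            (addr,),
            Severity.ERROR,
            f"invalid datetime {value!r}: {problem}",
            "datetime_valid",
        )
    ]
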