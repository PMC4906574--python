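"""Scaling benchmarks: validation walltime vs sheet rows and vs rule count.

Two harnesses time full validations of simulated QIIME mapping sheets:

* :func:`run_row_scaling` grows the number of sample rows at fixed width
  (24 columns) across a grid of error rates;
* :func:`run_rule_scaling` holds a fixed valid 1000x24 sheet and applies
  N copies of a single rule (the invalid-characters check), so each added
  rule has an identical cost and the per-rule overhead is isolated.

Timings are *reported*, never compared against absolute reference values:
walltime depends on hardware. What is asserted elsewhere is shape only —
runtime is non-decreasing in rows and in rule count, and close to linear
in rows on log-log axes.
"""

from __future__ import annotations

import platform
import statistics
import time
from dataclasses import dataclass

import numpy as np

from .primitives import character_class
from .qiime import DEFAULT_TEXT_CHARS, build_qiime_ruleset
from .rules import ALL_CELLS, RuleSet, validate
from .simulate import SimulationSpec, generate_valid_sheet, introduce_errors


@dataclass(frozen=True)
class BenchmarkPoint:
    """One timing observation."""

    x: int  # rows or rule count, depending on the axis
    error_rate: float
    replicate: int
    runtime_s: float


@dataclass(frozen=True)
class BenchmarkResult:
    """A full benchmark run over one axis (``rows`` or ``rules``)."""

    axis: str
    points: tuple[BenchmarkPoint, ...]
    environment: str

    def median_runtimes(self) -> dict[tuple[int, float], float]:
        """Median runtime per (x, error_rate) over replicates."""
        groups: dict[tuple[int, float], list[float]] = {}
        for p in self.points:
            groups.setdefault((p.x, p.error_rate), []).append(p.runtime_s)
        return {k: statistics.median(v) for k, v in groups.items()}


def _environment_note() -> str:
    return f"python {platform.python_version()} on {platform.platform()}"


def _time_validation(grid, ruleset) -> float:
    t0 = time.perf_counter()
    validate(grid, ruleset)
    return time.perf_counter() - t0


def run_row_scaling(
    row_counts: list[int],
    error_rates: list[float],
    replicates: int = 3,
    seed: int = 0,
) -> BenchmarkResult:
    """Time full QIIME validations over a (rows x error-rate) grid.

    For each combination and replicate a fresh sheet is generated and
    corrupted (with per-run derived seeds), then a complete QIIME
    validation is timed. Generation and corruption are excluded from the
    timing.
    """
    if not row_counts or not error_rates:
        raise ValueError("row_counts and error_rates must be non-empty")
    ruleset = build_qiime_ruleset()
    rng = np.random.default_rng(seed)
    points: list[BenchmarkPoint] = []
    for n_rows in row_counts:
        for rate in error_rates:
            for rep in range(replicates):
                run_seed = int(rng.integers(0, 2**31))
                grid = generate_valid_sheet(
                    SimulationSpec(n_rows=n_rows, seed=run_seed)
                )
                grid, _ = introduce_errors(grid, rate, (run_seed + 1) % (2**31))
                points.append(
                    BenchmarkPoint(n_rows, rate, rep, _time_validation(grid, ruleset))
                )
    return BenchmarkResult("rows", tuple(points), _environment_note())


def run_rule_scaling(
    rule_counts: list[int],
    seed: int = 0,
    n_rows: int = 1000,
    replicates: int = 3,
) -> BenchmarkResult:
    """Time validation of one fixed valid sheet as the rule count grows.

    The rule set for count N holds N independent copies of the
    invalid-characters check applied to every cell; on a valid sheet each
    copy scans all cells and finds nothing, so runtime isolates the
    per-rule cost.
    """
    if any(n < 1 for n in rule_counts):
        raise ValueError("rule counts must be positive")
    grid = generate_valid_sheet(SimulationSpec(n_rows=n_rows, seed=seed))
    points: list[BenchmarkPoint] = []
    for n_rules in rule_counts:
        ruleset = replicated_invalid_characters_ruleset(n_rules)
        for rep in range(replicates):
            points.append(
                BenchmarkPoint(n_rules, 0.0, rep, _time_validation(grid, ruleset))
            )
    return BenchmarkResult("rules", tuple(points), _environment_note())


def replicated_invalid_characters_ruleset(n_rules: int) -> RuleSet:
    """A rule set of *n_rules* identical invalid-characters checks."""
    rules = tuple(
        character_class(
            f"cell_invalid_characters_{i:04d}",
            column=ALL_CELLS,
            allowed=DEFAULT_TEXT_CHARS,
        )
        for i in range(n_rules)
    )
    return RuleSet(
        format_name=f"invalid-characters-x{n_rules}",
        dialect="tsv",
        rules=rules,
        comment_prefix="#",
    )


def result_to_tsv(result: BenchmarkResult) -> str:
    """Tidy TSV rendering: one row per timing point."""
    lines = [f"# {result.environment}", f"axis\t{result.axis}"]
    lines.append("x\terror_rate\treplicate\truntime_s")
    for p in result.points:
        lines.append(f"{p.x}\t{p.error_rate}\t{p.replicate}\t{p.runtime_s:.6f}")
    return "\n".join(lines) + "\n"


def loglog_slope(xs: list[float], ys: list[float]) -> float:
    """Least-squares slope of log(y) against log(x)."""
    if len(xs) < 2:
        raise ValueError("need at least two points")
    return float(np.polyfit(np.log(xs), np.log(ys), 1)[0])
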