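"""Group comparison of enumeration-process distributions.

Per analysis condition, the 3 (process) x 2 (group) contingency table is
tested with a Pearson k x 2 chi-square (no continuity correction), the
effect size is Cramer's V

    V = sqrt( chi^2 / (n * min(k-1, c-1)) ),

interpreted with Cohen's df-specific benchmarks (df=1: 0.10/0.30/0.50;
df=2: 0.07/0.21/0.35 for small/medium/large), and - when the omnibus
test is significant - each process is followed up with a 2x2 cell test
(this process vs. the pooled others, by group), Bonferroni-adjusted by
the number of cell tests in the family.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gaze import ProcessKind, process_label
from .stimuli import Condition

__all__ = [
    "ContingencyTable",
    "OmnibusResult",
    "CellTestResult",
    "ConditionReport",
    "StatsError",
    "chi_square_kx2",
    "cramers_v",
    "interpret_v",
    "cell_tests",
    "condition_reports",
    "reports_to_json",
    "reports_to_csv",
    "format_report",
]

logger = logging.getLogger(__name__)

# Cohen's benchmarks for Cramer's V by degrees of freedom
_V_THRESHOLDS = {1: (0.10, 0.30, 0.50), 2: (0.07, 0.21, 0.35)}

DEFAULT_ALPHA = 0.05
DEFAULT_BONFERRONI_M = 3


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """k x 2 counts of trials per (process type, group)."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    condition: Condition | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] != 2:
            raise StatsError(f"expected a k x 2 table with k >= 2, got {c.shape}")
        if (c < 0).any():
            raise StatsError("counts must be non-negative")
        if c.sum() == 0:
            raise StatsError("empty table")


def from_process_table(counts: np.ndarray, group_order: Sequence[str],
                       condition: Condition) -> ContingencyTable:
    rows = tuple(process_label(k, condition) for k in ProcessKind)
    return ContingencyTable(counts=np.asarray(counts), row_labels=rows,
                            col_labels=tuple(group_order), condition=condition)


@dataclass(frozen=True)
class OmnibusResult:
    chi2: float
    df: int
    p: float
    v: float
    effect_label: str          # none / small / medium / large / unsupported-df
    n: int
    low_expected: bool         # any expected cell count < 5
    dropped_rows: tuple[int, ...] = ()


@dataclass(frozen=True)
class CellTestResult:
    process: ProcessKind
    chi2: float
    p_raw: float
    p_adj: float
    v: float
    direction: str             # group label that over-uses the process
    testable: bool = True


def chi_square_kx2(t: ContingencyTable) -> OmnibusResult:
    """Pearson chi-square on a k x 2 table, df = k - 1, no correction.

    All-zero rows are dropped with a warning (an unobserved process
    carries no information); a low-expected-count flag is raised when any
    expected cell falls below 5, but the plain Pearson statistic is kept.
    """
    counts = t.counts
    nonzero = counts.sum(axis=1) > 0
    dropped = tuple(int(i) for i in np.flatnonzero(~nonzero))
    if dropped:
        logger.warning("dropping all-zero rows %s from the table", dropped)
        counts = counts[nonzero]
    if counts.shape[0] < 2:
        raise StatsError("fewer than two non-empty rows; nothing to test")
    if (counts.sum(axis=0) == 0).any():
        raise StatsError("a group column is entirely zero")
    chi2, p, dof, expected = sps.chi2_contingency(counts, correction=False)
    n = int(counts.sum())
    k = counts.shape[0]
    v = cramers_v(chi2, n, k, 2)
    try:
        label = interpret_v(v, dof)
    except StatsError:
        label = "unsupported-df"
    return OmnibusResult(chi2=float(chi2), df=int(dof), p=float(p), v=v,
                         effect_label=label, n=n,
                         low_expected=bool((expected < 5).any()),
                         dropped_rows=dropped)


def cramers_v(chi2: float, n: int, k: int, c: int) -> float:
    """Cramer's V = sqrt(chi2 / (n * min(k-1, c-1))), clipped to [0, 1]."""
    if n <= 0:
        raise StatsError("n must be positive")
    m = min(k - 1, c - 1)
    if m < 1:
        raise StatsError("table must have at least 2 rows and 2 columns")
    return float(np.clip(np.sqrt(chi2 / (n * m)), 0.0, 1.0))


def interpret_v(v: float, df: int) -> str:
    """Cohen's effect-size label for Cramer's V at df = min(k-1, c-1)."""
    if df not in _V_THRESHOLDS:
        raise StatsError(
            f"no benchmarks for df={df}; supply custom thresholds")
    small, medium, large = _V_THRESHOLDS[df]
    if v >= large:
        return "large"
    if v >= medium:
        return "medium"
    if v >= small:
        return "small"
    return "none"


def cell_tests(t: ContingencyTable,
               bonferroni_m: int = DEFAULT_BONFERRONI_M) -> list[CellTestResult]:
    """2x2 follow-up per process: this type vs. pooled others, by group.

    Plain Pearson chi-square with df 1, Cramer's V per 2x2, Bonferroni
    adjustment p_adj = min(1, m * p_raw).  The direction names the group
    whose observed count for the process exceeds its expected count.  A
    collapsed table with a zero margin is flagged untestable.
    """
    if t.counts.shape[0] != 3:
        raise StatsError("cell tests are defined for 3 x 2 tables")
    col_tot = t.counts.sum(axis=0)
    n = int(t.counts.sum())
    results: list[CellTestResult] = []
    for idx, kind in enumerate(ProcessKind):
        a, b = t.counts[idx]
        sub = np.array([[a, b], [col_tot[0] - a, col_tot[1] - b]])
        if (sub.sum(axis=0) == 0).any() or (sub.sum(axis=1) == 0).any():
            results.append(CellTestResult(process=kind, chi2=float("nan"),
                                          p_raw=float("nan"),
                                          p_adj=float("nan"), v=float("nan"),
                                          direction="", testable=False))
            continue
        chi2, p, _, expected = sps.chi2_contingency(sub, correction=False)
        v = cramers_v(chi2, n, 2, 2)
        direction = t.col_labels[0] if a > expected[0, 0] else t.col_labels[1]
        results.append(CellTestResult(
            process=kind, chi2=float(chi2), p_raw=float(p),
            p_adj=float(min(1.0, bonferroni_m * p)), v=v,
            direction=direction))
    return results


@dataclass
class ConditionReport:
    condition: Condition
    table: ContingencyTable
    omnibus: OmnibusResult
    cells: list[CellTestResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition.value,
            "row_labels": list(self.table.row_labels),
            "col_labels": list(self.table.col_labels),
            "counts": self.table.counts.tolist(),
            "omnibus": {
                "chi2": self.omnibus.chi2, "df": self.omnibus.df,
                "p": self.omnibus.p, "v": self.omnibus.v,
                "effect_label": self.omnibus.effect_label,
                "n": self.omnibus.n,
                "low_expected": self.omnibus.low_expected,
            },
            "cell_tests": [
                {"process": int(c.process),
                 "process_label": process_label(c.process, self.condition),
                 "chi2": c.chi2, "p_raw": c.p_raw, "p_adj": c.p_adj,
                 "v": c.v, "direction": c.direction, "testable": c.testable}
                for c in self.cells
            ],
        }


_CONDITION_ORDER = (Condition.SUBITIZING_RANDOM, Condition.COUNTING_RANDOM,
                    Condition.DICE_CANONICAL, Condition.BEYOND_DICE_CANONICAL)


def condition_reports(counts: Mapping[Condition, np.ndarray],
                      group_order: Sequence[str],
                      alpha: float = DEFAULT_ALPHA,
                      bonferroni_m: int = DEFAULT_BONFERRONI_M
                      ) -> dict[Condition, ConditionReport]:
    """One omnibus test per condition, plus cell tests when significant.

    The four omnibus p-values are reported without family-wise adjustment
    by default; apply an external adjustment to ``alpha`` if desired.
    """
    missing = [c.value for c in _CONDITION_ORDER if c not in counts]
    if missing:
        raise StatsError(f"missing condition table(s): {', '.join(missing)}")
    out: dict[Condition, ConditionReport] = {}
    for cond in _CONDITION_ORDER:
        table = from_process_table(counts[cond], group_order, cond)
        omnibus = chi_square_kx2(table)
        cells = (cell_tests(table, bonferroni_m)
                 if omnibus.p < alpha else [])
        out[cond] = ConditionReport(condition=cond, table=table,
                                    omnibus=omnibus, cells=cells)
    return out


def reports_to_json(reports: Mapping[Condition, ConditionReport],
                    path: str | Path) -> None:
    payload = {c.value: reports[c].to_dict() for c in reports}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def reports_to_csv(reports: Mapping[Condition, ConditionReport],
                   path: str | Path) -> None:
    rows = []
    for cond, rep in reports.items():
        rows.append({"condition": cond.value, "test": "omnibus", "process": "",
                     "chi2": rep.omnibus.chi2, "df": rep.omnibus.df,
                     "p": rep.omnibus.p, "p_adj": "", "v": rep.omnibus.v,
                     "effect_label": rep.omnibus.effect_label,
                     "n": rep.omnibus.n, "direction": ""})
        for c in rep.cells:
            rows.append({"condition": cond.value, "test": "cell",
                         "process": process_label(c.process, cond),
                         "chi2": c.chi2, "df": 1, "p": c.p_raw,
                         "p_adj": c.p_adj, "v": c.v,
                         "effect_label": "", "n": rep.omnibus.n,
                         "direction": c.direction})
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def format_report(reports: Mapping[Condition, ConditionReport]) -> str:
    """Human-readable results text, one block per condition."""
    lines = []
    for cond, rep in reports.items():
        o = rep.omnibus
        lines.append(f"{cond.value}: chi2({o.df}) = {o.chi2:.2f}, "
                     f"p = {o.p:.3f}, V = {o.v:.2f} ({o.effect_label} effect), "
                     f"n = {o.n}")
        if o.low_expected:
            lines.append("  note: some expected cell counts < 5")
        if not rep.cells:
            lines.append("  omnibus not significant; no cell tests run")
        for c in rep.cells:
            if not c.testable:
                lines.append(f"  {process_label(c.process, cond)}: untestable "
                             "(zero margin)")
                continue
            lines.append(f"  {process_label(c.process, cond)}: chi2(1) = "
                         f"{c.chi2:.2f}, p_adj = {c.p_adj:.3f}, V = {c.v:.2f}, "
                         f"over-used by {c.direction}")
        lines.append("")
    return "\n".join(lines)
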