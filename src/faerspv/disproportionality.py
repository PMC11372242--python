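"""Disproportionality statistics for spontaneous-report signal detection.

For each event term (MedDRA preferred term or system organ class) and an
index-vs-comparator group design, a 2x2 contingency table is built:

====================  =============  ==================
                      event present  event absent
index group           a              b
comparator group      c              d
====================  =============  ==================

Two estimators are computed per term:

* the reporting odds ratio, ``ROR = ad/bc``, with Woolf 95% confidence
  interval ``exp(ln ROR +/- z*sqrt(1/a + 1/b + 1/c + 1/d))``;
* the Bayesian confidence propagation (BCPNN) information component with
  +0.5 shrinkage, ``IC = log2((n11 + 0.5) / (E11 + 0.5))`` where
  ``n11 = a``, ``E11 = (a+b)(a+c)/N``, and the closed-form lower 95% bound
  ``IC025 = IC - 3.3 (n11+0.5)^{-1/2} - 2 (n11+0.5)^{-3/2}``.

A term is flagged as a safety signal when ROR > 1 and both IC > 0 and
IC025 > 0 (strict inequalities).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .cohorts import CohortAssignment, Group
from .faers_io import CaseReport

logger = logging.getLogger(__name__)


class ZeroCellError(ValueError):
    """A zero contingency cell makes the ROR undefined without correction."""


@dataclass(frozen=True)
class ContingencyTable:
    a: float  # index group, event present
    b: float  # index group, event absent
    c: float  # comparator group, event present
    d: float  # comparator group, event absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self, delta: float = 0.5) -> "ContingencyTable":
        """Haldane-Anscombe continuity correction: add delta to every cell."""
        return ContingencyTable(self.a + delta, self.b + delta, self.c + delta, self.d + delta)


@dataclass
class SignalResult:
    event_term: str
    level: str  # "PT" or "SOC"
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    ic: float
    ic025: float

    @property
    def is_signal(self) -> bool:
        return flag_signal(self.ror, self.ic, self.ic025)


def compute_ror(
    table: ContingencyTable,
    z: float = 1.96,
    correction: bool = False,
    term: Optional[str] = None,
) -> tuple[float, float, float]:
    """ROR with Woolf CI; zero cells are a hard error unless corrected."""
    t = table
    if correction:
        t = t.corrected()
    if min(t.a, t.b, t.c, t.d) <= 0:
        what = f" for term {term!r}" if term else ""
        raise ZeroCellError(
            f"zero cell in contingency table{what}: "
            f"(a,b,c,d)=({table.a},{table.b},{table.c},{table.d}); "
            "enable the Haldane-Anscombe correction to proceed"
        )
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def compute_ic(table: ContingencyTable) -> tuple[float, float]:
    """BCPNN information component and its closed-form lower 95% bound."""
    n = table.n
    if n <= 0:
        raise ValueError("empty contingency table: IC undefined")
    n11 = table.a
    e11 = (table.a + table.b) * (table.a + table.c) / n
    ic = math.log2((n11 + 0.5) / (e11 + 0.5))
    ic025 = ic - 3.3 * (n11 + 0.5) ** -0.5 - 2.0 * (n11 + 0.5) ** -1.5
    return ic, ic025


def flag_signal(ror: float, ic: float, ic025: float) -> bool:
    """Signal criterion: ROR > 1 and IC > 0 and IC025 > 0, all strict."""
    return ror > 1.0 and ic > 0.0 and ic025 > 0.0


def _event_terms(report: CaseReport, level: str, pt_to_soc: Optional[Mapping[str, str]]) -> set[str]:
    pts = {pt.strip().lower() for pt in report.reaction_pts if pt.strip()}
    if level == "PT":
        return pts
    if pt_to_soc is None:
        raise ValueError("SOC-level counting requires a PT->SOC mapping")
    return {pt_to_soc.get(pt, "unmapped") for pt in pts}


GroupSpec = "Group | str | tuple"


def _as_groups(spec) -> frozenset[Group]:
    """Normalize a group spec: one group, or several pooled together."""
    if isinstance(spec, (Group, str)):
        spec = (spec,)
    groups = frozenset(Group(g) for g in spec)
    if Group.EXCLUDED in groups:
        raise ValueError("excluded is not an analysis group")
    if not groups:
        raise ValueError("empty group specification")
    return groups


def _group_members(
    assignments: Iterable[CohortAssignment],
    reports: Mapping[str, CaseReport] | Iterable[CaseReport],
    group_spec,
) -> list[CaseReport]:
    if not isinstance(reports, Mapping):
        reports = {r.primaryid: r for r in reports}
    groups = _as_groups(group_spec)
    return [
        reports[a.primaryid]
        for a in assignments
        if a.group in groups and a.primaryid in reports
    ]


def build_contingency(
    assignments: Iterable[CohortAssignment],
    reports: Iterable[CaseReport],
    event_term: str,
    level: str = "PT",
    index_group: Group | str = Group.COMBINATION,
    comparator_group: Group | str = Group.DRUG_B_ONLY,
    pt_to_soc: Optional[Mapping[str, str]] = None,
) -> ContingencyTable:
    """2x2 counts for one event term; each report counts once per term."""
    if _as_groups(index_group) & _as_groups(comparator_group):
        raise ValueError("index and comparator groups must not overlap")
    assignments = list(assignments)
    by_pid = {r.primaryid: r for r in reports}
    term = event_term.strip().lower()
    index = _group_members(assignments, by_pid, index_group)
    comp = _group_members(assignments, by_pid, comparator_group)
    a = sum(1 for r in index if term in _event_terms(r, level, pt_to_soc))
    c = sum(1 for r in comp if term in _event_terms(r, level, pt_to_soc))
    return ContingencyTable(a, len(index) - a, c, len(comp) - c)


def screen_all_terms(
    assignments: Iterable[CohortAssignment],
    reports: Iterable[CaseReport],
    level: str = "PT",
    index_group: Group | str = Group.COMBINATION,
    comparator_group: Group | str = Group.DRUG_B_ONLY,
    min_count: int = 3,
    z: float = 1.96,
    correction: bool = False,
    pt_to_soc: Optional[Mapping[str, str]] = None,
) -> list[SignalResult]:
    """Screen every event term with >= min_count index reports.

    Results are ranked by descending ROR, ties broken by descending index
    count then lexically by term.  Without the continuity correction, terms
    producing a zero cell raise a single error listing all of them.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if _as_groups(index_group) & _as_groups(comparator_group):
        raise ValueError("index and comparator groups must not overlap")
    assignments = list(assignments)
    by_pid = {r.primaryid: r for r in reports}
    index = _group_members(assignments, by_pid, index_group)
    comp = _group_members(assignments, by_pid, comparator_group)

    counts_index: dict[str, int] = {}
    counts_comp: dict[str, int] = {}
    for r in index:
        for term in _event_terms(r, level, pt_to_soc):
            counts_index[term] = counts_index.get(term, 0) + 1
    for r in comp:
        for term in _event_terms(r, level, pt_to_soc):
            counts_comp[term] = counts_comp.get(term, 0) + 1

    results: list[SignalResult] = []
    zero_terms: list[str] = []
    for term, a in counts_index.items():
        if a < min_count:
            continue
        c = counts_comp.get(term, 0)
        table = ContingencyTable(a, len(index) - a, c, len(comp) - c)
        try:
            ror, lo, hi = compute_ror(table, z=z, correction=correction, term=term)
        except ZeroCellError:
            zero_terms.append(term)
            continue
        ic, ic025 = compute_ic(table)
        results.append(SignalResult(term, level, table, ror, lo, hi, ic, ic025))
    if zero_terms:
        raise ZeroCellError(
            "zero contingency cells for term(s) "
            + ", ".join(repr(t) for t in sorted(zero_terms))
            + "; enable the Haldane-Anscombe correction or raise min_count"
        )
    results.sort(key=lambda r: (-r.ror, -r.table.a, r.event_term))
    return results


def signal_table(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Flat table of screening results, one row per event term."""
    return pd.DataFrame(
        {
            "term": r.event_term,
            "level": r.level,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "ror": r.ror,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "ic": r.ic,
            "ic025": r.ic025,
            "is_signal": r.is_signal,
        }
        for r in results
    )


def frequency_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-wise percentages: 100 * count / column total.

    Input is a table of event counts with one row per SOC and one numeric
    column per group (plus optionally a pooled Total column); output has the
    same shape with percentages.
    """
    totals = counts.sum(axis=0)
    return 100.0 * counts / totals


def soc_frequency_table(
    assignments: Iterable[CohortAssignment],
    reports: Iterable[CaseReport],
    pt_to_soc: Mapping[str, str],
) -> pd.DataFrame:
    """Event counts and percentages per SOC and group, plus a pooled Total.

    Counting is event-level: each distinct reaction PT of a report
    contributes one event to its SOC (a report with three PTs in one SOC
    adds three).  PTs absent from the mapping are tallied under "unmapped".
    Percentages are of the column's total event count.
    """
    assignments = list(assignments)
    by_pid = {r.primaryid: r for r in reports}
    groups = [g for g in Group if g is not Group.EXCLUDED]
    counts: dict[str, dict[str, int]] = {}
    unmapped = 0
    for a in assignments:
        report = by_pid.get(a.primaryid)
        if report is None:
            continue
        for pt in {p.strip().lower() for p in report.reaction_pts if p.strip()}:
            soc = pt_to_soc.get(pt)
            if soc is None:
                soc = "unmapped"
                unmapped += 1
            counts.setdefault(soc, {g.value: 0 for g in groups})
            counts[soc][a.group.value] += 1
    if unmapped:
        logger.warning("soc_frequency_table: %d unmapped PT event(s)", unmapped)
    table = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    for g in groups:
        if g.value not in table.columns:
            table[g.value] = 0
    table = table[[g.value for g in groups]]
    table.insert(0, "Total", table.sum(axis=1))
    table = table.sort_values("Total", ascending=False)
    pct = frequency_percentages(table)
    out = pd.concat({"count": table, "pct": pct}, axis=1)
    out.index.name = "soc"
    return out
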