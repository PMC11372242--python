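"""Time-to-onset analysis of adverse events across treatment groups.

Onset time is the number of days from the start of therapy to the reported
event date.  Spontaneous reports are event-driven, so by default every
onset record is treated as an observed event (no administrative
censoring) — the Kaplan-Meier curve then describes the distribution of
time-to-reported-event; an ``event_observed`` flag exists for synthetic
censoring studies.

Group distributions are compared by median/IQR (linear-interpolation
quartiles), Kaplan-Meier curves, the log-rank test, and Cox
proportional-hazards ratios (Breslow tie handling).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test as _ll_mv_logrank
from scipy import stats as _st
from statsmodels.duration.hazard_regression import PHReg

from .cohorts import CohortAssignment, Group
from .faers_io import CaseReport, DatePrecision

logger = logging.getLogger(__name__)


@dataclass
class OnsetRecord:
    primaryid: str
    group: Group
    onset_days: float
    event_observed: bool = True
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        if self.onset_days < 0:
            raise ValueError("onset_days must be non-negative")


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    @property
    def median(self) -> Optional[float]:
        """Smallest time with S(t) <= 0.5; None if the curve never reaches it."""
        below = self.survival <= 0.5
        if not below.any():
            return None
        return float(self.times[int(np.argmax(below))])


@dataclass
class ContrastResult:
    group: Group
    reference: Group
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class GroupComparison:
    stratum: str
    medians: dict[Group, tuple[float, float, float]]
    n_per_group: dict[Group, int]
    logrank_chi2: Optional[float]
    logrank_p: Optional[float]
    hazard_ratios: list[ContrastResult] = field(default_factory=list)


def compute_onset_days(
    report: CaseReport, date_mode: str = "strict"
) -> Optional[float]:
    """Days from earliest therapy start to event date; None if incomputable.

    ``strict`` requires day precision on both dates; ``imputed`` resolves
    month-precision dates to day 15 and year-precision to July 15.
    Negative differences (event before therapy) are excluded.
    """
    if date_mode not in ("strict", "imputed"):
        raise ValueError(f"unknown date_mode: {date_mode!r}")
    if report.event_date is None:
        return None
    starts = [m.therapy_start for m in report.drugs if m.therapy_start is not None]
    if not starts:
        return None
    impute = date_mode == "imputed"
    if not impute:
        if report.event_date.precision is not DatePrecision.DAY:
            return None
        starts = [s for s in starts if s.precision is DatePrecision.DAY]
        if not starts:
            return None
    start_dates = [s.to_date(impute=impute) for s in starts]
    start = min(d for d in start_dates if d is not None)
    event = report.event_date.to_date(impute=impute)
    if event is None:
        return None
    delta = (event - start).days
    return float(delta) if delta >= 0 else None


def build_onset_records(
    assignments: Iterable[CohortAssignment],
    reports: Iterable[CaseReport],
    date_mode: str = "strict",
) -> tuple[list[OnsetRecord], int]:
    """Onset records for the analysis cohort; returns (records, n_excluded)."""
    by_pid = {r.primaryid: r for r in reports}
    records: list[OnsetRecord] = []
    excluded = 0
    for a in assignments:
        report = by_pid.get(a.primaryid)
        if report is None:
            continue
        onset = compute_onset_days(report, date_mode=date_mode)
        if onset is None:
            excluded += 1
            continue
        records.append(OnsetRecord(a.primaryid, a.group, onset))
    if excluded:
        logger.info("build_onset_records: %d report(s) without computable onset", excluded)
    return records, excluded


def median_iqr(onsets: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) under the linear-interpolation (type-7) convention."""
    arr = np.asarray(list(onsets), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr: empty input")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def km_estimate(records: Sequence[OnsetRecord]) -> SurvivalCurve:
    """Product-limit survival curve of onset times."""
    if not records:
        raise ValueError("km_estimate: no records")
    durations = [r.onset_days for r in records]
    observed = [r.event_observed for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill().to_numpy(dtype=float)
    # drop the t=0 anchor row lifelines prepends unless an event occurred there
    return SurvivalCurve(times, surv, at_risk)


def logrank_test(
    records_g1: Sequence[OnsetRecord], records_g2: Sequence[OnsetRecord]
) -> tuple[float, Optional[float]]:
    """Two-group log-rank statistic and chi-square(1) p-value."""
    if not records_g1 or not records_g2:
        raise ValueError("logrank_test: both groups must be non-empty")
    res = _ll_logrank(
        [r.onset_days for r in records_g1],
        [r.onset_days for r in records_g2],
        event_observed_A=[r.event_observed for r in records_g1],
        event_observed_B=[r.event_observed for r in records_g2],
    )
    chi2 = float(res.test_statistic)
    if not math.isfinite(chi2):
        logger.warning("logrank_test: degenerate variance, p unavailable")
        return 0.0, None
    return chi2, float(res.p_value)


def cox_hr(
    records: Sequence[OnsetRecord],
    contrast: tuple[Group | str, Group | str],
    z: float = 1.959963984540054,
) -> ContrastResult:
    """Hazard ratio for one group vs a reference from a single-indicator fit.

    Partial likelihood with Breslow tie handling; Wald CI and p-value.
    """
    g_index, g_ref = Group(contrast[0]), Group(contrast[1])
    sub = [r for r in records if r.group in (g_index, g_ref)]
    if not sub:
        raise ValueError(f"cox_hr: no records for contrast {g_index} vs {g_ref}")
    for g in (g_index, g_ref):
        if not any(r.group is g and r.event_observed for r in sub):
            raise ValueError(f"cox_hr: no observed events in group {g.value}")
    endog = np.array([r.onset_days for r in sub], dtype=float)
    status = np.array([r.event_observed for r in sub], dtype=float)
    exog = np.array([[1.0 if r.group is g_index else 0.0] for r in sub])
    model = PHReg(endog, exog, status=status, ties="breslow")
    res = model.fit()
    beta = float(res.params[0])
    se = float(res.bse[0])
    if not (math.isfinite(beta) and math.isfinite(se)) or se == 0.0:
        raise RuntimeError(
            f"cox_hr: degenerate fit for {g_index.value} vs {g_ref.value} "
            f"(beta={beta}, se={se}); possible complete separation"
        )
    p = 2.0 * _st.norm.sf(abs(beta / se))
    return ContrastResult(
        g_index, g_ref, math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se), float(p)
    )


def compare_groups(
    records: Sequence[OnsetRecord],
    reference: Group | str = Group.COMBINATION,
    strata: Optional[dict[str, Sequence[OnsetRecord]]] = None,
    min_events: int = 5,
) -> list[GroupComparison]:
    """Median/IQR, k-group log-rank and per-group Cox HRs, per stratum.

    ``records`` is the overall stratum; ``strata`` maps stratum labels (a
    SOC or PT) to their record subsets.  Strata where any present group has
    fewer than ``min_events`` records are skipped and logged.  Hazard ratios
    contrast each non-reference group against ``reference``.
    """
    reference = Group(reference)
    all_strata: dict[str, Sequence[OnsetRecord]] = {"overall": records}
    if strata:
        all_strata.update(strata)
    out: list[GroupComparison] = []
    for label, recs in all_strata.items():
        groups = sorted({r.group for r in recs}, key=lambda g: g.value)
        per_group = {g: [r for r in recs if r.group is g] for g in groups}
        if not groups or min(len(v) for v in per_group.values()) < min_events:
            logger.info("compare_groups: stratum %r skipped (< %d records)", label, min_events)
            continue
        medians = {g: median_iqr([r.onset_days for r in v]) for g, v in per_group.items()}
        chi2 = p = None
        if len(groups) >= 2:
            mv = _ll_mv_logrank(
                [r.onset_days for r in recs],
                [r.group.value for r in recs],
                event_observed=[r.event_observed for r in recs],
            )
            chi2, p = float(mv.test_statistic), float(mv.p_value)
        contrasts = []
        if reference in per_group:
            for g in groups:
                if g is reference:
                    continue
                try:
                    contrasts.append(cox_hr(recs, (g, reference)))
                except (ValueError, RuntimeError) as exc:
                    logger.warning("compare_groups: %s", exc)
        out.append(
            GroupComparison(
                stratum=label,
                medians=medians,
                n_per_group={g: len(v) for g, v in per_group.items()},
                logrank_chi2=chi2,
                logrank_p=p,
                hazard_ratios=contrasts,
            )
        )
    return out


def comparison_table(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison objects to one row per stratum x group."""
    rows = []
    for comp in comparisons:
        hr_by_group = {c.group: c for c in comp.hazard_ratios}
        for g, (med, q1, q3) in comp.medians.items():
            c = hr_by_group.get(g)
            rows.append(
                {
                    "stratum": comp.stratum,
                    "group": g.value,
                    "n": comp.n_per_group[g],
                    "median_days": med,
                    "q1": q1,
                    "q3": q3,
                    "logrank_chi2": comp.logrank_chi2,
                    "logrank_p": comp.logrank_p,
                    "hr": c.hr if c else None,
                    "hr_ci_low": c.ci_low if c else None,
                    "hr_ci_high": c.ci_high if c else None,
                    "hr_p": c.p if c else None,
                }
            )
    return pd.DataFrame(rows)
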