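"""End-to-end analysis pipeline: ingest -> cohort -> signals -> onset.

Mirrors the screening flowchart of a comparative spontaneous-report study:
quarterly tables are parsed and joined, case versions deduplicated, reports
assigned to the combination / drug-A-only / drug-B-only groups, and then
SOC frequency tables, disproportionality screens (combination vs each
monotherapy) and time-to-onset comparisons are written to the run
directory together with a manifest accounting for every report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import faers_io
from .cohorts import (
    BREAST_CANCER_INDICATIONS,
    CohortAssignment,
    DrugDictionary,
    Group,
    IndicationList,
    assign_group,
    match_indication,
    summarize_demographics,
)
from .disproportionality import (
    SignalResult,
    screen_all_terms,
    signal_table,
    soc_frequency_table,
)
from .faers_io import CaseReport, JoinStats
from .synthetic import load_pt_soc
from .time_to_onset import (
    build_onset_records,
    compare_groups,
    comparison_table,
    km_estimate,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    pt_soc_path: Optional[str] = None  # defaults to <input_dir>/pt_soc.txt
    drug_a_terms: Sequence[str] = ("pembrolizumab",)
    drug_b_terms: Sequence[str] = ("paclitaxel",)
    match_mode: str = "substring"
    indication_terms: Sequence[str] = BREAST_CANCER_INDICATIONS
    window_start: Optional[str] = None  # "YYYYqN"
    window_end: Optional[str] = None
    z: float = 1.96
    correction: str = "haldane"  # "none" | "haldane"
    min_count: int = 3
    top_n: int = 10
    date_mode: str = "strict"  # "strict" | "imputed"
    min_events: int = 5
    comparator: str = "group"  # "group" | "pooled"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _window(config: RunConfig) -> Optional[list[str]]:
    if config.window_start is None and config.window_end is None:
        return None
    start = config.window_start or "1900q1"
    end = config.window_end or "2999q4"
    if start > end:
        raise PipelineError(f"analysis window start {start} after end {end}")
    quarters = []
    for year in range(int(start[:4]), int(end[:4]) + 1):
        for q in range(1, 5):
            label = f"{year}q{q}"
            if start <= label <= end:
                quarters.append(label)
    return quarters


def yearly_trend(reports: Sequence[CaseReport]) -> dict[int, int]:
    """Report counts per report year (reports lacking a year are dropped)."""
    counts: dict[int, int] = {}
    for r in reports:
        if r.report_year is not None:
            counts[r.report_year] = counts.get(r.report_year, 0) + 1
    return dict(sorted(counts.items()))


def export_forest_data(results: Sequence[SignalResult], top_n: int) -> pd.DataFrame:
    """Top-N screening rows in rank order, ready for forest plotting."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(results) < top_n:
        logger.warning("export_forest_data: only %d result(s) for top_n=%d", len(results), top_n)
    rows = results[:top_n]
    return pd.DataFrame(
        {
            "term": r.event_term,
            "ror": r.ror,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "ic": r.ic,
            "ic025": r.ic025,
        }
        for r in rows
    )


def _accounting(
    dedup_reports: Sequence[CaseReport],
    drug_dict: DrugDictionary,
    indications: IndicationList,
) -> tuple[list[CohortAssignment], dict[str, int]]:
    """Assign reports and attribute every one to a single flowchart bucket."""
    retained: list[CohortAssignment] = []
    tally = {"retained": 0, "no-indication": 0, "no-drug-rule": 0, "no-drugs": 0}
    for report in dedup_reports:
        if not report.drugs:
            tally["no-drugs"] += 1
            continue
        indication = match_indication(report, indications)
        if indication is None:
            tally["no-indication"] += 1
            continue
        assignment = assign_group(report, drug_dict)
        if assignment.group is Group.EXCLUDED:
            tally["no-drug-rule"] += 1
            continue
        assignment.matched_indication = indication
        retained.append(assignment)
        tally["retained"] += 1
    return retained, tally


def run_pipeline(config: RunConfig, stages: Sequence[str] = ("cohort", "screen", "tto")) -> dict:
    """Execute the analysis and write all output tables; returns the results.

    ``stages`` restricts the work: "cohort" always runs (everything depends
    on it); "screen" adds disproportionality outputs; "tto" the onset
    comparisons.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stats = JoinStats()
    tables = faers_io.load_bundle(config.input_dir, quarters=_window(config))
    reports = faers_io.join_case(tables, stats=stats)
    n_joined = len(reports)
    reports = faers_io.deduplicate(reports)
    n_dedup = len(reports)

    drug_dict = DrugDictionary(
        tuple(config.drug_a_terms), tuple(config.drug_b_terms), config.match_mode
    )
    indications = IndicationList(tuple(config.indication_terms))
    assignments, tally = _accounting(reports, drug_dict, indications)
    if not assignments:
        empty_filter = (
            "indication match" if tally["no-indication"] else "drug role rules"
        )
        raise PipelineError(
            f"empty cohort: the {empty_filter} filter removed the last report "
            f"(accounting: {tally})"
        )
    by_pid = {r.primaryid: r for r in reports}
    group_counts = {
        g.value: sum(1 for a in assignments if a.group is g)
        for g in Group
        if g is not Group.EXCLUDED
    }

    pt_soc_path = config.pt_soc_path or str(Path(config.input_dir) / "pt_soc.txt")
    pt_to_soc = load_pt_soc(pt_soc_path) if Path(pt_soc_path).exists() else {}
    correction = config.correction == "haldane"

    results: dict = {"assignments": assignments, "reports": reports}
    manifest = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "steps": {
            "raw_demo_rows": sum(
                len(t.rows) for t in tables if t.table_kind is faers_io.TableKind.DEMO
            ),
            "joined_cases": n_joined,
            "after_dedup": n_dedup,
            "dedup_removed": n_joined - n_dedup,
            **tally,
            "groups": group_counts,
        },
        "parse_skipped_lines": sum(t.skipped_lines for t in tables),
        "join_orphans": stats.orphan_rows,
        "invalid_dates": stats.invalid_dates,
    }

    # cohort-level outputs
    pd.DataFrame(
        {
            "primaryid": a.primaryid,
            "caseid": a.caseid,
            "group": a.group.value,
            "matched_indication": a.matched_indication,
        }
        for a in assignments
    ).to_csv(out_dir / "assignments.csv", index=False)
    demo = summarize_demographics(reports, assignments)
    demo.to_csv(out_dir / "demographics.csv", index=False)
    results["demographics"] = demo
    combo_reports = [
        by_pid[a.primaryid] for a in assignments if a.group is Group.COMBINATION
    ]
    trend = yearly_trend(combo_reports)
    pd.DataFrame({"year": list(trend), "count": list(trend.values())}).to_csv(
        out_dir / "yearly_trend.csv", index=False
    )
    results["yearly_trend"] = trend
    if pt_to_soc:
        soc = soc_frequency_table(assignments, reports, pt_to_soc)
        soc.to_csv(out_dir / "soc_frequency.csv")
        results["soc_frequency"] = soc

    if "screen" in stages:
        comparators: dict[str, object] = (
            {"pooled": (Group.DRUG_A_ONLY, Group.DRUG_B_ONLY)}
            if config.comparator == "pooled"
            else {
                "vs_drug_a_only": Group.DRUG_A_ONLY,
                "vs_drug_b_only": Group.DRUG_B_ONLY,
            }
        )
        results["signals"] = {}
        for label, comparator in comparators.items():
            screened = screen_all_terms(
                assignments,
                reports,
                level="PT",
                index_group=Group.COMBINATION,
                comparator_group=comparator,
                min_count=config.min_count,
                z=config.z,
                correction=correction,
                pt_to_soc=pt_to_soc or None,
            )
            signal_table(screened).to_csv(
                out_dir / f"signals_pt_combination_{label}.csv", index=False
            )
            export_forest_data(screened, config.top_n).to_csv(
                out_dir / f"forest_combination_{label}.csv", index=False
            )
            results["signals"][label] = screened

    if "tto" in stages:
        records, excluded = build_onset_records(
            assignments, reports, date_mode=config.date_mode
        )
        manifest["steps"]["onset_records"] = len(records)
        manifest["steps"]["onset_excluded"] = excluded
        if records:
            strata = {}
            if pt_to_soc:
                top_socs = (
                    soc_frequency_table(assignments, reports, pt_to_soc)["count"]["Total"]
                    .head(3)
                    .index
                )
                rec_pids = {r.primaryid for r in records}
                for soc in top_socs:
                    pids = {
                        a.primaryid
                        for a in assignments
                        if a.primaryid in rec_pids
                        and any(
                            pt_to_soc.get(p.strip().lower()) == soc
                            for p in by_pid[a.primaryid].reaction_pts
                        )
                    }
                    strata[soc] = [r for r in records if r.primaryid in pids]
            comparisons = compare_groups(
                records, reference=Group.COMBINATION, strata=strata,
                min_events=config.min_events,
            )
            tto = comparison_table(comparisons)
            tto.to_csv(out_dir / "tto_comparison.csv", index=False)
            results["tto"] = comparisons
            km_rows = []
            for g in sorted({r.group for r in records}, key=lambda g: g.value):
                curve = km_estimate([r for r in records if r.group is g])
                for t, s, n_at in zip(curve.times, curve.survival, curve.at_risk):
                    km_rows.append({"group": g.value, "t": t, "survival": s, "at_risk": n_at})
            pd.DataFrame(km_rows).to_csv(out_dir / "km_curves.csv", index=False)

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results
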