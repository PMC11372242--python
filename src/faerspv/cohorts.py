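"""Cohort construction: breast-cancer reports by drug role pattern.

Three analysis groups are built from the reporter-assigned drug roles
(PS primary suspect, SS secondary suspect, C concomitant, I interacting):

* ``drug_a_only``  — drug A as primary suspect, drug B absent in any role
  (default A = pembrolizumab);
* ``drug_b_only``  — symmetric (default B = paclitaxel);
* ``combination``  — A as PS with B in any role, or B as PS with A in any
  role.  A report naming both drugs as PS is also assigned here: both drugs
  are suspected and co-reported.

Reports fitting none of these patterns are excluded.  Only reports whose
drug indication matches the breast-cancer preferred-term list enter the
analysis set.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .faers_io import CaseReport, DrugMention

logger = logging.getLogger(__name__)

#: Breast-cancer indication preferred terms (matched case-insensitively,
#: whole-term, against each drug mention's reported indication).
BREAST_CANCER_INDICATIONS: tuple[str, ...] = (
    "breast cancer",
    "advanced breast cancer",
    "breast cancer female",
    "breast cancer female nos",
    "breast cancer in situ",
    "breast cancer male",
    "breast cancer metastatic",
    "breast cancer nos",
    "breast cancer recurrent",
    "breast cancer stage i",
    "breast cancer stage ii",
    "breast cancer stage iii",
    "breast cancer stage iv",
    "estrogen receptor positive breast cancer",
    "her2 negative breast cancer",
    "her2 positive breast cancer",
    "her-2 positive breast cancer",
    "hormone receptor negative her2 positive breast cancer",
    "hormone receptor positive breast cancer",
    "hormone receptor positive her2 negative breast cancer",
    "hormone refractory breast cancer",
    "infiltrating ductal breast cancer",
    "inflammatory breast cancer",
    "invasive ductal breast cancer",
    "metastatic breast cancer",
    "node-negative breast cancer",
    "node-positive breast cancer",
    "oestrogen receptor positive breast cancer",
    "triple negative breast cancer",
    "triple positive breast cancer",
)


class Group(str, Enum):
    COMBINATION = "combination"
    DRUG_A_ONLY = "drug_a_only"
    DRUG_B_ONLY = "drug_b_only"
    EXCLUDED = "excluded"


@dataclass
class DrugDictionary:
    """Search terms identifying the two study drugs.

    Matching is case-insensitive over both the verbatim drug name and the
    active-ingredient field; ``substring`` (the default) also catches
    formulations such as "nab-paclitaxel" and brand-name composites like
    "KEYTRUDA (PEMBROLIZUMAB)".
    """

    drug_a_terms: Sequence[str] = ("pembrolizumab",)
    drug_b_terms: Sequence[str] = ("paclitaxel",)
    match_mode: str = "substring"  # or "exact"

    def __post_init__(self) -> None:
        if not self.drug_a_terms or not self.drug_b_terms:
            raise ValueError("drug term lists must be non-empty")
        if self.match_mode not in ("substring", "exact"):
            raise ValueError(f"unknown match_mode: {self.match_mode!r}")


@dataclass
class IndicationList:
    terms: Sequence[str] = BREAST_CANCER_INDICATIONS

    def __post_init__(self) -> None:
        self._set = {t.strip().lower() for t in self.terms}

    def lookup(self, pt: Optional[str]) -> Optional[str]:
        if not pt:
            return None
        key = pt.strip().lower()
        return key if key in self._set else None


@dataclass
class CohortAssignment:
    primaryid: str
    caseid: str
    group: Group
    matched_indication: Optional[str] = None


def match_drug(
    mention: DrugMention,
    terms: Iterable[str],
    match_mode: str = "substring",
) -> bool:
    """True iff any search term matches the mention's name or ingredient."""
    candidates = [mention.name or ""]
    if mention.active_ingredient:
        candidates.append(mention.active_ingredient)
    candidates = [c.lower() for c in candidates]
    for term in terms:
        t = term.lower()
        if match_mode == "substring":
            if any(t in c for c in candidates):
                return True
        else:
            if any(t == c.strip() for c in candidates):
                return True
    return False


def match_indication(
    report: CaseReport, indications: IndicationList
) -> Optional[str]:
    """First breast-cancer term matched scanning the report's drug indications."""
    for mention in report.drugs:
        hit = indications.lookup(mention.indication_pt)
        if hit is not None:
            return hit
    return None


def assign_group(report: CaseReport, drug_dict: DrugDictionary) -> CohortAssignment:
    """Classify one report by its drug role pattern (see module docstring)."""
    mode = drug_dict.match_mode
    a_roles = {
        m.role for m in report.drugs if match_drug(m, drug_dict.drug_a_terms, mode)
    }
    b_roles = {
        m.role for m in report.drugs if match_drug(m, drug_dict.drug_b_terms, mode)
    }
    a_ps, b_ps = "PS" in a_roles, "PS" in b_roles
    if (a_ps and b_roles) or (b_ps and a_roles):
        group = Group.COMBINATION
    elif a_ps and not b_roles:
        group = Group.DRUG_A_ONLY
    elif b_ps and not a_roles:
        group = Group.DRUG_B_ONLY
    else:
        group = Group.EXCLUDED
    return CohortAssignment(report.primaryid, report.caseid, group)


def build_cohort(
    reports: Iterable[CaseReport],
    drug_dict: Optional[DrugDictionary] = None,
    indications: Optional[IndicationList] = None,
) -> list[CohortAssignment]:
    """Assign deduplicated reports to groups, keeping only indication matches.

    Returns one assignment per retained report (group != excluded and a
    breast-cancer indication present); group counts are logged.
    """
    drug_dict = drug_dict or DrugDictionary()
    indications = indications or IndicationList()
    out: list[CohortAssignment] = []
    for report in reports:
        if not report.drugs:
            continue
        indication = match_indication(report, indications)
        if indication is None:
            continue
        assignment = assign_group(report, drug_dict)
        if assignment.group is Group.EXCLUDED:
            continue
        assignment.matched_indication = indication
        out.append(assignment)
    counts = Counter(a.group.value for a in out)
    if not out:
        logger.warning("build_cohort: empty analysis set")
    else:
        logger.info("build_cohort: %s", dict(counts))
    return out


# ---------------------------------------------------------------------------
# demographics

WEIGHT_BANDS = ("<50 kg", "50~100 kg", ">100 kg", "Missing")
AGE_BANDS = ("18~64", "65~85", "Other", "Missing")
OUTCOME_LABELS = {
    "DE": "Death",
    "DS": "Disability",
    "HO": "Hospitalization - Initial or Prolonged",
    "LT": "Life-Threatening",
    "OT": "Other Serious (Important Medical Event)",
}


def _weight_band(kg: Optional[float]) -> str:
    if kg is None:
        return "Missing"
    if kg < 50:
        return "<50 kg"
    if kg <= 100:
        return "50~100 kg"
    return ">100 kg"


def _age_band(years: Optional[float]) -> str:
    if years is None:
        return "Missing"
    if 18 <= years <= 64:
        return "18~64"
    if 64 < years <= 85:
        return "65~85"
    return "Other"


def summarize_demographics(
    reports: Iterable[CaseReport],
    assignments: Iterable[CohortAssignment],
) -> pd.DataFrame:
    """Per-group counts of sex, weight band, age band and outcome category.

    Percentages come in two flavours: ``pct_pooled`` uses the pooled cohort
    size as denominator (the convention of published baseline tables that
    sum to 100 across all groups) and ``pct_group`` the group's own size.
    """
    by_pid = {r.primaryid: r for r in reports}
    rows = []
    groups = [g for g in Group if g is not Group.EXCLUDED]
    assignments = list(assignments)
    n_total = len(assignments)
    group_sizes = Counter(a.group for a in assignments)

    def tally(characteristic: str, band_of) -> None:
        counts: Counter = Counter()
        for a in assignments:
            report = by_pid.get(a.primaryid)
            if report is None:
                continue
            for band in band_of(report):
                counts[(band, a.group)] += 1
        bands = sorted({band for band, _ in counts})
        for band in bands:
            for g in groups:
                n = counts.get((band, g), 0)
                rows.append(
                    {
                        "characteristic": characteristic,
                        "band": band,
                        "group": g.value,
                        "count": n,
                        "pct_pooled": 100.0 * n / n_total if n_total else float("nan"),
                        "pct_group": 100.0 * n / group_sizes[g] if group_sizes[g] else float("nan"),
                    }
                )

    tally("Sex", lambda r: [{"F": "Female", "M": "Male"}.get(r.sex, "Unknown")])
    tally("Weight", lambda r: [_weight_band(r.weight_kg)])
    tally("Age", lambda r: [_age_band(r.age_years)])

    def outcome_bands(r: CaseReport) -> list[str]:
        labels = sorted({OUTCOME_LABELS[c] for c in r.outcomes if c in OUTCOME_LABELS})
        return labels or ["Missing"]

    tally("Outcome", outcome_bands)
    return pd.DataFrame(rows)
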