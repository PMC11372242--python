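"""Validation studies: printed-table checks and simulation-based operating
characteristics of the estimators.

Holds the reference values from the published FAERS comparative analysis of
pembrolizumab plus paclitaxel in breast cancer (reporting window 2016Q1 to
2023Q2) that this pipeline re-implements — the SOC frequency table and the
top disproportionality signals — together with the Monte-Carlo routines
that measure CI coverage, estimator bias, test size and survival-median
recovery on data generated by :mod:`faerspv.synthetic`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cohorts import Group
from .disproportionality import (
    ContingencyTable,
    compute_ic,
    compute_ror,
    frequency_percentages,
)
from .synthetic import OnsetDistribution, sample_event_counts
from .time_to_onset import OnsetRecord, cox_hr, km_estimate, logrank_test

# ---------------------------------------------------------------------------
# published reference values

#: SOC event counts per column (total, combination, paclitaxel-only,
#: pembrolizumab-only) as printed in the source study's frequency table.
PUBLISHED_SOC_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "General disorders and administration site conditions": (2877, 224, 2300, 353),
    "Respiratory, thoracic and mediastinal disorders": (2032, 73, 1863, 96),
    "Gastrointestinal disorders": (1993, 130, 1691, 172),
    "Nervous system disorders": (1846, 94, 1609, 143),
    "Skin and subcutaneous tissue disorders": (1735, 112, 1507, 116),
    "Blood and lymphatic system disorders": (1297, 215, 896, 186),
    "Investigations": (1224, 187, 854, 183),
    "Infections and infestations": (1043, 96, 852, 95),
    "Neoplasms benign, malignant and unspecified": (1003, 72, 774, 157),
    "Musculoskeletal and connective tissue disorders": (928, 45, 783, 100),
    "Vascular disorders": (892, 35, 837, 20),
    "Injury, poisoning and procedural complications": (867, 101, 507, 259),
    "Cardiac disorders": (724, 34, 642, 48),
    "Hepatobiliary disorders": (616, 52, 467, 97),
    "Metabolism and nutrition disorders": (498, 53, 376, 69),
    "Immune system disorders": (415, 31, 367, 17),
    "Eye disorders": (381, 10, 341, 30),
    "Renal and urinary disorders": (326, 40, 246, 40),
    "Psychiatric disorders": (311, 15, 254, 42),
    "Endocrine disorders": (232, 95, 37, 100),
    "Surgical and medical procedures": (151, 39, 47, 65),
    "Ear and labyrinth disorders": (56, 2, 54, 0),
    "Reproductive system and breast disorders": (56, 6, 45, 5),
    "Social circumstances": (54, 25, 22, 7),
    "Congenital, familial and genetic disorders": (52, 7, 42, 3),
    "Product issues": (22, 2, 16, 4),
}

#: The percentages printed alongside the counts, same column order.
PUBLISHED_SOC_PCT: dict[str, tuple[float, float, float, float]] = {
    "General disorders and administration site conditions": (13.3, 12.48, 13.20, 14.67),
    "Respiratory, thoracic and mediastinal disorders": (9.39, 4.07, 10.69, 3.99),
    "Gastrointestinal disorders": (9.21, 7.24, 9.70, 7.15),
    "Nervous system disorders": (8.53, 5.24, 9.23, 5.94),
    "Skin and subcutaneous tissue disorders": (8.02, 6.24, 8.65, 4.82),
    "Blood and lymphatic system disorders": (6.00, 11.98, 5.14, 7.73),
    "Investigations": (5.66, 10.42, 4.90, 7.60),
    "Infections and infestations": (4.82, 5.35, 4.89, 3.95),
    "Neoplasms benign, malignant and unspecified": (4.64, 4.01, 4.44, 6.52),
    "Musculoskeletal and connective tissue disorders": (4.29, 2.51, 4.49, 4.15),
    "Vascular disorders": (4.12, 1.95, 4.80, 0.83),
    "Injury, poisoning and procedural complications": (4.01, 5.63, 2.91, 10.76),
    "Cardiac disorders": (3.34, 1.89, 3.68, 1.99),
    "Hepatobiliary disorders": (2.84, 2.90, 2.68, 4.03),
    "Metabolism and nutrition disorders": (2.30, 2.95, 2.16, 2.87),
    "Immune system disorders": (1.91, 1.73, 2.11, 0.71),
    "Eye disorders": (1.76, 0.56, 1.96, 1.25),
    "Renal and urinary disorders": (1.51, 2.23, 1.41, 1.66),
    "Psychiatric disorders": (1.44, 0.84, 1.46, 1.74),
    "Endocrine disorders": (1.07, 5.29, 0.21, 4.15),
    "Surgical and medical procedures": (0.70, 2.17, 0.27, 2.70),
    "Ear and labyrinth disorders": (0.26, 0.11, 0.31, 0.00),
    "Reproductive system and breast disorders": (0.26, 0.33, 0.26, 0.21),
    "Social circumstances": (0.25, 1.39, 0.13, 0.29),
    "Congenital, familial and genetic disorders": (0.24, 0.39, 0.24, 0.12),
    "Product issues": (0.10, 0.11, 0.09, 0.17),
}

SOC_COLUMNS = ("Total", "combination", "drug_b_only", "drug_a_only")

#: Published top disproportionality signals (combination vs paclitaxel):
#: (PT, ROR, CI low, CI high, IC, IC025).
PUBLISHED_TOP_SIGNALS: tuple[tuple[str, float, float, float, float, float], ...] = (
    ("adrenal insufficiency", 189.94, 25.41, 1419.7, 3.37, 1.59),
    ("hypophysitis", 99.46, 12.72, 777.4, 3.31, 1.44),
    ("myocarditis", 69.5, 8.55, 565.23, 3.25, 1.33),
)


def published_soc_counts() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        PUBLISHED_SOC_COUNTS, orient="index", columns=SOC_COLUMNS
    )


def published_soc_percentages() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        PUBLISHED_SOC_PCT, orient="index", columns=SOC_COLUMNS
    )


def soc_percentage_deviation() -> pd.DataFrame:
    """Computed-minus-printed percentage for every published cell."""
    return frequency_percentages(published_soc_counts()) - published_soc_percentages()


# ---------------------------------------------------------------------------
# Monte-Carlo operating characteristics


def ror_oracle_max_rel_err(n_tables: int, rng: np.random.Generator) -> float:
    """Worst relative disagreement between compute_ror and the direct
    full-precision formula over random tables with cells in [1, 1e4]."""
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = (int(x) for x in rng.integers(1, 10_001, size=4))
        ror, lo, hi = compute_ror(ContingencyTable(a, b, c, d))
        oror = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        olo, ohi = oror * math.exp(-1.96 * se), oror * math.exp(1.96 * se)
        for got, want in ((ror, oror), (lo, olo), (hi, ohi)):
            worst = max(worst, abs(got - want) / want)
    return worst


def ror_recovery(
    target_or: float,
    n_per_group: int,
    n_reps: int,
    rng: np.random.Generator,
    p_background: float = 0.05,
) -> dict[str, float]:
    """CI coverage and relative bias of the ROR on planted-odds cohorts."""
    covered = 0
    rel_bias = []
    for _ in range(n_reps):
        a, c = sample_event_counts(n_per_group, n_per_group, p_background, target_or, rng)
        table = ContingencyTable(a, n_per_group - a, c, n_per_group - c)
        ror, lo, hi = compute_ror(table, correction=min(a, c) == 0)
        if lo <= target_or <= hi:
            covered += 1
        rel_bias.append((ror - target_or) / target_or)
    return {
        "coverage": covered / n_reps,
        "mean_rel_bias": float(np.mean(rel_bias)),
        "n_reps": n_reps,
    }


def logrank_type_one_error(
    n_reps: int, n_per_group: int, rng: np.random.Generator, alpha: float = 0.05
) -> float:
    """Rejection rate of the log-rank test under an exponential null."""
    rejections = 0
    for _ in range(n_reps):
        g1 = [
            OnsetRecord(str(i), Group.COMBINATION, t)
            for i, t in enumerate(rng.exponential(30.0, n_per_group))
        ]
        g2 = [
            OnsetRecord(str(i + n_per_group), Group.DRUG_B_ONLY, t)
            for i, t in enumerate(rng.exponential(30.0, n_per_group))
        ]
        _, p = logrank_test(g1, g2)
        if p is not None and p < alpha:
            rejections += 1
    return rejections / n_reps


def cox_loghr_bias(
    n_reps: int,
    n_per_group: int,
    true_hr: float,
    rng: np.random.Generator,
    base_scale: float = 50.0,
) -> float:
    """Mean log-HR error of the Cox fit on exponential two-group data."""
    errors = []
    for _ in range(n_reps):
        records = [
            OnsetRecord(str(i), Group.COMBINATION, t)
            for i, t in enumerate(rng.exponential(base_scale, n_per_group))
        ] + [
            OnsetRecord(str(i + n_per_group), Group.DRUG_B_ONLY, t)
            for i, t in enumerate(rng.exponential(base_scale / true_hr, n_per_group))
        ]
        res = cox_hr(records, (Group.DRUG_B_ONLY, Group.COMBINATION))
        errors.append(math.log(res.hr) - math.log(true_hr))
    return float(np.mean(errors))


def km_median_rel_err(
    n: int, rng: np.random.Generator, dist: OnsetDistribution | None = None
) -> float:
    """Relative error of the KM median against the analytic median."""
    dist = dist or OnsetDistribution("exponential", (35.0 / math.log(2),))
    sample = dist.sample(n, rng)
    records = [OnsetRecord(str(i), Group.COMBINATION, t) for i, t in enumerate(sample)]
    km_median = km_estimate(records).median
    truth = dist.analytic_median()
    return abs(km_median - truth) / truth


def ic_on_uniform_table(n: int = 25) -> float:
    """IC of a perfectly independent all-equal-cell table (exactly zero)."""
    ic, _ = compute_ic(ContingencyTable(n, n, n, n))
    return ic
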