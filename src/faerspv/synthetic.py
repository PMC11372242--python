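"""Synthetic FAERS-dialect bundle generator with known ground truth.

Emits multi-quarter DEMO/DRUG/REAC/OUTC/THER ``$``-delimited files that the
ingest module consumes, together with a ``groundtruth.json`` recording what
was planted: group sizes, per-PT true reporting odds ratios, analytic
median onset per group, and the pre-duplication report roster.

The default configuration mirrors the published pembrolizumab/paclitaxel
breast-cancer study conditions: 550 combination, 362 pembrolizumab-only and
204 paclitaxel-only reports spread over quarters 2016q1-2023q2, demographic
and outcome-category probabilities from the study's baseline table,
exponential onset-time distributions with medians 35/43/42 days, and
immune-mediated adverse events (adrenal insufficiency, hypophysitis,
myocarditis, immune-mediated enterocolitis) injected at elevated reporting
odds ratios in both pembrolizumab-containing groups relative to the
paclitaxel background.

Event presence is sampled per report and PT as an independent Bernoulli
draw; for an injected signal the index-group probability is the background
probability tilted on the odds scale so that the true odds ratio equals the
target.  One root seed spawns independent sub-streams (demographics,
events, onsets, dates, duplicates) so adding a stream never perturbs
another.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cohorts import Group

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PTSpec:
    """One catalog entry: preferred term, its SOC, background probability."""

    pt: str
    soc: str
    p_background: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_background < 1.0:
            raise ValueError(f"background probability for {self.pt!r} must be in (0,1)")


@dataclass(frozen=True)
class InjectedSignal:
    """Elevated reporting odds for one PT in the listed groups."""

    pt: str
    target_or: float
    groups: tuple[str, ...] = (Group.COMBINATION.value, Group.DRUG_A_ONLY.value)

    def __post_init__(self) -> None:
        if self.target_or <= 0:
            raise ValueError("target odds ratio must be positive")


@dataclass(frozen=True)
class OnsetDistribution:
    """Parametric onset-time family for one group (days)."""

    family: str  # exponential | weibull | lognormal
    params: tuple[float, ...]

    def analytic_median(self) -> float:
        if self.family == "exponential":
            (scale,) = self.params
            return scale * math.log(2.0)
        if self.family == "weibull":
            shape, scale = self.params
            return scale * math.log(2.0) ** (1.0 / shape)
        if self.family == "lognormal":
            mu, _sigma = self.params
            return math.exp(mu)
        raise ValueError(f"unknown onset family: {self.family!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "exponential":
            (scale,) = self.params
            return rng.exponential(scale, size=n)
        if self.family == "weibull":
            shape, scale = self.params
            return scale * rng.weibull(shape, size=n)
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size=n)
        raise ValueError(f"unknown onset family: {self.family!r}")


_LN2 = math.log(2.0)

DEFAULT_PT_CATALOG: tuple[PTSpec, ...] = (
    PTSpec("fatigue", "General disorders and administration site conditions", 0.20),
    PTSpec("pyrexia", "General disorders and administration site conditions", 0.08),
    PTSpec("dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.10),
    PTSpec("nausea", "Gastrointestinal disorders", 0.12),
    PTSpec("diarrhoea", "Gastrointestinal disorders", 0.08),
    PTSpec("neuropathy peripheral", "Nervous system disorders", 0.10),
    PTSpec("alopecia", "Skin and subcutaneous tissue disorders", 0.08),
    PTSpec("rash", "Skin and subcutaneous tissue disorders", 0.06),
    PTSpec("anaemia", "Blood and lymphatic system disorders", 0.07),
    PTSpec("neutropenia", "Blood and lymphatic system disorders", 0.06),
    PTSpec("white blood cell count decreased", "Investigations", 0.06),
    PTSpec("adrenal insufficiency", "Endocrine disorders", 0.002),
    PTSpec("hypophysitis", "Endocrine disorders", 0.001),
    PTSpec("myocarditis", "Cardiac disorders", 0.001),
    PTSpec("immune-mediated enterocolitis", "Gastrointestinal disorders", 0.002),
)

#: Published top-signal odds ratios, planted in both pembrolizumab-containing
#: groups; the enterocolitis value is a plausible choice (no printed estimate).
DEFAULT_INJECTED: tuple[InjectedSignal, ...] = (
    InjectedSignal("adrenal insufficiency", 189.94),
    InjectedSignal("hypophysitis", 99.46),
    InjectedSignal("myocarditis", 69.5),
    InjectedSignal("immune-mediated enterocolitis", 20.0),
)

DEFAULT_ONSETS: dict[str, OnsetDistribution] = {
    Group.COMBINATION.value: OnsetDistribution("exponential", (35.0 / _LN2,)),
    Group.DRUG_A_ONLY.value: OnsetDistribution("exponential", (43.0 / _LN2,)),
    Group.DRUG_B_ONLY.value: OnsetDistribution("exponential", (42.0 / _LN2,)),
}

DEFAULT_QUARTERS: tuple[str, ...] = tuple(
    f"{year}q{q}"
    for year in range(2016, 2024)
    for q in range(1, 5)
    if not (year == 2023 and q > 2)
)

# Baseline-table band probabilities per group (normalized at sampling time).
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, dict[str, float]]] = {
    "sex": {
        Group.COMBINATION.value: {"F": 549, "M": 1},
        Group.DRUG_A_ONLY.value: {"F": 360, "M": 2},
        Group.DRUG_B_ONLY.value: {"F": 203, "M": 1},
    },
    "weight": {
        Group.COMBINATION.value: {"<50": 20, "50-100": 146, ">100": 14, "missing": 370},
        Group.DRUG_A_ONLY.value: {"<50": 9, "50-100": 63, ">100": 8, "missing": 285},
        Group.DRUG_B_ONLY.value: {"<50": 13, "50-100": 99, ">100": 7, "missing": 85},
    },
    "age": {
        Group.COMBINATION.value: {"18-64": 305, "65-85": 93, "missing": 152},
        Group.DRUG_A_ONLY.value: {"18-64": 159, "65-85": 76, "missing": 127},
        Group.DRUG_B_ONLY.value: {"18-64": 156, "65-85": 38, "missing": 10},
    },
    "outcome": {
        Group.COMBINATION.value: {"DE": 22, "DS": 9, "HO": 166, "LT": 20, "OT": 309, "missing": 24},
        Group.DRUG_A_ONLY.value: {"DE": 15, "DS": 6, "HO": 87, "LT": 8, "OT": 230, "missing": 22},
        Group.DRUG_B_ONLY.value: {"DE": 12, "DS": 5, "HO": 83, "LT": 11, "OT": 90, "missing": 3},
    },
}

DEFAULT_INDICATIONS: tuple[str, ...] = (
    "breast cancer",
    "breast cancer metastatic",
    "triple negative breast cancer",
    "her2 negative breast cancer",
    "hormone receptor positive breast cancer",
)


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {
            Group.COMBINATION.value: 550,
            Group.DRUG_A_ONLY.value: 362,
            Group.DRUG_B_ONLY.value: 204,
        }
    )
    quarters: Sequence[str] = DEFAULT_QUARTERS
    pt_catalog: Sequence[PTSpec] = DEFAULT_PT_CATALOG
    injected_signals: Sequence[InjectedSignal] = DEFAULT_INJECTED
    onset_distributions: dict[str, OnsetDistribution] = field(
        default_factory=lambda: dict(DEFAULT_ONSETS)
    )
    baseline_group: str = Group.DRUG_B_ONLY.value
    duplicate_rate: float = 0.05
    missing_date_rate: float = 0.10
    demographics: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: DEFAULT_DEMOGRAPHICS
    )
    indications: Sequence[str] = DEFAULT_INDICATIONS
    messy: bool = False  # adds orphan rows, malformed lines, a both-PS report

    def __post_init__(self) -> None:
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must be in [0,1)")
        if not 0.0 <= self.missing_date_rate < 1.0:
            raise ValueError("missing_date_rate must be in [0,1)")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be non-negative")
        catalog_pts = {p.pt for p in self.pt_catalog}
        for sig in self.injected_signals:
            if sig.pt not in catalog_pts:
                raise ValueError(f"injected signal PT {sig.pt!r} not in catalog")


@dataclass
class SynthReport:
    caseid: int
    primaryid: int
    version: int
    group: str
    quarter: str
    sex: str
    age_years: Optional[float]
    weight_kg: Optional[float]
    outcome: Optional[str]
    indication: str
    pts: list[str]
    onset_days: float
    start_date: _dt.date
    start_raw: str  # serialized, possibly truncated to month/year precision
    event_raw: str
    rept_raw: str
    has_duplicate: bool = False


@dataclass
class GroundTruth:
    true_or: dict[str, float]  # PT -> odds ratio vs baseline group
    true_median_onset: dict[str, float]  # group -> analytic median (days)
    n_per_group: dict[str, int]
    roster: list[dict]  # pre-duplication: primaryid, caseid, group, pts

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# sampling primitives (also used directly by the validation simulations)


def tilt_probability(p_background: float, target_or: float) -> float:
    """Probability whose odds are ``target_or`` times the background odds."""
    if not 0.0 < p_background < 1.0:
        raise ValueError("p_background must be in (0,1)")
    if target_or <= 0:
        raise ValueError("target_or must be positive")
    odds = p_background / (1.0 - p_background) * target_or
    return odds / (1.0 + odds)


def event_probability(
    pt: PTSpec, group: str, injected: Sequence[InjectedSignal]
) -> float:
    for sig in injected:
        if sig.pt == pt.pt and group in sig.groups:
            return tilt_probability(pt.p_background, sig.target_or)
    return pt.p_background


def sample_event_counts(
    n_index: int,
    n_comparator: int,
    p_background: float,
    target_or: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Bernoulli event counts (index, comparator) for one injected PT.

    This is the generator's per-PT sampling core, exposed for parameter-
    recovery simulations without file round-trips.
    """
    p_index = tilt_probability(p_background, target_or)
    a = int(rng.binomial(n_index, p_index))
    c = int(rng.binomial(n_comparator, p_background))
    return a, c


def _sample_band(bands: dict[str, float], rng: np.random.Generator) -> str:
    labels = list(bands)
    weights = np.array([bands[k] for k in labels], dtype=float)
    weights /= weights.sum()
    return labels[int(rng.choice(len(labels), p=weights))]


_QUARTER_MONTH = {1: 1, 2: 4, 3: 7, 4: 10}


def quarter_start(label: str) -> _dt.date:
    year, q = int(label[:4]), int(label[-1])
    return _dt.date(year, _QUARTER_MONTH[q], 1)


def _sample_date_in_quarter(label: str, rng: np.random.Generator) -> _dt.date:
    start = quarter_start(label)
    return start + _dt.timedelta(days=int(rng.integers(0, 89)))


def _truncate(raw: str, rng: np.random.Generator) -> str:
    # month or year precision, 50/50
    return raw[:6] if rng.random() < 0.5 else raw[:4]


def corrupt_dates(
    roster: list[SynthReport], rate: float, rng: np.random.Generator
) -> list[SynthReport]:
    """Truncate the given fraction of start/event dates to partial precision."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0,1]")
    for rep in roster:
        if rate and rng.random() < rate:
            rep.start_raw = _truncate(rep.start_raw, rng)
        if rate and rng.random() < rate:
            rep.event_raw = _truncate(rep.event_raw, rng)
    return roster


# ---------------------------------------------------------------------------
# roster generation


def generate_reports(config: SyntheticConfig) -> tuple[list[SynthReport], GroundTruth]:
    """Sample the full report roster (pre-file-serialization)."""
    root = np.random.SeedSequence(config.seed)
    rng_demo, rng_events, rng_onsets, rng_dates, rng_dup = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    quarters = list(config.quarters)
    roster: list[SynthReport] = []
    caseid = 10_000_001
    demo = config.demographics
    for group in sorted(config.n_per_group):
        n = config.n_per_group[group]
        dist = config.onset_distributions[group]
        onsets = dist.sample(n, rng_onsets)
        for i in range(n):
            quarter = quarters[int(rng_dates.integers(0, len(quarters)))]
            sex = _sample_band(demo["sex"][group], rng_demo)
            wband = _sample_band(demo["weight"][group], rng_demo)
            aband = _sample_band(demo["age"][group], rng_demo)
            oband = _sample_band(demo["outcome"][group], rng_demo)
            weight = {
                "<50": lambda: rng_demo.uniform(35, 50),
                "50-100": lambda: rng_demo.uniform(50, 100),
                ">100": lambda: rng_demo.uniform(100, 130),
                "missing": lambda: None,
            }[wband]()
            age = {
                "18-64": lambda: rng_demo.uniform(18, 64),
                "65-85": lambda: rng_demo.uniform(65, 85),
                "missing": lambda: None,
            }[aband]()
            pts = [
                spec.pt
                for spec in config.pt_catalog
                if rng_events.random() < event_probability(spec, group, config.injected_signals)
            ]
            onset = float(onsets[i])
            start = _sample_date_in_quarter(quarter, rng_dates)
            event = start + _dt.timedelta(days=int(round(onset)))
            rept = event + _dt.timedelta(days=14)
            indication = config.indications[
                int(rng_demo.integers(0, len(config.indications)))
            ]
            roster.append(
                SynthReport(
                    caseid=caseid,
                    primaryid=caseid * 10 + 2,
                    version=2,
                    group=group,
                    quarter=quarter,
                    sex=sex,
                    age_years=age,
                    weight_kg=weight,
                    outcome=None if oband == "missing" else oband,
                    indication=indication,
                    pts=pts,
                    onset_days=onset,
                    start_date=start,
                    start_raw=start.strftime("%Y%m%d"),
                    event_raw=event.strftime("%Y%m%d"),
                    rept_raw=rept.strftime("%Y%m%d"),
                    has_duplicate=bool(rng_dup.random() < config.duplicate_rate),
                )
            )
            caseid += 1
    corrupt_dates(roster, config.missing_date_rate, rng_dates)
    truth = GroundTruth(
        true_or={sig.pt: sig.target_or for sig in config.injected_signals},
        true_median_onset={
            g: config.onset_distributions[g].analytic_median()
            for g in config.n_per_group
        },
        n_per_group=dict(config.n_per_group),
        roster=[
            {
                "primaryid": str(r.primaryid),
                "caseid": str(r.caseid),
                "group": r.group,
                "pts": sorted(r.pts),
            }
            for r in roster
        ],
    )
    return roster, truth


# ---------------------------------------------------------------------------
# file serialization

_HEADERS = {
    "DEMO": "primaryid$caseid$caseversion$event_dt$rept_dt$sex$age$age_cod$wt$wt_cod",
    "DRUG": "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai$indi_pt",
    "REAC": "primaryid$caseid$pt",
    "OUTC": "primaryid$caseid$outc_cod",
    "THER": "primaryid$caseid$dsg_drug_seq$start_dt",
}

_GROUP_DRUGS = {
    # (drugname, prod_ai, role) rows realizing each group's role pattern
    Group.COMBINATION.value: [
        ("KEYTRUDA", "PEMBROLIZUMAB", "PS"),
        ("PACLITAXEL", "PACLITAXEL", "SS"),
    ],
    Group.DRUG_A_ONLY.value: [("KEYTRUDA", "PEMBROLIZUMAB", "PS")],
    Group.DRUG_B_ONLY.value: [("PACLITAXEL", "PACLITAXEL", "PS")],
}


def _emit_report_rows(
    rep: SynthReport, primaryid: int, version: int, lines: dict[str, list[str]]
) -> None:
    pid, cid = str(primaryid), str(rep.caseid)
    age = f"{rep.age_years:.0f}" if rep.age_years is not None else ""
    wt = f"{rep.weight_kg:.1f}" if rep.weight_kg is not None else ""
    lines["DEMO"].append(
        f"{pid}${cid}${version}${rep.event_raw}${rep.rept_raw}${rep.sex}${age}$"
        f"{'YR' if age else ''}${wt}${'KG' if wt else ''}"
    )
    for seq, (name, ai, role) in enumerate(_GROUP_DRUGS[rep.group], start=1):
        indi = rep.indication if seq == 1 else ""
        lines["DRUG"].append(f"{pid}${cid}${seq}${role}${name}${ai}${indi}")
        lines["THER"].append(f"{pid}${cid}${seq}${rep.start_raw}")
    for pt in rep.pts:
        lines["REAC"].append(f"{pid}${cid}${pt}")
    if rep.outcome:
        lines["OUTC"].append(f"{pid}${cid}${rep.outcome}")


def write_bundle(
    roster: Sequence[SynthReport],
    truth: GroundTruth,
    out_dir: str | Path,
    config: SyntheticConfig,
) -> dict[str, Path]:
    """Serialize a roster to quarterly files plus groundtruth and PT->SOC map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_quarter: dict[str, dict[str, list[str]]] = {
        q: {k: [] for k in _HEADERS} for q in config.quarters
    }
    for rep in roster:
        lines = per_quarter[rep.quarter]
        if rep.has_duplicate:
            # an earlier version of the same case, superseded after dedup
            _emit_report_rows(rep, rep.caseid * 10 + 1, 1, lines)
        _emit_report_rows(rep, rep.primaryid, rep.version, lines)
    if config.messy and roster:
        lines = per_quarter[roster[0].quarter]
        lines["REAC"].append("999999991$99999999$orphan reaction")  # no DEMO row
        lines["DRUG"].append("malformed line without enough fields")
        both_ps = roster[0]
        pid = "888888882"
        lines["DEMO"].append(f"{pid}$88888888$1${both_ps.event_raw}${both_ps.rept_raw}$F$55$YR$$")
        lines["DRUG"].append(f"{pid}$88888888$1$PS$KEYTRUDA$PEMBROLIZUMAB$breast cancer")
        lines["DRUG"].append(f"{pid}$88888888$2$PS$PACLITAXEL$PACLITAXEL$")
        lines["REAC"].append(f"{pid}$88888888$fatigue")
        lines["THER"].append(f"{pid}$88888888$1${both_ps.start_raw}")
    paths: dict[str, Path] = {}
    for quarter, tables in per_quarter.items():
        for kind, body in tables.items():
            path = out_dir / f"{kind}{quarter}.txt"
            path.write_text("\n".join([_HEADERS[kind]] + body) + "\n", encoding="utf-8")
            paths[f"{kind}{quarter}"] = path
    (out_dir / "groundtruth.json").write_text(truth.to_json(), encoding="utf-8")
    pt_soc_lines = ["pt$soc"] + [f"{s.pt}${s.soc}" for s in config.pt_catalog]
    (out_dir / "pt_soc.txt").write_text("\n".join(pt_soc_lines) + "\n", encoding="utf-8")
    paths["groundtruth"] = out_dir / "groundtruth.json"
    paths["pt_soc"] = out_dir / "pt_soc.txt"
    return paths


def generate_bundle(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate and serialize a full bundle; deterministic given the seed."""
    roster, truth = generate_reports(config)
    paths = write_bundle(roster, truth, out_dir, config)
    return paths, truth


def load_pt_soc(path: str | Path) -> dict[str, str]:
    """Read a two-column ``pt$soc`` mapping file."""
    mapping: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        pt, _, soc = line.partition("$")
        mapping[pt.strip().lower()] = soc.strip()
    return mapping
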