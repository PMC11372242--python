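"""Reading and joining FAERS-style quarterly ASCII tables.

FAERS quarters ship as ``$``-delimited text tables (DEMO, DRUG, REAC, OUTC,
THER) keyed by ``primaryid`` (report version) and ``caseid`` (persistent
case).  A case can appear as several versions, possibly across quarters;
analysis keeps one report per case.  Only the post-2012Q4 dialect
(``primaryid``/``caseid`` keys) is supported.

Parsing is tolerant: malformed lines are skipped and tallied rather than
aborting the run, so silent data loss stays visible in the warning counts.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "TableKind",
    "PartialDate",
    "DrugMention",
    "CaseReport",
    "RawTable",
    "JoinStats",
    "FaersFormatError",
    "parse_partial_date",
    "parse_quarter_file",
    "load_bundle",
    "join_case",
    "deduplicate",
]


class FaersFormatError(ValueError):
    """Raised when a table is structurally unusable (e.g. missing key columns)."""


class TableKind(str, Enum):
    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    OUTC = "OUTC"
    THER = "THER"


class DatePrecision(str, Enum):
    YEAR = "year"
    MONTH = "month"
    DAY = "day"


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date string resolved to year, year-month, or full-day precision.

    FAERS encodes dates as 4/6/8-digit strings; many reports carry only a
    year or year-month.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> DatePrecision:
        if self.day is not None:
            return DatePrecision.DAY
        if self.month is not None:
            return DatePrecision.MONTH
        return DatePrecision.YEAR

    def to_date(self, impute: bool = False) -> Optional[_dt.date]:
        """Resolve to a calendar date.

        Day precision resolves directly.  With ``impute=True``, month
        precision substitutes day 15 and year precision July 15; otherwise
        partial dates resolve to ``None``.
        """
        if self.precision is DatePrecision.DAY:
            return _dt.date(self.year, self.month, self.day)
        if not impute:
            return None
        if self.precision is DatePrecision.MONTH:
            return _dt.date(self.year, self.month, 15)
        return _dt.date(self.year, 7, 15)

    def serialize(self) -> str:
        if self.precision is DatePrecision.DAY:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.precision is DatePrecision.MONTH:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_partial_date(raw: str) -> Optional[PartialDate]:
    """Parse a 4/6/8-digit FAERS date string; invalid input returns None."""
    raw = (raw or "").strip()
    if not re.fullmatch(r"\d{4}|\d{6}|\d{8}", raw):
        return None
    year = int(raw[:4])
    if year < 1900 or year > 2100:
        return None
    if len(raw) == 4:
        return PartialDate(year)
    month = int(raw[4:6])
    if not 1 <= month <= 12:
        return None
    if len(raw) == 6:
        return PartialDate(year, month)
    day = int(raw[6:8])
    try:
        _dt.date(year, month, day)
    except ValueError:
        return None
    return PartialDate(year, month, day)


@dataclass
class DrugMention:
    """One DRUG-table row: a drug name with its reporter-assigned role.

    Roles: PS (primary suspect), SS (secondary suspect), C (concomitant),
    I (interacting).  ``indication_pt`` is the treatment indication preferred
    term reported for this drug; ``therapy_start`` is linked from the THER
    table via the drug sequence number.
    """

    name: str
    role: str
    drug_seq: Optional[str] = None
    active_ingredient: Optional[str] = None
    indication_pt: Optional[str] = None
    therapy_start: Optional[PartialDate] = None

    ROLES = ("PS", "SS", "C", "I")

    def __post_init__(self) -> None:
        self.role = self.role.upper()
        if self.role not in self.ROLES:
            raise ValueError(f"unknown drug role code: {self.role!r}")


@dataclass
class CaseReport:
    """One safety report: demographics joined with drugs, reactions, outcomes."""

    primaryid: str
    caseid: str
    sex: str = "unknown"  # F / M / unknown
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    event_date: Optional[PartialDate] = None
    report_year: Optional[int] = None
    drugs: list[DrugMention] = field(default_factory=list)
    reaction_pts: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)


@dataclass
class RawTable:
    """Rows of one quarterly table, parsed but not yet joined."""

    table_kind: TableKind
    quarter_label: str
    rows: list[dict[str, str]]
    skipped_lines: int = 0


@dataclass
class JoinStats:
    """Warning tallies from joining the five tables into case reports."""

    orphan_rows: dict[str, int] = field(default_factory=dict)
    invalid_dates: int = 0

    @property
    def total_orphans(self) -> int:
        return sum(self.orphan_rows.values())


def parse_quarter_file(
    stream: IO[str] | Iterable[str],
    table_kind: TableKind | str,
    quarter_label: str,
    source_name: str = "<stream>",
) -> RawTable:
    """Parse one ``$``-delimited FAERS table.

    The first line is the header; names are lower-cased and must include
    ``primaryid`` and ``caseid``.  Lines whose field count disagrees with the
    header (after tolerating one trailing ``$``) are skipped and tallied.
    """
    kind = TableKind(table_kind)
    lines = iter(stream)
    try:
        header_line = next(lines)
    except StopIteration:
        raise FaersFormatError(
            f"{source_name} ({kind.value}): empty file, no header line"
        ) from None
    header = [h.strip().lower() for h in header_line.rstrip("\r\n").split("$")]
    if header and header[-1] == "":
        header = header[:-1]
    for key in ("primaryid", "caseid"):
        if key not in header:
            raise FaersFormatError(
                f"{source_name} ({kind.value}): header lacks required column {key!r}"
            )
    ncol = len(header)
    rows: list[dict[str, str]] = []
    skipped = 0
    for line in lines:
        line = line.rstrip("\r\n")
        if not line:
            continue
        fields_ = line.split("$")
        if len(fields_) == ncol + 1 and fields_[-1] == "":
            fields_ = fields_[:-1]
        if len(fields_) != ncol:
            skipped += 1
            continue
        rows.append(dict(zip(header, fields_)))
    if skipped:
        logger.warning(
            "%s (%s %s): skipped %d malformed line(s)",
            source_name, kind.value, quarter_label, skipped,
        )
    return RawTable(kind, quarter_label, rows, skipped)


def serialize_table(table: RawTable) -> str:
    """Inverse of :func:`parse_quarter_file` for the supported dialect."""
    if not table.rows:
        return "primaryid$caseid\n"
    header = list(table.rows[0].keys())
    out = ["$".join(header)]
    for row in table.rows:
        out.append("$".join(row.get(h, "") for h in header))
    return "\n".join(out) + "\n"


_FILE_RE = re.compile(r"^(DEMO|DRUG|REAC|OUTC|THER)(\d{4}q[1-4])\.txt$", re.IGNORECASE)


def load_bundle(
    directory: str | Path,
    quarters: Optional[Iterable[str]] = None,
) -> list[RawTable]:
    """Load every recognized quarter table file from a directory.

    Files are matched by the ``<KIND><YYYYqN>.txt`` naming convention.
    ``quarters`` optionally restricts to an analysis window.
    """
    directory = Path(directory)
    wanted = {q.lower() for q in quarters} if quarters is not None else None
    tables: list[RawTable] = []
    for path in sorted(directory.iterdir()):
        m = _FILE_RE.match(path.name)
        if not m:
            continue
        kind, quarter = m.group(1).upper(), m.group(2).lower()
        if wanted is not None and quarter not in wanted:
            continue
        with open(path, encoding="utf-8") as fh:
            tables.append(parse_quarter_file(fh, kind, quarter, source_name=path.name))
    if not tables:
        raise FaersFormatError(f"no FAERS quarter tables found under {directory}")
    return tables


def _parse_age_years(row: dict[str, str]) -> Optional[float]:
    raw = row.get("age", "").strip()
    if not raw:
        return None
    try:
        value = float(raw)
    except ValueError:
        return None
    code = row.get("age_cod", "YR").strip().upper() or "YR"
    factor = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12.0, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766.0}
    if code not in factor:
        return None
    years = value * factor[code]
    return years if years >= 0 else None


def _parse_weight_kg(row: dict[str, str]) -> Optional[float]:
    raw = row.get("wt", "").strip()
    if not raw:
        return None
    try:
        value = float(raw)
    except ValueError:
        return None
    code = row.get("wt_cod", "KG").strip().upper() or "KG"
    factor = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}
    if code not in factor:
        return None
    kg = value * factor[code]
    return kg if kg >= 0 else None


def join_case(
    raw_tables: list[RawTable],
    stats: Optional[JoinStats] = None,
) -> list[CaseReport]:
    """Join DEMO/DRUG/REAC/OUTC/THER rows into one CaseReport per DEMO row.

    Rows are attached by ``primaryid``.  THER start dates attach to drug
    mentions via ``dsg_drug_seq`` == ``drug_seq``; when either side lacks a
    sequence number the earliest therapy start of the case is used for
    mentions without one.  DRUG/REAC/OUTC/THER rows whose primaryid matches
    no DEMO row are counted as orphans and dropped.
    """
    if stats is None:
        stats = JoinStats()
    by_kind: dict[TableKind, list[dict[str, str]]] = {k: [] for k in TableKind}
    for table in raw_tables:
        by_kind[table.table_kind].extend(table.rows)
    if not by_kind[TableKind.DEMO]:
        raise FaersFormatError("no DEMO table rows: cannot build case reports")

    reports: dict[str, CaseReport] = {}
    for row in by_kind[TableKind.DEMO]:
        pid = row["primaryid"].strip()
        sex = row.get("sex", "").strip().upper()
        event_date = parse_partial_date(row.get("event_dt", ""))
        if row.get("event_dt", "").strip() and event_date is None:
            stats.invalid_dates += 1
        rept = parse_partial_date(row.get("rept_dt", "")) or parse_partial_date(
            row.get("fda_dt", "")
        )
        reports[pid] = CaseReport(
            primaryid=pid,
            caseid=row["caseid"].strip(),
            sex=sex if sex in ("F", "M") else "unknown",
            age_years=_parse_age_years(row),
            weight_kg=_parse_weight_kg(row),
            event_date=event_date,
            report_year=rept.year if rept else None,
        )

    def _orphan(kind: TableKind) -> None:
        stats.orphan_rows[kind.value] = stats.orphan_rows.get(kind.value, 0) + 1

    for row in by_kind[TableKind.DRUG]:
        pid = row["primaryid"].strip()
        report = reports.get(pid)
        if report is None:
            _orphan(TableKind.DRUG)
            continue
        role = row.get("role_cod", "").strip().upper()
        if role not in DrugMention.ROLES:
            stats.orphan_rows["DRUG-badrole"] = stats.orphan_rows.get("DRUG-badrole", 0) + 1
            continue
        report.drugs.append(
            DrugMention(
                name=row.get("drugname", "").strip(),
                role=role,
                drug_seq=row.get("drug_seq", "").strip() or None,
                active_ingredient=row.get("prod_ai", "").strip() or None,
                indication_pt=row.get("indi_pt", "").strip() or None,
            )
        )

    for row in by_kind[TableKind.REAC]:
        pid = row["primaryid"].strip()
        report = reports.get(pid)
        if report is None:
            _orphan(TableKind.REAC)
            continue
        pt = row.get("pt", "").strip()
        if pt:
            report.reaction_pts.append(pt)

    for row in by_kind[TableKind.OUTC]:
        pid = row["primaryid"].strip()
        report = reports.get(pid)
        if report is None:
            _orphan(TableKind.OUTC)
            continue
        code = row.get("outc_cod", "").strip().upper()
        if code:
            report.outcomes.append(code)

    # THER: per-case start dates, linked by drug sequence when possible
    ther_by_pid: dict[str, list[dict[str, str]]] = {}
    for row in by_kind[TableKind.THER]:
        pid = row["primaryid"].strip()
        if pid not in reports:
            _orphan(TableKind.THER)
            continue
        ther_by_pid.setdefault(pid, []).append(row)
    for pid, ther_rows in ther_by_pid.items():
        report = reports[pid]
        starts: list[tuple[Optional[str], PartialDate]] = []
        for row in ther_rows:
            start = parse_partial_date(row.get("start_dt", ""))
            if start is None:
                if row.get("start_dt", "").strip():
                    stats.invalid_dates += 1
                continue
            starts.append((row.get("dsg_drug_seq", "").strip() or None, start))
        if not starts:
            continue
        earliest = min(
            (s for _, s in starts),
            key=lambda d: (d.year, d.month or 1, d.day or 1),
        )
        by_seq = {seq: date for seq, date in starts if seq is not None}
        for mention in report.drugs:
            mention.therapy_start = by_seq.get(mention.drug_seq, earliest)

    if stats.total_orphans:
        logger.warning("join_case: %d orphan row(s): %s", stats.total_orphans, stats.orphan_rows)
    return [reports[pid] for pid in sorted(reports)]


def _primaryid_sort_key(pid: str):
    try:
        return (0, int(pid))
    except ValueError:
        return (1, pid)


def deduplicate(reports: list[CaseReport]) -> list[CaseReport]:
    """Keep one report per caseid: the numerically largest primaryid.

    FAERS primaryids encode case number plus version, so the largest
    primaryid is the latest version of the case.  Output is sorted by
    caseid, making the operation deterministic and idempotent.
    """
    best: dict[str, CaseReport] = {}
    for report in reports:
        kept = best.get(report.caseid)
        if kept is None or _primaryid_sort_key(report.primaryid) > _primaryid_sort_key(
            kept.primaryid
        ):
            best[report.caseid] = report
    return [best[cid] for cid in sorted(best)]
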