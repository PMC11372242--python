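"""Parsing, joining and deduplication of the quarterly table dialect."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.faers_io import (
    FaersFormatError,
    JoinStats,
    PartialDate,
    RawTable,
    TableKind,
    deduplicate,
    join_case,
    parse_partial_date,
    parse_quarter_file,
)
from faerspv.faers_io import serialize_table

from conftest import make_report


class TestParseQuarterFile:
    def test_header_only_gives_empty_table(self):
        table = parse_quarter_file(io.StringIO("primaryid$caseid$pt\n"), "REAC", "2016q1")
        assert table.rows == [] and table.skipped_lines == 0

    def test_single_row_matches_direct_split(self):
        text = "primaryid$caseid$drugname$role_cod\n1230001$123$PEMBROLIZUMAB$PS\n"
        table = parse_quarter_file(io.StringIO(text), "DRUG", "2016q1")
        assert table.rows == [
            {"primaryid": "1230001", "caseid": "123", "drugname": "PEMBROLIZUMAB", "role_cod": "PS"}
        ]

    def test_short_line_skipped_and_tallied(self):
        text = "primaryid$caseid$pt\n1$1\n"
        table = parse_quarter_file(io.StringIO(text), "REAC", "2016q1")
        assert table.rows == [] and table.skipped_lines == 1

    def test_trailing_dollar_tolerated(self):
        text = "primaryid$caseid$pt$\n1$1$nausea$\n"
        table = parse_quarter_file(io.StringIO(text), "REAC", "2016q1")
        assert table.rows[0]["pt"] == "nausea"

    def test_missing_key_column_is_format_error(self):
        with pytest.raises(FaersFormatError, match="caseid"):
            parse_quarter_file(io.StringIO("primaryid$pt\n"), "REAC", "2016q1")

    def test_empty_fields_become_empty_strings(self):
        text = "primaryid$caseid$pt\n1$1$\n"
        table = parse_quarter_file(io.StringIO(text), "REAC", "2016q1")
        assert table.rows[0]["pt"] == ""

    @given(
        rows=st.lists(
            st.tuples(
                st.integers(1, 10**9),
                st.integers(1, 10**8),
                st.text(
                    alphabet=st.characters(
                        blacklist_characters="$\n\r", min_codepoint=32, max_codepoint=126
                    ),
                    max_size=12,
                ),
            ),
            max_size=20,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_roundtrip_parse_serialize_parse(self, rows):
        """Parsing a serialized table reproduces the rows exactly."""
        table = RawTable(
            TableKind.REAC,
            "2016q1",
            [{"primaryid": str(p), "caseid": str(c), "pt": t} for p, c, t in rows],
        )
        text = serialize_table(table)
        again = parse_quarter_file(io.StringIO(text), "REAC", "2016q1")
        assert again.rows == table.rows and again.skipped_lines == 0


class TestPartialDate:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("20200315", PartialDate(2020, 3, 15)),
            ("202003", PartialDate(2020, 3)),
            ("2020", PartialDate(2020)),
            ("20200230", None),  # invalid calendar date
            ("", None),
            ("2020031", None),  # 7 digits
            ("20201315", None),  # month 13
        ],
    )
    def test_parse(self, raw, expected):
        assert parse_partial_date(raw) == expected

    def test_precision_levels(self):
        assert parse_partial_date("20200315").precision.value == "day"
        assert parse_partial_date("202003").precision.value == "month"
        assert parse_partial_date("2020").precision.value == "year"

    def test_imputation_rules(self):
        assert parse_partial_date("202003").to_date(impute=True).day == 15
        d = parse_partial_date("2020").to_date(impute=True)
        assert (d.month, d.day) == (7, 15)
        assert parse_partial_date("202003").to_date(impute=False) is None


class TestDeduplicate:
    def test_singleton_unchanged(self):
        reports = [make_report(primaryid="1230001", caseid="123")]
        assert deduplicate(reports) == reports

    def test_largest_primaryid_wins(self):
        r1 = make_report(primaryid="1230001", caseid="123")
        r2 = make_report(primaryid="1230002", caseid="123")
        assert deduplicate([r1, r2]) == [r2]
        assert deduplicate([r2, r1]) == [r2]

    def test_idempotent_and_sorted(self):
        reports = [
            make_report(primaryid="50", caseid="5"),
            make_report(primaryid="31", caseid="3"),
            make_report(primaryid="32", caseid="3"),
        ]
        once = deduplicate(reports)
        assert deduplicate(once) == once
        assert [r.caseid for r in once] == ["3", "5"]

    @given(
        pairs=st.lists(
            st.tuples(st.integers(1, 50), st.integers(1, 5)), max_size=30
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_one_survivor_per_caseid(self, pairs):
        """Output size equals the number of distinct caseids; idempotent."""
        reports = [
            make_report(primaryid=str(c * 100 + v), caseid=str(c)) for c, v in pairs
        ]
        out = deduplicate(reports)
        assert len(out) == len({r.caseid for r in reports})
        assert len(out) <= len(reports)
        assert deduplicate(out) == out


def _raw(kind, rows):
    return RawTable(TableKind(kind), "2016q1", rows)


class TestJoinCase:
    def test_reactions_attach_by_primaryid(self):
        demo = _raw("DEMO", [{"primaryid": "1", "caseid": "1"}])
        reac = _raw(
            "REAC",
            [
                {"primaryid": "1", "caseid": "1", "pt": "nausea"},
                {"primaryid": "1", "caseid": "1", "pt": "rash"},
            ],
        )
        (report,) = join_case([demo, reac])
        assert report.reaction_pts == ["nausea", "rash"]

    def test_orphan_drug_row_tallied(self):
        demo = _raw("DEMO", [{"primaryid": "1", "caseid": "1"}])
        drug = _raw(
            "DRUG",
            [{"primaryid": "2", "caseid": "2", "role_cod": "PS", "drugname": "X"}],
        )
        stats = JoinStats()
        (report,) = join_case([demo, drug], stats=stats)
        assert report.drugs == [] and stats.orphan_rows == {"DRUG": 1}

    def test_each_report_gets_own_reactions(self):
        demo = _raw(
            "DEMO", [{"primaryid": "1", "caseid": "1"}, {"primaryid": "2", "caseid": "2"}]
        )
        reac = _raw(
            "REAC",
            [
                {"primaryid": "1", "caseid": "1", "pt": "nausea"},
                {"primaryid": "2", "caseid": "2", "pt": "rash"},
                {"primaryid": "2", "caseid": "2", "pt": "fatigue"},
            ],
        )
        r1, r2 = join_case([demo, reac])
        assert r1.reaction_pts == ["nausea"]
        assert sorted(r2.reaction_pts) == ["fatigue", "rash"]

    def test_reaction_conservation(self):
        """Attached reactions + orphan tally equals the REAC row count."""
        demo = _raw("DEMO", [{"primaryid": "1", "caseid": "1"}])
        reac_rows = [
            {"primaryid": pid, "caseid": pid, "pt": f"pt{i}"}
            for i, pid in enumerate(["1", "1", "2", "3"])
        ]
        stats = JoinStats()
        reports = join_case([demo, _raw("REAC", reac_rows)], stats=stats)
        attached = sum(len(r.reaction_pts) for r in reports)
        assert attached + stats.orphan_rows.get("REAC", 0) == len(reac_rows)

    def test_ther_links_by_drug_seq_with_fallback(self):
        demo = _raw("DEMO", [{"primaryid": "1", "caseid": "1"}])
        drug = _raw(
            "DRUG",
            [
                {"primaryid": "1", "caseid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "A"},
                {"primaryid": "1", "caseid": "1", "drug_seq": "2", "role_cod": "C", "drugname": "B"},
                {"primaryid": "1", "caseid": "1", "drug_seq": "3", "role_cod": "C", "drugname": "C"},
            ],
        )
        ther = _raw(
            "THER",
            [
                {"primaryid": "1", "caseid": "1", "dsg_drug_seq": "1", "start_dt": "20200201"},
                {"primaryid": "1", "caseid": "1", "dsg_drug_seq": "2", "start_dt": "20200301"},
            ],
        )
        (report,) = join_case([demo, drug, ther])
        starts = {m.name: m.therapy_start for m in report.drugs}
        assert starts["A"] == PartialDate(2020, 2, 1)
        assert starts["B"] == PartialDate(2020, 3, 1)
        # no matching seq: earliest start for the case
        assert starts["C"] == PartialDate(2020, 2, 1)

    def test_demo_required(self):
        with pytest.raises(FaersFormatError, match="DEMO"):
            join_case([_raw("REAC", [{"primaryid": "1", "caseid": "1", "pt": "x"}])])

    def test_demographics_parsed(self):
        demo = _raw(
            "DEMO",
            [
                {
                    "primaryid": "1",
                    "caseid": "1",
                    "sex": "f",
                    "age": "650",
                    "age_cod": "MON",
                    "wt": "154",
                    "wt_cod": "LBS",
                    "event_dt": "20200315",
                    "rept_dt": "20200401",
                }
            ],
        )
        (r,) = join_case([demo])
        assert r.sex == "F"
        assert r.age_years == pytest.approx(650 / 12)
        assert r.weight_kg == pytest.approx(154 * 0.45359237)
        assert r.event_date == PartialDate(2020, 3, 15)
        assert r.report_year == 2020
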