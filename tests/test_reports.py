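"""Loading, filtering and case classification of report-level data."""

import datetime

import pytest

from pvsignal.reports import (
    DECADE_BUCKETS,
    Dialect,
    DrugClassDef,
    DrugEntry,
    PTSet,
    ReportSet,
    apply_exclusions,
    classify_case,
    is_exposed,
    load_report_set,
    write_report_set,
)
from pvsignal.synthetic_data import default_config, simulate

from conftest import make_report


def _write_four_tables(tmp_path, demo, drug, reac, hist):
    paths = {}
    for name, text in (("demo", demo), ("drug", drug), ("reac", reac), ("hist", hist)):
        p = tmp_path / f"{name}.csv"
        p.write_text(text)
        paths[name] = p
    return paths


DEMO = "case_id,sex,age\nA1,male,60-69\nA2,female,70-79\nA3,male,50-59\n"
DRUG = (
    "case_id,drug_name,role,start_date,end_date\n"
    "A1,Exenatide,suspect,2010-01-01,2010-06-01\n"
    "A1,metformin,concomitant,,\n"
    "A2,sitagliptin,suspect,,\n"
)
REAC = (
    "case_id,pt_id,pt_name,onset_date\n"
    "A1,10047700,Vomiting,2010-02-01\n"
    "A2,10020993,Hypoglycaemia,\n"
    "A3,10028813,Nausea,\n"
)
HIST = "case_id,disease\nA1,type 2 diabetes mellitus\nA2,type 2 diabetes mellitus\n"


class TestLoadReportSet:
    def test_one_record_per_case_id(self, tmp_path):
        p = _write_four_tables(tmp_path, DEMO, DRUG, REAC, HIST)
        rs = load_report_set(p["demo"], p["drug"], p["reac"], p["hist"])
        assert len(rs) == 3
        assert {r.case_id for r in rs} == {"A1", "A2", "A3"}

    def test_drug_names_normalized_and_dates_parsed(self, tmp_path):
        p = _write_four_tables(tmp_path, DEMO, DRUG, REAC, HIST)
        rs = load_report_set(p["demo"], p["drug"], p["reac"], p["hist"])
        exen = rs["A1"].drugs[0]
        assert exen.drug_name == "exenatide"
        assert exen.start_date == datetime.date(2010, 1, 1)
        assert rs["A2"].drugs[0].start_date is None  # missing stays missing

    def test_case_only_in_demo_gets_empty_lists(self, tmp_path):
        p = _write_four_tables(
            tmp_path, DEMO, "case_id,drug_name,role,start_date,end_date\n",
            "case_id,pt_id,pt_name,onset_date\n", "case_id,disease\n",
        )
        rs = load_report_set(p["demo"], p["drug"], p["reac"], p["hist"])
        assert rs["A1"].drugs == () and rs["A1"].events == ()

    def test_unmatched_event_rows_create_records(self, tmp_path):
        reac = REAC + "A9,10047700,Vomiting,\n"
        p = _write_four_tables(tmp_path, DEMO, DRUG, reac, HIST)
        rs = load_report_set(p["demo"], p["drug"], p["reac"], p["hist"])
        assert "A9" in rs and rs["A9"].sex is None

    def test_duplicate_drug_rows_collapse_with_warning(self, tmp_path, caplog):
        drug = DRUG + "A1,Exenatide,suspect,2010-01-01,2010-06-01\n"
        p = _write_four_tables(tmp_path, DEMO, drug, REAC, HIST)
        with caplog.at_level("WARNING"):
            rs = load_report_set(p["demo"], p["drug"], p["reac"], p["hist"])
        assert sum(d.drug_name == "exenatide" for d in rs["A1"].drugs) == 1
        assert "duplicate" in caplog.text

    def test_malformed_date_names_file_and_line(self, tmp_path):
        drug = DRUG.replace("2010-01-01", "01/2010")
        p = _write_four_tables(tmp_path, DEMO, drug, REAC, HIST)
        with pytest.raises(ValueError, match="drug.csv"):
            load_report_set(p["demo"], p["drug"], p["reac"], p["hist"])

    def test_simulated_set_round_trips_through_files(self, tmp_path):
        cfg = default_config(n_reports=300, seed=9)
        rs = simulate(cfg)
        paths = write_report_set(rs, tmp_path)
        rs2 = load_report_set(
            paths["demo"], paths["drug"], paths["reac"], paths["hist"]
        )
        assert rs2 == rs

    def test_custom_dialect_column_names(self, tmp_path):
        dialect = Dialect(
            delimiter="\t",
            demo_cols={"case_id": "id", "sex": "seibetsu", "age": "nenrei"},
        )
        (tmp_path / "demo.csv").write_text("id\tseibetsu\tnenrei\nB1\tfemale\t30-39\n")
        for name, header in (
            ("drug", "case_id\tdrug_name\trole\tstart_date\tend_date"),
            ("reac", "case_id\tpt_id\tpt_name\tonset_date"),
            ("hist", "case_id\tdisease"),
        ):
            (tmp_path / f"{name}.csv").write_text(header + "\n")
        rs = load_report_set(
            tmp_path / "demo.csv", tmp_path / "drug.csv",
            tmp_path / "reac.csv", tmp_path / "hist.csv", dialect,
        )
        assert rs["B1"].sex == "female" and rs["B1"].age_bucket == "30-39"


class TestApplyExclusions:
    def test_missing_sex_and_qualitative_age_excluded(self, mixed_reports):
        kept = apply_exclusions(mixed_reports)
        assert {r.case_id for r in kept} == {"C1", "C4", "C5"}

    def test_disease_restriction(self, mixed_reports):
        kept = apply_exclusions(
            mixed_reports, require_primary_disease_in={"type 2 diabetes mellitus"}
        )
        assert len(kept) == 3
        none = apply_exclusions(mixed_reports, require_primary_disease_in={"asthma"})
        assert len(none) == 0

    def test_idempotent(self, mixed_reports):
        once = apply_exclusions(mixed_reports)
        twice = apply_exclusions(once)
        assert once == twice

    def test_matches_independent_row_scan_on_synthetic_data(self):
        cfg = default_config(n_reports=10_000, seed=21)
        cfg.missing_sex_rate = 0.1
        cfg.missing_age_rate = 0.1
        rs = simulate(cfg)
        kept = apply_exclusions(rs)
        # independent oracle: raw row scan over record fields
        expected = sum(
            1 for r in rs
            if r.sex in ("male", "female")
            and r.age_bucket in DECADE_BUCKETS
            and len(r.primary_diseases) > 0
        )
        assert len(kept) == expected
        assert 0 < len(kept) < len(rs)


class TestClassifyCase:
    def test_any_member_event_is_a_case(self, gerd_pts):
        r = make_report(events=[("10047700", "Vomiting"), ("10019211", "Hepatitis")])
        assert classify_case(r, gerd_pts) is True

    def test_non_member_event_is_noncase(self, gerd_pts):
        r = make_report(events=[("10019211", "Hepatitis")])
        assert classify_case(r, gerd_pts) is False

    def test_zero_events_is_an_error(self, gerd_pts):
        r = make_report(events=[])
        with pytest.raises(ValueError, match="no adverse events"):
            classify_case(r, gerd_pts)

    def test_union_distributes_over_or(self, gerd_pts):
        p1 = PTSet("half1", frozenset(list(gerd_pts.pt_ids)[:18]))
        p2 = PTSet("half2", frozenset(list(gerd_pts.pt_ids)[18:]))
        union = p1.union(p2)
        cfg = default_config(n_reports=500, seed=2)
        for r in simulate(cfg):
            assert classify_case(r, union) == (
                classify_case(r, p1) or classify_case(r, p2)
            )

    def test_case_count_matches_membership_scan(self, gerd_pts):
        cfg = default_config(n_reports=1_000, seed=4)
        rs = simulate(cfg)
        count = sum(classify_case(r, gerd_pts) for r in rs)
        oracle = sum(
            1 for r in rs if {e.pt_id for e in r.events} & set(gerd_pts.pt_ids)
        )
        assert count == oracle


class TestIsExposed:
    def test_suspect_member_counts(self, glp1):
        r = make_report(drugs=[("exenatide", "suspect")])
        assert is_exposed(r, glp1) is True

    def test_concomitant_only_does_not_count_by_default(self, dpp4):
        r = make_report(drugs=[("sitagliptin", "concomitant")])
        assert is_exposed(r, dpp4) is False
        assert is_exposed(r, dpp4, include_concomitant=True) is True

    def test_single_drug_name_target(self):
        r = make_report(drugs=[("exenatide",)])
        assert is_exposed(r, "Exenatide") is True
        assert is_exposed(r, "liraglutide") is False

    def test_exposure_counts_match_row_scan(self, glp1):
        cfg = default_config(n_reports=5_000, seed=6)
        rs = simulate(cfg)
        count = sum(is_exposed(r, glp1) for r in rs)
        oracle = sum(
            1 for r in rs
            if any(d.drug_name in glp1.members and d.role == "suspect" for d in r.drugs)
        )
        assert count == oracle > 0


class TestShippedDefinitions:
    def test_gerd_query_has_36_distinct_pts(self, gerd_pts):
        assert len(gerd_pts.pt_ids) == 36
        assert all(p.startswith("100") and len(p) == 8 for p in gerd_pts.pt_ids)

    def test_drug_classes(self, glp1, dpp4):
        assert glp1.members == {"dulaglutide", "exenatide", "liraglutide", "lixisenatide"}
        assert len(dpp4.members) == 9

    def test_duplicate_class_members_collapse(self):
        cls = DrugClassDef("x", frozenset({"A", "a ", "b"}))
        assert cls.members == {"a", "b"}

    def test_drug_entry_rejects_reversed_dates(self):
        with pytest.raises(ValueError, match="precedes"):
            DrugEntry("x", start_date=datetime.date(2010, 5, 1),
                      end_date=datetime.date(2010, 1, 1))

    def test_duplicate_case_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ReportSet([make_report("C1"), make_report("C1")])
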