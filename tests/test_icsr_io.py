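"""Raw-table parsing, deduplication, PLID construction and name matching."""

import random
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.icsr_io import (
    DemoRecord,
    DrugRecord,
    EventTarget,
    PlidCase,
    RawTables,
    ReacRecord,
    build_plid,
    deduplicate_faers,
    match_event,
    parse_complete_date,
    read_plid,
    read_tables,
    standardize_drug_name,
    write_plid,
    write_tables,
)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def test_faers_demo_line_maps_fields(tmp_path):
    (tmp_path / "demo.txt").write_text(
        "primaryid$caseid$caseversion$sex$age$age_cod$event_dt\n"
        "1001$100$1$M$65$YR$20200101\n")
    (tmp_path / "drug.txt").write_text(
        "primaryid$drug_seq$drugname$role_cod\n1001$1$MIRABEGRON$PS\n")
    (tmp_path / "reac.txt").write_text("primaryid$pt\n1001$Atrial fibrillation\n")
    raw = read_tables({"demo": tmp_path / "demo.txt",
                       "drug": tmp_path / "drug.txt",
                       "reac": tmp_path / "reac.txt"}, "FAERS")
    rec = raw.demo[0]
    assert rec.case_version == 1
    assert rec.sex == "male"
    assert rec.age_years == 65
    assert rec.event_date == date(2020, 1, 1)
    assert raw.drug[0].role == "primary_suspected"


def test_blank_and_partial_dates_map_to_missing(tmp_path):
    (tmp_path / "demo.csv").write_text("case_id,sex,age\nA1,male,60s\n")
    (tmp_path / "drug.csv").write_text(
        "case_id,drug_name,role,drug_seq,start_date\n"
        "A1,MIRABEGRON,suspected,1,\n"
        "A1,ASPIRIN,concomitant,2,202001\n")  # partial year-month
    (tmp_path / "reac.csv").write_text(
        "case_id,pt_code,pt_name,onset_date\nA1,10003658,Atrial fibrillation,2020\n")
    raw = read_tables({"demo": tmp_path / "demo.csv",
                       "drug": tmp_path / "drug.csv",
                       "reac": tmp_path / "reac.csv"}, "JADER")
    assert all(r.start_date is None for r in raw.drug)
    assert raw.reac[0].onset_date is None
    assert raw.parse_log.partial_dates == 2


@pytest.mark.parametrize("value", ["2020", "202001", "2020-01", "20201340", "n/a"])
def test_partial_or_garbled_date_never_becomes_a_date(value):
    assert parse_complete_date(value) is None


def test_three_case_jader_fixture_counts(tmp_path):
    (tmp_path / "demo.csv").write_text(
        "case_id,sex,age\nA1,male,60s\nA2,female,70s\nA3,female,40s\n")
    (tmp_path / "drug.csv").write_text(
        "case_id,drug_name,role,drug_seq,start_date\n"
        "A1,MIRABEGRON,suspected,1,20200101\n"
        "A2,SOLIFENACIN,suspected,1,20200201\n"
        "A2,ASPIRIN,concomitant,2,\n"
        "A3,VIBEGRON,suspected,1,20200301\n")
    (tmp_path / "reac.csv").write_text(
        "case_id,pt_code,pt_name,onset_date\n"
        "A1,10003658,Atrial fibrillation,20200401\n"
        "A2,99000001,Drug ineffective,\n")
    raw = read_tables({"demo": tmp_path / "demo.csv",
                       "drug": tmp_path / "drug.csv",
                       "reac": tmp_path / "reac.csv"}, "JADER")
    assert len(raw.demo) == 3
    assert len(raw.drug) == 4
    assert len(raw.reac) == 2
    plid, log = build_plid(raw)
    assert len(plid) == 3
    assert log.n_orphans == 0


def test_missing_mandatory_column_is_a_hard_error(tmp_path):
    (tmp_path / "demo.csv").write_text("ident,sex,age\nA1,male,60s\n")
    (tmp_path / "drug.csv").write_text("case_id,drug_name\nA1,X\n")
    (tmp_path / "reac.csv").write_text("case_id,pt_name\nA1,Y\n")
    with pytest.raises(ValueError, match="demo.*case_id"):
        read_tables({"demo": tmp_path / "demo.csv",
                     "drug": tmp_path / "drug.csv",
                     "reac": tmp_path / "reac.csv"}, "JADER")


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def _demo(case, version, rid=None):
    return DemoRecord(case_id=case, report_id=rid or f"{case}-{version}",
                      case_version=version)


def test_single_version_case_unchanged():
    recs = [_demo("7", 1)]
    assert deduplicate_faers(recs) == recs


def test_highest_caseversion_retained():
    recs = [_demo("7", v) for v in (1, 3, 2)]
    (kept,) = deduplicate_faers(recs)
    assert kept.case_version == 3


def test_dedup_matches_brute_force_groupby_max():
    rng = random.Random(5)
    recs = []
    for c in range(10):
        for v in (1, 2):
            recs.append(_demo(str(c), v))
    rng.shuffle(recs)
    kept = deduplicate_faers(recs)
    # brute force: per case, max by (version, report_id)
    expect = {}
    for r in recs:
        k = expect.get(r.case_id)
        if k is None or (r.case_version, r.report_id) > (k.case_version, k.report_id):
            expect[r.case_id] = r
    assert len(kept) == 10
    assert {r.case_id: r for r in kept} == expect
    assert all(r.case_version == 2 for r in kept)


def test_version_tie_broken_by_report_id():
    recs = [_demo("9", 2, rid="9-b"), _demo("9", 2, rid="9-a")]
    (kept,) = deduplicate_faers(recs)
    assert kept.report_id == "9-b"


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 4), st.integers(0, 9))))
def test_dedup_idempotent(triples):
    recs = [_demo(str(c), v, rid=f"{c}-{r}") for c, v, r in triples]
    once = deduplicate_faers(recs)
    assert deduplicate_faers(once) == once
    assert len({r.case_id for r in once}) == len(once)


# ---------------------------------------------------------------------------
# PLID
# ---------------------------------------------------------------------------


def test_max_drug_seq_is_max_over_rows():
    raw = RawTables(source_system="JADER",
                    demo=[DemoRecord("A", "A")],
                    drug=[DrugRecord("A", "X", drug_seq=1),
                          DrugRecord("A", "Y", drug_seq=4)],
                    reac=[ReacRecord("A", pt_name="rash")])
    (case,), _ = build_plid(raw)
    assert case.max_drug_seq == 4


def test_orphan_drug_row_dropped_and_counted():
    raw = RawTables(source_system="JADER",
                    demo=[DemoRecord("A", "A")],
                    drug=[DrugRecord("B", "X")])
    plid, log = build_plid(raw)
    assert len(plid) == 1
    assert plid[0].drugs == ()
    assert log.orphan_records["drug"] == 1


def test_case_without_drug_rows_retained_empty():
    raw = RawTables(source_system="JADER", demo=[DemoRecord("A", "A")])
    (case,), _ = build_plid(raw)
    assert case.drugs == () and case.max_drug_seq == 0


def test_duplicate_case_id_after_dedup_is_hard_error():
    raw = RawTables(source_system="JADER",
                    demo=[DemoRecord("A", "A"), DemoRecord("A", "A")])
    with pytest.raises(ValueError, match="duplicate case_id"):
        build_plid(raw)


def test_plid_matches_hand_joined_fixture():
    # five cases covering: multi-drug, multi-event, no drugs, no events
    raw = RawTables(
        source_system="JADER",
        demo=[DemoRecord(c, c, sex=s, age_band=b)
              for c, s, b in [("A", "male", "60s"), ("B", "female", "70s"),
                              ("C", "female", "40s"), ("D", "unknown", None),
                              ("E", "male", "80s")]],
        drug=[DrugRecord("A", "MIRABEGRON", role="suspected", drug_seq=1,
                         start_date=date(2020, 1, 1)),
              DrugRecord("A", "ASPIRIN", role="concomitant", drug_seq=2),
              DrugRecord("B", "SOLIFENACIN", role="suspected", drug_seq=3),
              DrugRecord("C", "VIBEGRON", role="interacting", drug_seq=1),
              DrugRecord("E", "MIRABEGRON", role="suspected", drug_seq=1)],
        reac=[ReacRecord("A", 10003658, "Atrial fibrillation", date(2020, 3, 1)),
              ReacRecord("B", 99000001, "Drug ineffective", None),
              ReacRecord("B", 10003658, "Atrial fibrillation", None)],
    )
    plid, log = build_plid(raw, synonyms={"mirabegron": "mirabegron",
                                          "solifenacin": "solifenacin"})
    by_id = {c.case_id: c for c in plid}
    assert sorted(by_id) == ["A", "B", "C", "D", "E"]
    assert by_id["A"].max_drug_seq == 2
    assert {d.name for d in by_id["A"].drugs} == {"mirabegron", "aspirin"}
    assert len(by_id["B"].events) == 2
    assert by_id["C"].drugs[0].name_std is None  # not in dictionary
    assert by_id["D"].drugs == ()
    assert sum(len(c.drugs) for c in plid) == 5  # every linkable DRUG row lands
    assert log.n_orphans == 0


def test_faers_ther_dates_attach_by_drug_seq(tmp_path):
    (tmp_path / "demo.txt").write_text(
        "primaryid$caseid$caseversion$sex$age$age_cod$event_dt\n"
        "11$1$1$F$70$YR$20210601\n")
    (tmp_path / "drug.txt").write_text(
        "primaryid$drug_seq$drugname$role_cod\n11$1$MIRABEGRON$PS\n11$2$OTHER$C\n")
    (tmp_path / "reac.txt").write_text("primaryid$pt\n11$Atrial fibrillation\n")
    (tmp_path / "ther.txt").write_text(
        "primaryid$dsg_drug_seq$start_dt\n11$1$20210501\n11$2$20200101\n")
    raw = read_tables({"demo": tmp_path / "demo.txt", "drug": tmp_path / "drug.txt",
                       "reac": tmp_path / "reac.txt", "ther": tmp_path / "ther.txt"},
                      "FAERS")
    (case,), _ = build_plid(raw, synonyms={"mirabegron": "mirabegron"})
    starts = {d.name: d.start_dates for d in case.drugs}
    assert starts["mirabegron"] == (date(2021, 5, 1),)
    assert starts["other"] == (date(2020, 1, 1),)


# ---------------------------------------------------------------------------
# standardization and matching
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("raw_name,expected", [
    ("MIRABEGRON.", "mirabegron"),
    ("  Mirabegron  ", "mirabegron"),
    ("MIRABEGRON 50 MG", "mirabegron"),
    ("BETANIS", "mirabegron"),
    ("ASPIRIN", None),
    ("MIRABEGRONE", None),  # prefix must end at a word boundary
])
def test_standardize_drug_name(raw_name, expected):
    d = {"mirabegron": "mirabegron", "betanis": "mirabegron"}
    assert standardize_drug_name(raw_name, d) == expected


def test_match_event_by_code_term_and_normalization():
    from pvsignal.icsr_io import CaseEvent

    target = EventTarget.of(10003658, ["atrial fibrillation"])
    # by PT code
    c1 = PlidCase(case_id="A", events=(CaseEvent(10003658, "Atrial fibrillation", None),))
    assert match_event(c1, target)
    # non-matching term, no code
    c2 = PlidCase(case_id="B", events=(CaseEvent(None, "atrial flutter", None),))
    assert not match_event(c2, target)
    # normalization: whitespace and case folded
    c3 = PlidCase(case_id="C", events=(CaseEvent(None, " Atrial  Fibrillation ", None),))
    assert match_event(c3, target)


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("fixture", ["jader_draw", "faers_draw"])
def test_raw_tables_round_trip(fixture, request, tmp_path):
    _, raw, _ = request.getfixturevalue(fixture)
    sub = RawTables(source_system=raw.source_system,
                    demo=raw.demo[:300], drug=raw.drug[:300],
                    reac=raw.reac[:300], hist=raw.hist[:50],
                    indi=raw.indi[:50], ther=raw.ther[:300],
                    outc=raw.outc[:50])
    paths = write_tables(sub, tmp_path)
    back = read_tables(paths, raw.source_system)
    assert back.demo == sub.demo
    assert back.drug == sub.drug
    assert back.reac == sub.reac
    assert back.ther == sub.ther
    assert back.parse_log.n_issues == 0


def test_plid_round_trip(jader_draw, tmp_path):
    _, raw, _ = jader_draw
    from pvsignal.synthetic import default_synonyms
    plid, _ = build_plid(raw, synonyms=default_synonyms())
    write_plid(plid[:200], tmp_path / "plid.tsv")
    back = read_plid(tmp_path / "plid.tsv")
    assert back == plid[:200]
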