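import datetime as dt
import itertools

import pytest
from hypothesis import given, strategies as st

from faerspv import faers_io
from faerspv.records import CaseReport, DemoRecord, DrugRecord, ReacRecord


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="latin-1")


class TestReadTable:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(path, ["primaryid$caseid$fda_dt$sex", "1001$500$20240101$F"])
        (rec,) = faers_io.read_faers_table(path, "demo")
        assert rec.primary_id == "1001"
        assert rec.case_id == "500"
        assert rec.report_date == dt.date(2024, 1, 1)
        assert rec.sex == "F"

    def test_empty_fields_become_missing(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(path, ["primaryid$caseid$fda_dt$sex", "1002$501$$"])
        (rec,) = faers_io.read_faers_table(path, "demo")
        assert rec.report_date is None and rec.sex is None

    def test_header_case_insensitive_and_isr_alias(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(path, ["ISR$CASEID$FDA_DT", "7$3$20100601"])
        (rec,) = faers_io.read_faers_table(path, "demo")
        assert rec.primary_id == "7"
        assert rec.report_date == dt.date(2010, 6, 1)

    def test_partial_dates_default_to_first(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(path, ["primaryid$caseid$fda_dt", "1$1$202403", "2$1$2019"])
        recs = faers_io.read_faers_table(path, "demo")
        assert recs[0].report_date == dt.date(2024, 3, 1)
        assert recs[1].report_date == dt.date(2019, 1, 1)

    def test_missing_primaryid_column_is_hard_error(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(path, ["caseid$fda_dt", "500$20240101"])
        with pytest.raises(ValueError, match="primaryid"):
            faers_io.read_faers_table(path, "demo")

    def test_unparseable_date_kept_with_missing_date(self, tmp_path):
        path = tmp_path / "demo.txt"
        write_lines(path, ["primaryid$caseid$fda_dt", "1$9$NOTADATE"])
        (rec,) = faers_io.read_faers_table(path, "demo")
        assert rec.primary_id == "1" and rec.report_date is None

    def test_unknown_extra_columns_ignored(self, tmp_path):
        path = tmp_path / "drug.txt"
        write_lines(path, [
            "primaryid$mystery$drug_seq$role_cod$drugname",
            "1$zzz$1$PS$TRAZODONE HYDROCHLORIDE",
        ])
        (rec,) = faers_io.read_faers_table(path, "drug")
        assert rec.role == "PS" and rec.drug_name == "TRAZODONE HYDROCHLORIDE"

    def test_round_trip_preserves_records(self, tmp_path, small_dataset):
        for kind in faers_io.TABLE_KINDS:
            path = tmp_path / f"{kind}.txt"
            records = getattr(small_dataset, kind)[:50]
            faers_io.write_faers_table(path, records, kind)
            assert faers_io.read_faers_table(path, kind) == records


class TestDeduplicate:
    def test_most_recent_report_retained(self):
        demo = [
            DemoRecord("1", "500", report_date=dt.date(2020, 1, 1)),
            DemoRecord("2", "500", report_date=dt.date(2021, 6, 1)),
        ]
        (survivor,) = faers_io.deduplicate_cases(demo)
        assert survivor.primary_id == "2"

    def test_single_report_per_case_unchanged(self):
        demo = [DemoRecord("1", "a"), DemoRecord("2", "b")]
        assert faers_io.deduplicate_cases(demo) == demo

    def test_date_tie_broken_by_larger_primary_id_any_order(self):
        base = [
            DemoRecord("7", "c1", report_date=dt.date(2022, 5, 5)),
            DemoRecord("9", "c1", report_date=dt.date(2022, 5, 5)),
        ]
        for perm in itertools.permutations(base):
            (survivor,) = faers_io.deduplicate_cases(list(perm))
            assert survivor.primary_id == "9"

    def test_missing_date_loses_to_dated_report(self):
        demo = [
            DemoRecord("5", "c1", report_date=None),
            DemoRecord("4", "c1", report_date=dt.date(2005, 1, 1)),
        ]
        (survivor,) = faers_io.deduplicate_cases(demo)
        assert survivor.primary_id == "4"

    def test_all_undated_keeps_largest_id(self):
        demo = [DemoRecord(str(i), "c1") for i in (3, 11, 7)]
        (survivor,) = faers_io.deduplicate_cases(demo)
        assert survivor.primary_id == "11"

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 50),  # primary id
                st.integers(1, 6),  # case id
                st.one_of(st.none(), st.dates(dt.date(2004, 1, 1), dt.date(2024, 6, 30))),
            ),
            max_size=30,
            unique_by=lambda t: t[0],
        )
    )
    def test_unique_cases_and_idempotence(self, rows):
        demo = [DemoRecord(str(pid), str(cid), report_date=date)
                for pid, cid, date in rows]
        out = faers_io.deduplicate_cases(demo)
        assert len({r.case_id for r in out}) == len(out)
        assert len(out) <= len(demo)
        assert faers_io.deduplicate_cases(out) == out


class TestAssemble:
    def test_join_and_pt_dedup(self):
        demo = [DemoRecord("1", "c1")]
        drugs = [DrugRecord("1", "1", "PS", "A"), DrugRecord("1", "2", "C", "B")]
        reac = [ReacRecord("1", "Nausea"), ReacRecord("1", "NAUSEA"),
                ReacRecord("1", "Headache")]
        (case,) = faers_io.assemble_cases(demo, drugs, reac)
        assert len(case.drugs) == 2
        assert case.pts == {"NAUSEA", "HEADACHE"}

    def test_orphan_child_rows_dropped(self):
        demo = [DemoRecord("1", "c1")]
        reac = [ReacRecord("2", "NAUSEA")]
        (case,) = faers_io.assemble_cases(demo, reac=reac)
        assert case.reactions == []

    def test_order_invariance(self, small_dataset):
        ds = small_dataset
        demo = faers_io.deduplicate_cases(ds.demo)
        forward = faers_io.assemble_cases(demo, ds.drug, ds.reac, ds.outc,
                                          ds.ther, ds.indi)
        backward = faers_io.assemble_cases(
            demo, ds.drug[::-1], ds.reac[::-1], ds.outc[::-1],
            ds.ther[::-1], ds.indi[::-1])
        key = lambda c: c.primary_id
        for f, b in zip(sorted(forward, key=key), sorted(backward, key=key)):
            assert f.primary_id == b.primary_id
            assert f.pts == b.pts
            assert sorted(map(repr, f.drugs)) == sorted(map(repr, b.drugs))
            assert sorted(o.outcome_code for o in f.outcomes) == sorted(
                o.outcome_code for o in b.outcomes)


class TestPrimarySuspectFilter:
    def _case(self, pid, drugs):
        return CaseReport(demo=DemoRecord(pid, pid), drugs=drugs)

    def test_substring_match_on_salt_name(self):
        case = self._case("1", [DrugRecord("1", "1", "PS", "TRAZODONE HYDROCHLORIDE")])
        kept = faers_io.filter_primary_suspect([case], ["trazodone"])
        assert kept and kept[0].matched_drug_seqs == {"1"}

    def test_concomitant_role_excluded(self):
        case = self._case("1", [DrugRecord("1", "1", "C", "TRAZODONE")])
        assert faers_io.filter_primary_suspect([case], ["trazodone"]) == []

    def test_active_ingredient_matches(self):
        case = self._case("1", [DrugRecord("1", "1", "PS", "DESYREL",
                                           active_ingredient="TRAZODONE HCL")])
        assert faers_io.filter_primary_suspect([case], ["trazodone"])

    def test_empty_target_list_is_hard_error(self):
        with pytest.raises(ValueError):
            faers_io.filter_primary_suspect([], [])

    def test_matches_brute_force_scan(self, small_cases):
        kept = faers_io.filter_primary_suspect(small_cases, ["trazodone"])
        expected = {
            c.primary_id
            for c in small_cases
            if any(d.role == "PS" and "trazodone" in (d.drug_name or "").lower()
                   for d in c.drugs)
        }
        assert {c.primary_id for c in kept} == expected
        assert 0 < len(kept) < len(small_cases)
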