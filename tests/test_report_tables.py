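import datetime as dt

import pytest

from faerspv import faers_io, report_tables as rt
from faerspv.bayesian import BcpnnResult, MgpsCell
from faerspv.frequentist import PrrResult, RorResult
from faerspv.records import (
    CaseReport,
    DemoRecord,
    DrugRecord,
    ReacRecord,
    TherapyRecord,
)
from faerspv.signals import SignalDecision


class TestBreakdown:
    def test_percent_convention(self):
        result = rt.breakdown("Outcomes", [("Hospitalization", 1298),
                                           ("Everything else", 3651)])
        assert result.rows[0] == ("Hospitalization", 1298, 26.23)

    def test_single_row_is_hundred_percent(self):
        result = rt.breakdown("Gender", [("Female", 1)])
        assert result.rows[0][2] == 100.00

    def test_rounding_is_half_up(self):
        assert rt.round_half_up(26.225) == 26.23
        assert rt.round_half_up(3.904, 1) == 3.9

    def test_section_percents_sum_to_hundred(self, small_cases):
        kept = faers_io.filter_primary_suspect(small_cases, ["trazodone"])
        for section in rt.demographics_table(kept):
            total = sum(pct for _, _, pct in section.rows)
            assert total == pytest.approx(100.0, abs=0.05)

    def test_published_counts_reproduce_published_percentages(self):
        from faerspv.studies import demographic_reference_rows

        rows = demographic_reference_rows()
        assert len(rows) == 80
        for section, label, computed, printed in rows:
            assert computed == printed, (section, label)


class TestTimeToOnset:
    def _case(self, event, starts, seqs=("1",)):
        demo = DemoRecord("1", "c1", event_date=event)
        ther = [TherapyRecord("1", str(i + 1), s) for i, s in enumerate(starts)]
        drugs = [DrugRecord("1", str(i + 1), "PS", "X") for i in range(len(starts))]
        return CaseReport(demo=demo, drugs=drugs, therapies=ther,
                          matched_drug_seqs=frozenset(seqs))

    def test_simple_gap(self):
        case = self._case(dt.date(2024, 1, 4), [dt.date(2024, 1, 1)])
        assert rt.time_to_onset(case) == 3
        assert rt.onset_bin(3) == "<7"

    def test_missing_event_date_is_unknown(self):
        case = self._case(None, [dt.date(2024, 1, 1)])
        assert rt.time_to_onset(case) is None

    def test_event_before_start_is_unknown(self):
        case = self._case(dt.date(2024, 1, 1), [dt.date(2024, 2, 1)])
        assert rt.time_to_onset(case) is None

    def test_earliest_matched_start_used(self):
        case = self._case(dt.date(2024, 3, 1),
                          [dt.date(2024, 2, 20), dt.date(2024, 1, 1)],
                          seqs=("1", "2"))
        assert rt.time_to_onset(case) == 60

    def test_unmatched_seq_ignored(self):
        case = self._case(dt.date(2024, 3, 1),
                          [dt.date(2024, 2, 20), dt.date(2024, 1, 1)],
                          seqs=("1",))
        assert rt.time_to_onset(case) == 10

    @pytest.mark.parametrize("days,label", [
        (0, "<7"), (6, "<7"), (7, "7~30"), (29, "7~30"), (30, "30~180"),
        (179, "30~180"), (180, "180~360"), (359, "180~360"), (360, ">=360"),
        (5000, ">=360"), (None, "Unknown"),
    ])
    def test_bins(self, days, label):
        assert rt.onset_bin(days) == label


def result_row(name, a, soc=None):
    return rt.DisproResult(
        name=name, soc=soc, a=a,
        ror=RorResult(2.0, 1.5, 3.0),
        prr=PrrResult(2.0, 1.5, 3.0, chisq=10.0),
        bcpnn=BcpnnResult(1.0, 0.2, 0.6),
        mgps=MgpsCell(a, 1.0, 0.5, 2.0, 1.5),
        decision=SignalDecision(True, True, True, False),
    )


class TestRanking:
    def test_top_pt_selection(self):
        rows = [result_row("X", 5), result_row("Y", 3), result_row("Z", 1)]
        assert [r.name for r in rt.top_pt_table(rows, k=2)] == ["X", "Y"]

    def test_tie_broken_by_pt_string(self):
        rows = [result_row("B", 5), result_row("A", 5)]
        assert [r.name for r in rt.top_pt_table(rows, k=2)] == ["A", "B"]

    def test_k_larger_than_available(self):
        rows = [result_row("X", 5)]
        assert len(rt.top_pt_table(rows, k=20)) == 1

    def test_topk_is_prefix_of_full_sort(self):
        rows = [result_row(f"PT{i}", a) for i, a in enumerate([4, 9, 1, 9, 2, 7])]
        full = rt.top_pt_table(rows, k=len(rows))
        for k in range(len(rows) + 1):
            assert rt.top_pt_table(rows, k=k) == full[:k]

    def test_soc_table_sorted_descending(self):
        rows = [result_row("SOC_B", 3, "SOC_B"), result_row("SOC_A", 9, "SOC_A")]
        assert [r.name for r in rt.soc_table(rows)] == ["SOC_A", "SOC_B"]


class TestAgeDistribution:
    def _case(self, pid, age, pts):
        return CaseReport(
            demo=DemoRecord(pid, pid, age_value=age, age_unit="YR"),
            reactions=[ReacRecord(pid, pt) for pt in pts],
        )

    def test_banded_tally(self):
        cases = [self._case("1", 45, ["PRIAPISM"]), self._case("2", 55, ["PRIAPISM"])]
        hist, excluded = rt.age_distribution(cases, ["PRIAPISM"])
        assert hist["PRIAPISM"] == {"40~50": 1, "50~60": 1}
        assert excluded["PRIAPISM"] == 0

    def test_all_missing_ages_excluded(self):
        cases = [self._case(str(i), None, ["X"]) for i in range(4)]
        hist, excluded = rt.age_distribution(cases, ["X"])
        assert hist["X"] == {}
        assert excluded["X"] == 4

    def test_matches_brute_force_tally(self, small_cases):
        from faerspv.contingency import age_band

        hist, excluded = rt.age_distribution(small_cases, ["PT_0005"])
        expected = {}
        missing = 0
        for c in small_cases:
            if "PT_0005" not in c.pts:
                continue
            band = age_band(c.age_years)
            if band == "Unknown":
                missing += 1
            else:
                expected[band] = expected.get(band, 0) + 1
        assert hist["PT_0005"] == expected
        assert excluded["PT_0005"] == missing


class TestDemographicsSections:
    def test_sections_cover_report_counts(self, small_cases):
        kept = faers_io.filter_primary_suspect(small_cases, ["trazodone"])
        sections = {s.section: s for s in rt.demographics_table(kept)}
        n = len(kept)
        for name in ("Year", "Gender", "Age", "Reporter", "Route",
                     "Time to event onset (days)"):
            assert sum(c for _, c, _ in sections[name].rows) == n, name
        outcome_entries = sum(len(c.outcomes) for c in kept)
        assert sum(c for _, c, _ in sections["Outcomes"].rows) == outcome_entries

    def test_empty_case_list(self):
        assert rt.demographics_table([]) == []

    def test_age_units_normalized_to_years(self):
        case = CaseReport(demo=DemoRecord("1", "1", age_value=540.0, age_unit="MON"))
        sections = {s.section: s for s in rt.demographics_table([case])}
        assert sections["Age"].rows[0][0] == "40~50"  # 540 months = 45 years

    def test_tsv_writers(self, tmp_path, small_cases):
        kept = faers_io.filter_primary_suspect(small_cases, ["trazodone"])
        out = tmp_path / "table1.tsv"
        rt.write_breakdowns_tsv(out, rt.demographics_table(kept))
        header, *rows = out.read_text().splitlines()
        assert header == "section\tlabel\tcount\tpercent"
        assert rows
        out2 = tmp_path / "pt.tsv"
        rt.write_results_tsv(out2, [result_row("X", 5)])
        assert "is_signal" in out2.read_text().splitlines()[0]
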