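"""Drug standardization, cohort membership rules and 2x2 construction."""

import pytest

from conftest import make_tables
from pvdispro.cohort import (
    DrugDictionary,
    EventTermSet,
    build_analysis_frame,
    build_cohort,
    contingency,
    standardize_drug,
)
from pvdispro.errors import ConfigError


class TestStandardize:
    def test_synonym_maps_to_canonical(self, drug_dictionary):
        assert standardize_drug("Cipro XR", drug_dictionary) == "CIPROFLOXACIN"

    def test_canonical_identity(self, drug_dictionary):
        assert standardize_drug("OFLOXACIN", drug_dictionary) == "OFLOXACIN"

    def test_case_and_whitespace_insensitive(self, drug_dictionary):
        assert standardize_drug("  cipro   xr ", drug_dictionary) == "CIPROFLOXACIN"

    def test_unmapped_is_a_value(self, drug_dictionary):
        assert standardize_drug("tobramycin", drug_dictionary) is None

    def test_ambiguous_synonyms_rejected(self):
        with pytest.raises(ConfigError, match="maps to both"):
            DrugDictionary.from_dict(
                {
                    "A": {"synonyms": ["x"], "approval_date": 20000101},
                    "B": {"synonyms": ["X"], "approval_date": 20000101},
                }
            )

    def test_empty_event_set_rejected(self):
        with pytest.raises(ConfigError):
            EventTermSet([])


DICT = DrugDictionary.from_dict(
    {
        "OFLOXACIN": {"synonyms": ["Tarivid"], "approval_date": 19901228},
        "CIPROFLOXACIN": {"synonyms": ["Cipro"], "approval_date": 19871022},
    }
)
EVENTS = EventTermSet(["Pemphigoid"])


def _report(pid, fda="20200101", drugname="OFLOXACIN", role="PS", pts=("Pemphigoid",)):
    demo = {"primaryid": pid, "caseid": f"C{pid}", "fda_dt": fda}
    drugs = [{"primaryid": pid, "drug_seq": "1", "drugname": drugname, "role_cod": role}]
    reacs = [{"primaryid": pid, "pt": p} for p in pts]
    return demo, drugs, reacs


class TestBuildCohort:
    def _cohort(self, reports):
        demo, drugs, reacs = [], [], []
        for d, g, r in reports:
            demo.append(d)
            drugs.extend(g)
            reacs.extend(r)
        tables, _ = make_tables(demo, drugs, reacs)
        return build_cohort(tables, DICT, EVENTS)

    def test_primary_suspect_in_window_included(self):
        cohort = self._cohort([_report("1")])
        assert len(cohort) == 1
        assert cohort.iloc[0]["drug"] == "OFLOXACIN"
        assert bool(cohort.iloc[0]["event"])

    def test_concomitant_role_excluded(self):
        assert len(self._cohort([_report("1", role="C")])) == 0

    def test_before_approval_excluded(self):
        assert len(self._cohort([_report("1", fda="19891231")])) == 0

    def test_event_match_is_case_insensitive_exact(self):
        cohort = self._cohort([_report("1", pts=("PEMPHIGOID",))])
        assert bool(cohort.iloc[0]["event"])
        cohort = self._cohort([_report("2", pts=("Pemphigoid benign",))])
        assert not bool(cohort.iloc[0]["event"])

    def test_multi_ps_report_enters_both_cohorts_once_each(self):
        d, g, r = _report("1")
        g.append({"primaryid": "1", "drug_seq": "2", "drugname": "Cipro", "role_cod": "PS"})
        cohort = self._cohort([(d, g, r)])
        assert sorted(cohort["drug"]) == ["CIPROFLOXACIN", "OFLOXACIN"]
        assert cohort.groupby("drug")["primaryid"].nunique().eq(1).all()


class TestContingency:
    def _frame(self, reports):
        demo, drugs, reacs = [], [], []
        for d, g, r in reports:
            demo.append(d)
            drugs.extend(g)
            reacs.extend(r)
        tables, _ = make_tables(demo, drugs, reacs)
        return build_analysis_frame(tables, DICT, EVENTS)

    def test_hand_enumerated_partition(self):
        reports = (
            [_report(str(i)) for i in (1, 2)]  # drug & event -> a
            + [_report(str(i), pts=("Nausea",)) for i in (3, 4, 5)]  # drug only -> b
            + [_report("6", drugname="AMOXICILLIN")]  # event only -> c
            + [_report(str(i), drugname="AMOXICILLIN", pts=("Nausea",)) for i in (7, 8, 9, 10)]
        )
        t = contingency(self._frame(reports), "OFLOXACIN")
        assert (t.a, t.b, t.c, t.d) == (2, 3, 1, 4)
        assert t.n == 10

    def test_no_exposed_reports(self):
        reports = [_report("1", drugname="AMOXICILLIN"), _report("2", drugname="AMOXICILLIN")]
        t = contingency(self._frame(reports), "OFLOXACIN")
        assert (t.a, t.b) == (0, 0) and t.n == 2

    def test_all_exposed_and_evented(self):
        reports = [_report(str(i)) for i in range(1, 4)]
        t = contingency(self._frame(reports), "OFLOXACIN")
        assert (t.a, t.b, t.c, t.d) == (3, 0, 0, 0)

    def test_window_restricts_both_margins(self):
        reports = [
            _report("1", fda="19950101"),
            _report("2", fda="19950101", drugname="AMOXICILLIN"),
            _report("3", fda="20200101"),
        ]
        frame = self._frame(reports)
        assert contingency(frame, "OFLOXACIN").n == 3
        assert contingency(frame, "OFLOXACIN", approval_date=19960101).n == 1

    def test_unknown_drug_column_rejected(self):
        with pytest.raises(ConfigError, match="no primary-suspect"):
            contingency(self._frame([_report("1")]), "LINEZOLID")


def test_frame_and_cohort_consistency_on_synthetic_data(small_tables, drug_dictionary, event_terms):
    from pvdispro.ingest import deduplicate, restrict_to

    tables = restrict_to(small_tables, deduplicate(small_tables.demo))
    frame = build_analysis_frame(tables, drug_dictionary, event_terms)
    cohort = build_cohort(tables, drug_dictionary, event_terms)
    assert len(frame) == tables.demo["caseid"].nunique()
    # cohort membership implies the frame flags the same report as PS
    from pvdispro.cohort import ps_column

    for drug, grp in cohort.groupby("drug"):
        flagged = set(frame.loc[frame[ps_column(drug)], "primaryid"])
        assert set(grp["primaryid"]).issubset(flagged)
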