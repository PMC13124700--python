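"""Quarterly-file parsing, normalisation and FDA-style deduplication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_tables, random_demo
from pvdispro.errors import FormatError, IntegrityError
from pvdispro.ingest import deduplicate, read_quarter


class TestReadAndNormalize:
    def test_single_complete_row(self, tiny_tables_factory):
        tables, report = tiny_tables_factory(
            [{"primaryid": "1", "caseid": "A", "fda_dt": "20230315", "event_dt": "20230301",
              "sex": "F", "age": "70", "age_cod": "YR", "wt": "60", "wt_cod": "KG",
              "occp_cod": "MD", "occr_country": "Europe", "outc_cod": "HO"}],
        )
        row = tables.demo.iloc[0]
        assert row["sex"] == "F" and row["occp_cod"] == "MD" and row["outc_cod"] == "HO"
        assert row["age_years"] == 70 and row["weight_kg"] == 60
        assert row["report_year"] == 2023
        assert report.total_warnings() == 0

    def test_missing_codes_become_ns(self, tiny_tables_factory):
        tables, _ = tiny_tables_factory(
            [{"primaryid": "1", "caseid": "A", "fda_dt": "20230315",
              "sex": "", "occp_cod": "LW", "outc_cod": ""}],
        )
        row = tables.demo.iloc[0]
        assert row["sex"] == "NS" and row["occp_cod"] == "NS" and row["outc_cod"] == "NS"

    def test_partial_date_is_missing_but_year_kept(self, tiny_tables_factory):
        tables, report = tiny_tables_factory(
            [{"primaryid": "1", "caseid": "A", "fda_dt": "2023"}],
        )
        row = tables.demo.iloc[0]
        assert pd.isna(row["fda_date"])
        assert row["report_year"] == 2023
        assert report.partial_dates["fda_dt"] == 1

    @pytest.mark.parametrize(
        "age, cod, years",
        [("7", "DEC", 70.0), ("18", "MON", 1.5), ("730.5", "DY", 2.0), ("45", "", 45.0)],
    )
    def test_age_unit_normalisation(self, tiny_tables_factory, age, cod, years):
        tables, _ = tiny_tables_factory(
            [{"primaryid": "1", "caseid": "A", "fda_dt": "20230315", "age": age, "age_cod": cod}],
        )
        assert tables.demo.iloc[0]["age_years"] == pytest.approx(years)

    def test_weight_lbs_to_kg(self, tiny_tables_factory):
        tables, _ = tiny_tables_factory(
            [{"primaryid": "1", "caseid": "A", "fda_dt": "20230315", "wt": "154.3", "wt_cod": "LBS"}],
        )
        assert tables.demo.iloc[0]["weight_kg"] == pytest.approx(154.3 * 0.45359237)

    def test_outcome_other_serious_collapse(self, tiny_tables_factory):
        tables, _ = tiny_tables_factory(
            [{"primaryid": "1", "caseid": "A", "fda_dt": "20230315", "outc_cod": "LT"}],
        )
        assert tables.demo.iloc[0]["outc_cod"] == "OT"

    def test_malformed_rows_counted_not_silently_dropped(self, tiny_tables_factory):
        tables, report = tiny_tables_factory(
            [
                {"primaryid": "1", "caseid": "A", "fda_dt": "20230315"},
                {"primaryid": "", "caseid": "B", "fda_dt": "20230316"},
            ],
        )
        assert len(tables.demo) == 1
        assert report.malformed_rows["demo"] == 1

    def test_missing_mandatory_column_names_file_and_column(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("primaryid$caseid\n1$A\n")
        for name in ("DRUG", "REAC", "THER"):
            (tmp_path / f"{name}.txt").write_text("primaryid\n1\n")
        with pytest.raises(FormatError, match="fda_dt"):
            read_quarter(
                tmp_path / "DEMO.txt", tmp_path / "DRUG.txt",
                tmp_path / "REAC.txt", tmp_path / "THER.txt",
            )


class TestDeduplicate:
    def _demo(self, pairs):
        df = pd.DataFrame(pairs, columns=["primaryid", "caseid"]).astype(str)
        df["fda_date"] = pd.NaT
        return df

    def test_largest_primaryid_retained(self):
        out = deduplicate(self._demo([("100", "A"), ("101", "A")]))
        assert list(out["primaryid"]) == ["101"]

    def test_single_record_unchanged(self):
        out = deduplicate(self._demo([("7", "A")]))
        assert list(out["primaryid"]) == ["7"]

    def test_hand_enumerated_retention(self):
        out = deduplicate(self._demo([("1", "A"), ("2", "B"), ("3", "A"), ("4", "C")]))
        assert dict(zip(out["caseid"], out["primaryid"])) == {"A": "3", "B": "2", "C": "4"}

    def test_numeric_not_lexicographic_ordering(self):
        out = deduplicate(self._demo([("9", "A"), ("10", "A")]))
        assert list(out["primaryid"]) == ["10"]

    def test_duplicate_primaryid_raises(self):
        with pytest.raises(IntegrityError, match="primaryid"):
            deduplicate(self._demo([("1", "A"), ("1", "B")]))

    @settings(max_examples=40, deadline=None)
    @given(
        n_cases=st.integers(min_value=1, max_value=30),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_idempotent_and_counts_cases(self, n_cases, seed):
        demo = random_demo(np.random.default_rng(seed), n_cases)
        once = deduplicate(demo)
        assert len(once) == demo["caseid"].nunique()
        pd.testing.assert_frame_equal(deduplicate(once), once)

    @settings(max_examples=25, deadline=None)
    @given(
        n_cases=st.integers(min_value=1, max_value=20),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_row_order_invariance(self, n_cases, seed):
        rng = np.random.default_rng(seed)
        demo = random_demo(rng, n_cases)
        shuffled = demo.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(deduplicate(demo), deduplicate(shuffled))


def test_dedup_keeps_last_version_of_generated_cases(small_tables):
    """On generator output, retention must pick each case's final version."""
    demo = small_tables.demo
    out = deduplicate(demo)
    expect = demo.loc[demo["primaryid"].astype(int).groupby(demo["caseid"]).idxmax()]
    assert set(out["primaryid"]) == set(expect["primaryid"])
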