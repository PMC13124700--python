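"""Disproportionality statistics: frozen worked examples and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from pvdispro.errors import ConfigError, IntegrityError
from pvdispro.signals import (
    ContingencyTable,
    Disproportionality,
    bcpnn,
    chi2_stat,
    evaluate_signals,
    prr,
    ror,
    signal_table,
    stratified_signals,
)

cells = st.integers(min_value=1, max_value=5000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


class TestRor:
    def test_balanced_table(self):
        est, lo, hi = ror(ContingencyTable(5, 5, 5, 5))
        assert est == pytest.approx(1.0)
        assert lo == pytest.approx(0.1732, abs=1e-4)
        assert hi == pytest.approx(5.7723, abs=1e-4)

    def test_three_case_example_lower_bound_below_one(self):
        est, lo, hi = ror(ContingencyTable(3, 97, 100, 9900))
        assert est == pytest.approx(3.0619, abs=1e-4)
        assert lo == pytest.approx(0.954, abs=1e-3)
        assert hi == pytest.approx(9.823, abs=1e-3)

    def test_zero_cell_undefined_without_correction(self):
        est, lo, hi = ror(ContingencyTable(5, 0, 5, 5))
        assert math.isnan(est) and math.isnan(lo) and math.isnan(hi)

    def test_haldane_correction_defines_zero_cell(self):
        est, lo, hi = ror(ContingencyTable(5, 0, 5, 5), zero_cell="haldane")
        assert est == pytest.approx((5.5 / 0.5) / (5.5 / 5.5))
        assert lo < est < hi


class TestPrrChi2:
    def test_balanced_table(self):
        est, _, _, chi2 = prr(ContingencyTable(5, 5, 5, 5))
        assert est == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.2)  # Yates at exact independence
        assert chi2_stat(ContingencyTable(5, 5, 5, 5), "none") == pytest.approx(0.0)

    def test_three_case_example_fails_chi2_criterion(self):
        est, _, _, chi2 = prr(ContingencyTable(3, 97, 100, 9900))
        assert est == pytest.approx(3.0)
        assert chi2 == pytest.approx(2.192, abs=1e-3)

    def test_no_target_cases_gives_zero(self):
        est, lo, hi, _ = prr(ContingencyTable(0, 100, 10, 9890))
        assert est == 0.0 and math.isnan(lo)

    def test_comparator_without_events_undefined(self):
        assert math.isnan(prr(ContingencyTable(5, 95, 0, 9900)).estimate)

    def test_standard_ci_narrower_than_printed(self):
        t = ContingencyTable(30, 970, 300, 29700)
        printed = prr(t, ci="printed")
        standard = prr(t, ci="standard")
        assert printed.estimate == standard.estimate
        assert (standard.hi - standard.lo) < (printed.hi - printed.lo)


class TestBcpnn:
    @pytest.mark.parametrize(
        "table, expected_ic",
        [
            (ContingencyTable(1, 9, 9, 81), 0.0),  # exact independence
            (ContingencyTable(4, 6, 16, 74), 1.0),  # aN = 2 x margins product
            (ContingencyTable(3, 97, 100, 9900), math.log2(30300 / 10300)),
        ],
    )
    def test_point_ic(self, table, expected_ic):
        assert bcpnn(table).ic == pytest.approx(expected_ic, abs=1e-9)

    def test_posterior_defined_for_zero_a(self):
        est = bcpnn(ContingencyTable(0, 10, 10, 80))
        assert math.isnan(est.ic)
        assert not math.isnan(est.ic_e) and not math.isnan(est.ic025)
        assert est.ic025 <= est.ic_e


class TestSignalCriteria:
    def test_fewer_than_three_cases_never_ror_flags(self):
        res = Disproportionality.from_counts(2, 1, 1, 10000).fit().result
        assert res.ror > 100
        assert not res.flags["ror_signal"] and not res.flags["prr_signal"]

    def test_three_case_example_not_flagged(self):
        flags = Disproportionality.from_counts(3, 97, 100, 9900).fit().flags
        assert not flags["ror_signal"] and not flags["prr_signal"]

    def test_ic025_boundary_is_strict(self):
        res = Disproportionality.from_counts(5, 5, 5, 5).fit().result
        res.ic025 = 0.0
        assert not evaluate_signals(res)["bcpnn_signal"]

    def test_strong_association_flags_all_three(self):
        flags = Disproportionality.from_counts(50, 950, 100, 98900).fit().flags
        assert flags["ror_signal"] and flags["prr_signal"] and flags["bcpnn_signal"]
        assert flags["any_signal"]


class TestInvariants:
    @settings(max_examples=300, deadline=None)
    @given(tables)
    def test_cross_product_identity(self, t):
        est = ror(t).estimate
        assert est == pytest.approx(t.a * t.d / (t.b * t.c), rel=1e-12)

    @settings(max_examples=300, deadline=None)
    @given(tables)
    def test_ror_prr_ordering(self, t):
        r, p = ror(t).estimate, prr(t).estimate
        if r >= 1.0:
            assert r >= p * (1 - 1e-12)
        else:
            assert r <= p * (1 + 1e-12)

    @settings(max_examples=300, deadline=None)
    @given(tables)
    def test_ic_sign_matches_log_ror(self, t):
        # aN - (a+b)(a+c) = ad - bc, so IC and ln ROR share their sign
        ic = bcpnn(t).ic
        lr = math.log(ror(t).estimate)
        if abs(ic) < 1e-12 or abs(lr) < 1e-12:
            assert abs(ic) < 1e-9 and abs(lr) < 1e-9
        else:
            assert (ic > 0) == (lr > 0)

    @settings(max_examples=300, deadline=None)
    @given(tables)
    def test_intervals_bracket_estimates(self, t):
        r = ror(t)
        p = prr(t)
        assert r.lo <= r.estimate <= r.hi
        assert p.lo <= p.estimate <= p.hi
        b = bcpnn(t)
        assert b.ic025 <= b.ic_e

    @settings(max_examples=300, deadline=None)
    @given(tables)
    def test_chi2_matches_expected_count_oracle(self, t):
        obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        yates_oracle = (((np.abs(obs - exp) - 0.5) ** 2) / exp).sum()
        assert chi2_stat(t, "yates") == pytest.approx(yates_oracle, abs=1e-9, rel=1e-9)
        scipy_plain = chi2_contingency(obs, correction=False).statistic
        assert chi2_stat(t, "none") == pytest.approx(scipy_plain, abs=1e-9, rel=1e-9)

    def test_large_count_limit(self):
        base = ContingencyTable(4, 6, 16, 74)
        widths, gaps = [], []
        for k in (1, 10, 100, 1000, 10000):
            t = ContingencyTable(4 * k, 6 * k, 16 * k, 74 * k)
            r = ror(t)
            b = bcpnn(t)
            widths.append(math.log(r.hi / r.lo))
            gaps.append(abs(b.ic - b.ic025))
        assert all(w2 < w1 for w1, w2 in zip(widths, widths[1:]))
        assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.05 and widths[-1] < 0.05


class TestStratified:
    def _frame(self):
        import pandas as pd

        n = 400
        rng = np.random.default_rng(5)
        return pd.DataFrame(
            {
                "sex": rng.choice(["F", "M"], n),
                "event": rng.random(n) < 0.3,
                "ps_DRUGX": rng.random(n) < 0.4,
                "fda_int": 20200101,
            }
        )

    def test_preset_strata_partition(self):
        frame = self._frame()
        tab = stratified_signals(frame, "DRUGX", "sex")
        assert sorted(tab["stratum"]) == ["F", "M"]
        assert tab["n"].sum() == len(frame)

    def test_overlapping_custom_strata_rejected(self):
        frame = self._frame()
        masks = {"all": frame["sex"].notna(), "female": frame["sex"] == "F"}
        with pytest.raises(ConfigError, match="overlap"):
            stratified_signals(frame, "DRUGX", masks)

    def test_zero_exposed_stratum_non_evaluable(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "sex": ["F"] * 5 + ["M"] * 5,
                "event": [True, False] * 5,
                "ps_DRUGX": [True, False, True, False, True] + [False] * 5,
                "fda_int": 20200101,
            }
        )
        tab = stratified_signals(frame, "DRUGX", "sex").set_index("stratum")
        assert not tab.loc["M", "evaluable"]
        assert math.isnan(tab.loc["M", "ror"])


def test_contingency_cell_validation():
    with pytest.raises(IntegrityError):
        ContingencyTable(-1, 2, 3, 4)


def test_signal_table_one_row_per_drug():
    import pandas as pd

    frame = pd.DataFrame(
        {
            "event": [True, False, True, False],
            "ps_A": [True, True, False, False],
            "ps_B": [False, False, True, True],
            "fda_int": 20200101,
        }
    )
    tab = signal_table(frame, ["A", "B"])
    assert list(tab["drug"]) == ["A", "B"]
    assert tab.loc[0, ["a", "b", "c", "d"]].tolist() == [1, 1, 1, 1]
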