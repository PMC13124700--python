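"""Disproportionality statistics for spontaneous-report signal detection.

Implements the three classical measures computed from a 2x2 contingency
table of a drug-event pair against the rest of a reporting database:

* ROR  — reporting odds ratio (a/b)/(c/d) with a Wald 95% CI on the log
  scale, ``exp(ln ROR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``.
* PRR  — proportional reporting ratio (a/(a+b))/(c/(c+d)) with its log-scale
  CI, accompanied by the Pearson chi-squared statistic (Yates-corrected by
  default, as conventional for the PRR>=2 / chi2>=4 / n>=3 rule).
* BCPNN information component IC = log2(aN / ((a+b)(a+c))) with the
  closed-form Bayesian posterior moments of Bate et al. (1998) and the
  lower bound IC025 = E(IC) - 2 sqrt(V(IC)).

Signal criteria (each evaluated independently):

* ROR signal:   a >= 3 and lower 95% bound > 1
* PRR signal:   a >= 3 and PRR >= 2 and chi2 >= 4
* BCPNN signal: IC025 > 0

The module exposes a statsmodels-style pair — :class:`Disproportionality`
(the model, built from counts or from a report-level analysis frame) and
:class:`DisproportionalityResults` (estimates, intervals, flags and a
``summary()`` table) — plus stratified (subgroup) analysis helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError

__all__ = [
    "ContingencyTable",
    "Disproportionality",
    "DisproportionalityResults",
    "ror",
    "prr",
    "chi2_stat",
    "bcpnn",
    "evaluate_signals",
    "signal_table",
    "stratified_signals",
]

Z95 = 1.96  # the CI formulas are printed with 1.96, not the exact quantile
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair.

    a: target drug (primary suspect) & target event
    b: target drug, other events
    c: other drugs, target event
    d: other drugs, other events
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise IntegrityError(f"contingency cell {name}={v!r} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_flags(cls, exposed: np.ndarray, event: np.ndarray) -> "ContingencyTable":
        exposed = np.asarray(exposed, dtype=bool)
        event = np.asarray(event, dtype=bool)
        if exposed.shape != event.shape:
            raise IntegrityError("exposed/event flag vectors differ in length")
        a = int(np.sum(exposed & event))
        b = int(np.sum(exposed & ~event))
        c = int(np.sum(~exposed & event))
        d = int(np.sum(~exposed & ~event))
        return cls(a, b, c, d)

    def corrected(self) -> "tuple[float, float, float, float]":
        """Haldane–Anscombe +0.5 on every cell (only applied when requested)."""
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


class RorEstimate(NamedTuple):
    estimate: float
    lo: float
    hi: float


class PrrEstimate(NamedTuple):
    estimate: float
    lo: float
    hi: float
    chi2: float


class BcpnnEstimate(NamedTuple):
    ic: float
    ic_e: float
    ic_v: float
    ic025: float


def _cells(t: ContingencyTable, zero_cell: str) -> tuple[float, float, float, float, bool]:
    """Return working cells and whether a zero-cell correction was applied."""
    if zero_cell not in ("none", "haldane"):
        raise ConfigError(f"unknown zero_cell correction {zero_cell!r}")
    if zero_cell == "haldane" and 0 in (t.a, t.b, t.c, t.d):
        return (*t.corrected(), True)
    return (float(t.a), float(t.b), float(t.c), float(t.d), False)


def ror(t: ContingencyTable, zero_cell: str = "none") -> RorEstimate:
    """Reporting odds ratio with log-scale Wald 95% CI.

    Undefined (NaN) when any cell is zero and no correction is requested.
    """
    a, b, c, d, _ = _cells(t, zero_cell)
    if min(a, b, c, d) <= 0:
        return RorEstimate(math.nan, math.nan, math.nan)
    est = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorEstimate(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se))


def chi2_stat(t: ContingencyTable, correction: str = "yates") -> float:
    """Pearson chi-squared on the 2x2 table.

    ``correction="yates"`` applies the continuity correction in its
    classical shortcut form N(|ad-bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d));
    ``"none"`` gives the plain Pearson statistic. NaN if a margin is zero.
    """
    if correction not in ("yates", "none"):
        raise ConfigError(f"unknown chi2 correction {correction!r}")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    cross = a * d - b * c
    if correction == "yates":
        return n * (abs(cross) - n / 2.0) ** 2 / denom
    return n * cross**2 / denom


def prr(
    t: ContingencyTable,
    zero_cell: str = "none",
    chi2_correction: str = "yates",
    ci: str = "printed",
) -> PrrEstimate:
    """Proportional reporting ratio, 95% CI and chi-squared.

    ``ci="printed"`` uses se = sqrt(1/a + 1/(a+b) + 1/c + 1/(c+d)) — the
    form this analysis convention prints; ``ci="standard"`` uses the usual
    delta-method variance 1/a - 1/(a+b) + 1/c - 1/(c+d).

    PRR is 0 when a=0 (with a defined denominator) and undefined when the
    comparator has no events (c=0) under ``zero_cell="none"``.
    """
    if ci not in ("printed", "standard"):
        raise ConfigError(f"unknown PRR ci variant {ci!r}")
    chi2 = chi2_stat(t, chi2_correction)
    a, b, c, d, _ = _cells(t, zero_cell)
    if a + b <= 0 or c + d <= 0 or c <= 0:
        return PrrEstimate(math.nan, math.nan, math.nan, chi2)
    est = (a / (a + b)) / (c / (c + d))
    if a <= 0:
        return PrrEstimate(0.0, math.nan, math.nan, chi2)
    if ci == "printed":
        se2 = 1 / a + 1 / (a + b) + 1 / c + 1 / (c + d)
    else:
        se2 = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(se2)
    return PrrEstimate(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), chi2)


def bcpnn(t: ContingencyTable) -> BcpnnEstimate:
    """Information component with closed-form Bayesian posterior moments.

    Point IC = log2(aN / ((a+b)(a+c))) (NaN when a=0 or a margin is empty).
    E(IC) and V(IC) follow the Bate et al. (1998) closed form with priors
    alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1 and
    gamma = gamma11 (N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1)), which
    remain defined even for empty cells; IC025 = E(IC) - 2 sqrt(V(IC)).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    if n <= 0:
        return BcpnnEstimate(math.nan, math.nan, math.nan, math.nan)
    ab, ac = a + b, a + c
    ic = math.log2(a * n / (ab * ac)) if a > 0 and ab > 0 and ac > 0 else math.nan

    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    g = g11 * (n + al) * (n + be) / ((ab + a1) * (ac + b1))
    ic_e = math.log2((a + g11) * (n + al) * (n + be) / ((n + g) * (ab + a1) * (ac + b1)))
    ic_v = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - ab + al - a1) / ((ab + a1) * (1 + n + al))
        + (n - ac + be - b1) / ((ac + b1) * (1 + n + be))
    ) / (LN2**2)
    return BcpnnEstimate(ic, ic_e, ic_v, ic_e - 2.0 * math.sqrt(ic_v))


# --------------------------------------------------------------------------
# result container + signal criteria


@dataclass
class SignalResult:
    a: int
    b: int
    c: int
    d: int
    n: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    ic_e: float
    ic_v: float
    ic025: float
    flags: dict[str, bool] = field(default_factory=dict)
    defined: dict[str, bool] = field(default_factory=dict)

    def as_dict(self) -> dict[str, object]:
        out: dict[str, object] = {
            k: getattr(self, k)
            for k in (
                "a", "b", "c", "d", "n",
                "ror", "ror_lo", "ror_hi",
                "prr", "prr_lo", "prr_hi", "chi2",
                "ic", "ic_e", "ic_v", "ic025",
            )
        }
        out.update(self.flags)
        return out


def evaluate_signals(r: SignalResult) -> dict[str, bool]:
    """Apply the three signal criteria; NaN statistics never flag."""
    ror_signal = bool(r.a >= 3 and r.ror_lo == r.ror_lo and r.ror_lo > 1.0)
    prr_signal = bool(
        r.a >= 3
        and r.prr == r.prr
        and r.prr >= 2.0
        and r.chi2 == r.chi2
        and r.chi2 >= 4.0
    )
    bcpnn_signal = bool(r.ic025 == r.ic025 and r.ic025 > 0.0)
    return {
        "ror_signal": ror_signal,
        "prr_signal": prr_signal,
        "bcpnn_signal": bcpnn_signal,
        "any_signal": ror_signal or prr_signal or bcpnn_signal,
    }


class Disproportionality:
    """Disproportionality model for one drug-event 2x2 table.

    Parameters
    ----------
    table
        The a/b/c/d counts.
    zero_cell
        "none" (default: statistics involving an empty cell are undefined
        and flagged) or "haldane" (+0.5 on every cell when any is zero).
    chi2_correction
        "yates" (default) or "none".
    prr_ci
        "printed" (default) or "standard"; see :func:`prr`.
    """

    def __init__(
        self,
        table: ContingencyTable,
        *,
        zero_cell: str = "none",
        chi2_correction: str = "yates",
        prr_ci: str = "printed",
    ) -> None:
        self.table = table
        self.zero_cell = zero_cell
        self.chi2_correction = chi2_correction
        self.prr_ci = prr_ci

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int, **kwargs) -> "Disproportionality":
        return cls(ContingencyTable(a, b, c, d), **kwargs)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        drug: str,
        *,
        approval_date: int | None = None,
        **kwargs,
    ) -> "Disproportionality":
        """Build from a report-level analysis frame (see cohort module).

        The frame carries one row per deduplicated report with a boolean
        ``event`` column and per-drug primary-suspect flag columns; with
        ``approval_date`` the whole 2x2 universe is restricted to reports
        received on or after that date (drug-specific reporting period).
        """
        from .cohort import contingency  # local import to avoid a cycle

        return cls(contingency(frame, drug, approval_date=approval_date), **kwargs)

    def fit(self) -> "DisproportionalityResults":
        t = self.table
        r = ror(t, self.zero_cell)
        p = prr(t, self.zero_cell, self.chi2_correction, self.prr_ci)
        ic = bcpnn(t)
        res = SignalResult(
            a=t.a, b=t.b, c=t.c, d=t.d, n=t.n,
            ror=r.estimate, ror_lo=r.lo, ror_hi=r.hi,
            prr=p.estimate, prr_lo=p.lo, prr_hi=p.hi, chi2=p.chi2,
            ic=ic.ic, ic_e=ic.ic_e, ic_v=ic.ic_v, ic025=ic.ic025,
        )
        res.defined = {
            "ror": r.estimate == r.estimate,
            "prr": p.estimate == p.estimate,
            "chi2": p.chi2 == p.chi2,
            "ic": ic.ic == ic.ic,
            "ic025": ic.ic025 == ic.ic025,
        }
        res.flags = evaluate_signals(res)
        return DisproportionalityResults(self, res)


class DisproportionalityResults:
    """Fitted estimates, intervals and signal flags for one 2x2 table."""

    def __init__(self, model: Disproportionality, result: SignalResult) -> None:
        self.model = model
        self._r = result

    def __getattr__(self, name: str):
        try:
            return getattr(self.__dict__["_r"], name)
        except AttributeError:  # pragma: no cover
            raise AttributeError(name) from None

    @property
    def result(self) -> SignalResult:
        return self._r

    def as_series(self) -> pd.Series:
        return pd.Series(self._r.as_dict())

    def summary(self) -> str:
        r = self._r

        def fmt(x: float) -> str:
            return "   --" if x != x else f"{x:8.4f}"

        lines = [
            "Disproportionality analysis (2x2 spontaneous-report table)",
            "=" * 62,
            f"  a={r.a}  b={r.b}  c={r.c}  d={r.d}   N={r.n}",
            "-" * 62,
            f"  ROR   {fmt(r.ror)}   95% CI [{fmt(r.ror_lo)}, {fmt(r.ror_hi)}]"
            f"   signal={r.flags['ror_signal']}",
            f"  PRR   {fmt(r.prr)}   95% CI [{fmt(r.prr_lo)}, {fmt(r.prr_hi)}]"
            f"   chi2={fmt(r.chi2)}   signal={r.flags['prr_signal']}",
            f"  IC    {fmt(r.ic)}   E(IC)={fmt(r.ic_e)}   IC025={fmt(r.ic025)}"
            f"   signal={r.flags['bcpnn_signal']}",
            "-" * 62,
            f"  any criterion met: {r.flags['any_signal']}",
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# multi-drug and stratified analyses


def signal_table(
    frame: pd.DataFrame,
    drugs: Iterable[str],
    approval_dates: Mapping[str, int] | None = None,
    **model_kwargs,
) -> pd.DataFrame:
    """One fitted SignalResult row per drug from a report-level frame."""
    rows = []
    for drug in drugs:
        approval = (approval_dates or {}).get(drug)
        res = Disproportionality.from_frame(
            frame, drug, approval_date=approval, **model_kwargs
        ).fit()
        rows.append({"drug": drug, **res.result.as_dict()})
    return pd.DataFrame(rows)


_PRESET_STRATA = {
    "age": "age_band",
    "sex": "sex",
    "reporter": "reporter_group",
}


def _strata_masks(frame: pd.DataFrame, strata) -> dict[str, pd.Series]:
    if isinstance(strata, str):
        try:
            col = _PRESET_STRATA[strata]
        except KeyError:
            raise ConfigError(
                f"unknown strata preset {strata!r}; use one of {sorted(_PRESET_STRATA)}"
            ) from None
        labels = frame[col].astype(str)
        return {lev: labels == lev for lev in sorted(labels.unique())}
    masks = {k: pd.Series(np.asarray(v, dtype=bool), index=frame.index) for k, v in strata.items()}
    total = sum(m.astype(int) for m in masks.values())
    if (total > 1).any():
        raise ConfigError("strata overlap: some reports fall in more than one stratum")
    return masks


def stratified_signals(
    frame: pd.DataFrame,
    drug: str,
    strata="sex",
    approval_date: int | None = None,
    **model_kwargs,
) -> pd.DataFrame:
    """Subgroup disproportionality: each stratum is its own 2x2 universe.

    ``strata`` is a preset name ("age", "sex", "reporter") or a mapping of
    stratum label -> boolean mask over the frame (must be disjoint). Both
    the exposed and the comparator reports come from the same stratum.
    Strata with fewer than 3 exposed-event cases are reported but marked
    non-evaluable for the case-count-gated ROR/PRR criteria.
    """
    masks = _strata_masks(frame, strata)
    rows = []
    for label, mask in masks.items():
        sub = frame[mask]
        res = Disproportionality.from_frame(
            sub, drug, approval_date=approval_date, **model_kwargs
        ).fit()
        rows.append(
            {
                "drug": drug,
                "stratum": label,
                "n_stratum": int(len(sub)),
                "evaluable": bool(res.result.a >= 3),
                **res.result.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def forest_table(signal_df: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (drug, ror, lo, hi, n-cases) slice of a signal table."""
    cols = [c for c in ("drug", "stratum") if c in signal_df.columns]
    out = signal_df[cols + ["ror", "ror_lo", "ror_hi", "a"]].copy()
    return out.rename(columns={"ror_lo": "lo", "ror_hi": "hi", "a": "n"})
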