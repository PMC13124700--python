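"""Shared helpers: rounding conventions and FAERS date handling."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round `x` half-up to `ndigits` decimals.

    Spontaneous-report summary tables conventionally round .5 away from
    zero (22.95 -> 23.0); Python's built-in round() is banker's rounding
    and would give 22.9 there, so percentages go through this helper.
    """
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 1) -> float:
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * count / total, ndigits)


def parse_yyyymmdd(values: pd.Series) -> tuple[pd.Series, pd.Series, int]:
    """Parse YYYYMMDD date strings.

    Returns (dates, years, n_partial): `dates` is datetime64 with NaT for
    missing/partial/invalid entries; `years` is a nullable-integer series
    populated from any >=4-digit prefix (so a year-only entry like "2023"
    still contributes a report year); `n_partial` counts entries that had
    digits but fewer than 8 of them.
    """
    s = values.fillna("").astype(str).str.strip()
    digits = s.str.fullmatch(r"\d+")
    full = digits & (s.str.len() == 8)
    partial = digits & (s.str.len() >= 4) & (s.str.len() < 8)
    dates = pd.to_datetime(s.where(full, ""), format="%Y%m%d", errors="coerce")
    years = pd.Series(pd.NA, index=s.index, dtype="Int64")
    has_year = full | partial
    years[has_year] = s[has_year].str[:4].astype(int)
    # 8-digit but calendar-invalid (e.g. 20231340) also parses to NaT above
    n_partial = int(partial.sum())
    return dates, years, n_partial


def to_yyyymmdd(dates: pd.Series) -> pd.Series:
    """Render datetime64 values back to YYYYMMDD strings (blank for NaT)."""
    out = dates.dt.strftime("%Y%m%d")
    return out.fillna("").astype(str)


def quota_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of `n` items over categories.

    Used where a small sample must realise a categorical distribution
    exactly (e.g. 7 of 9 cases in one age band) rather than in expectation.
    """
    probs = np.asarray(probs, dtype=float)
    raw = probs * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base
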