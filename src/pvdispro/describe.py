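"""Descriptive cohort summaries (counts and percentages per characteristic).

Reproduces the conventional clinical-characteristics table of a
spontaneous-report cohort: counts and percentages by drug, sex, age band
(<18, 18-44, 45-64, >=65), weight band (<80, >=80 kg), reporter
occupation, reporter region and outcome. Missing values are a first-class
"NS" level in every characteristic, never silently dropped. Percentages
are 100*count/total rounded half-up to one decimal (the convention of
such tables: 42/183 = 22.95 prints as 23.0).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from ._util import percent
from .errors import ConfigError

__all__ = ["profile", "profile_from_counts", "yearly_counts", "render_profile"]

_CHARACTERISTICS = {
    "drug": ("drug", None),
    "sex": ("sex", ("F", "M", "NS")),
    "age": ("age_band", ("<18", "18-44", "45-64", ">=65", "NS")),
    "weight": ("weight_band", ("<80", ">=80", "NS")),
    "occupation": ("occp_cod", ("CN", "MD", "NS", "OT", "PH")),
    "region": ("region", None),
    "outcome": ("outc_cod", ("DE", "HO", "NS", "OT")),
}


def profile(cohort: pd.DataFrame, characteristics: Mapping[str, tuple] | None = None) -> pd.DataFrame:
    """Long-format summary: (characteristic, level, count, percent).

    Every characteristic's counts sum to the cohort size; its percents
    sum to 100 within rounding slack. Raises on an empty cohort.
    """
    if len(cohort) == 0:
        raise ConfigError("cannot profile an empty cohort")
    chars = characteristics or _CHARACTERISTICS
    total = len(cohort)
    rows = []
    for name, (col, levels) in chars.items():
        if col not in cohort.columns:
            continue
        values = cohort[col].fillna("NS").astype(str)
        counts = values.value_counts()
        order = list(levels) if levels else sorted(counts.index)
        for lev in order:
            n = int(counts.get(lev, 0))
            if levels is None and n == 0:
                continue
            rows.append(
                {"characteristic": name, "level": lev, "count": n, "percent": percent(n, total)}
            )
    return pd.DataFrame(rows)


def profile_from_counts(counts: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Summary table straight from per-level counts.

    Same output contract as :func:`profile`, for the case where only a
    published count breakdown (not row-level data) is available.
    """
    rows = []
    for name, levels in counts.items():
        total = sum(levels.values())
        if total == 0:
            raise ConfigError(f"characteristic {name!r} has zero total")
        for lev, n in levels.items():
            rows.append(
                {"characteristic": name, "level": str(lev), "count": int(n), "percent": percent(n, total)}
            )
    return pd.DataFrame(rows)


def yearly_counts(cohort: pd.DataFrame) -> pd.Series:
    """Report counts per calendar year, dense (zero-filled) over the span.

    Reports without a usable year are counted under the "NS" key, kept
    apart from the dense integer range.
    """
    years = cohort["report_year"]
    known = years.dropna().astype(int)
    if len(known):
        full = range(int(known.min()), int(known.max()) + 1)
        counts = known.value_counts().reindex(full, fill_value=0).sort_index()
    else:
        counts = pd.Series(dtype=int)
    n_missing = int(years.isna().sum())
    if n_missing:
        counts = pd.concat([counts, pd.Series({"NS": n_missing})])
    counts.name = "count"
    return counts


def render_profile(table: pd.DataFrame, total: int | None = None) -> str:
    """Fixed-width text rendering of a profile table."""
    lines = ["Characteristics          Level        n (%)", "-" * 46]
    if total is not None:
        lines.append(f"{'Overall':<25}{'':<13}{total}")
    for char, group in table.groupby("characteristic", sort=False):
        first = True
        for _, row in group.iterrows():
            label = char if first else ""
            first = False
            lines.append(f"{label:<25}{row['level']:<13}{row['count']} ({row['percent']:.1f})")
    return "\n".join(lines)
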