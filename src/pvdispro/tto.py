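"""Time-to-onset: latency from therapy start to event onset, binned.

Latency is the day count from the suspect drug's (earliest) therapy start
to the event onset date. Only reports where both dates are present at
full day precision contribute; partial dates, missing dates and negative
differences are excluded and counted in an exclusion log — the
denominator for percentages is the records with computable latency.

Bins are closed on integer days: [0,30], [31,60], [61,90], [91,359],
[360,inf). The 91-359 gap is carried as its own bin so the partition is
total and percentages can sum to 100. "Within one month" means <=30 days;
"after one year" means >=360 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import ConfigError

__all__ = ["BIN_LABELS", "assign_bin", "compute_latency", "tto_summary", "cumulative_curve"]

BIN_EDGES = (30, 60, 90, 359)
BIN_LABELS = ("0-30", "31-60", "61-90", "91-359", ">=360")


def assign_bin(latency_days: int) -> str:
    """Total on non-negative integers; raises on negative input."""
    if latency_days < 0:
        raise ValueError(f"latency must be non-negative, got {latency_days}")
    for edge, label in zip(BIN_EDGES, BIN_LABELS):
        if latency_days <= edge:
            return label
    return BIN_LABELS[-1]


@dataclass
class ExclusionLog:
    missing_start: int = 0
    missing_event: int = 0
    negative: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.missing_start + self.missing_event + self.negative


def compute_latency(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Latency records for every cohort row with usable dates.

    Returns (records, exclusions); records carry primaryid, drug,
    latency_days and the assigned bin.
    """
    log = ExclusionLog()
    start = cohort["start_date"]
    event = cohort["event_date"]
    log.missing_start = int(start.isna().sum())
    log.missing_event = int((start.notna() & event.isna()).sum())
    usable = start.notna() & event.notna()
    days = (event[usable] - start[usable]).dt.days
    negative = days < 0
    log.negative = int(negative.sum())
    keep = days[~negative]
    records = cohort.loc[keep.index, ["primaryid", "drug"]].copy()
    records["latency_days"] = keep.astype(int)
    records["bin"] = [assign_bin(d) for d in records["latency_days"]]
    return records.reset_index(drop=True), log


def tto_summary(records: pd.DataFrame, drug: str | None = None) -> pd.DataFrame:
    """Per-bin counts, percents (2 decimals, half-up) and cumulative curve.

    Cumulative percents are recomputed from the exact cumulative counts,
    so the curve is non-decreasing and ends at exactly 100.00.
    """
    sub = records if drug is None else records[records["drug"] == drug]
    if len(sub) == 0:
        raise ConfigError(f"no latency records{'' if drug is None else f' for {drug!r}'}")
    total = len(sub)
    counts = sub["bin"].value_counts().reindex(BIN_LABELS, fill_value=0)
    cum = counts.cumsum()
    return pd.DataFrame(
        {
            "bin": BIN_LABELS,
            "count": counts.to_numpy(),
            "percent": [round_half_up(100.0 * c / total, 2) for c in counts],
            "cumulative_percent": [round_half_up(100.0 * c / total, 2) for c in cum],
        }
    )


def cumulative_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Per-drug cumulative onset table (plot-ready, one row per drug x bin)."""
    frames = []
    for drug in sorted(records["drug"].unique()):
        tab = tto_summary(records, drug)
        tab.insert(0, "drug", drug)
        tab["n_total"] = int((records["drug"] == drug).sum())
        frames.append(tab)
    if not frames:
        raise ConfigError("no latency records at all")
    return pd.concat(frames, ignore_index=True)


def median_latency(records: pd.DataFrame) -> tuple[float, int, int]:
    """(median, min, max) of latency days (mean-of-central-two for even n)."""
    days = records["latency_days"].to_numpy()
    if len(days) == 0:
        raise ConfigError("no latency records")
    return float(np.median(days)), int(days.min()), int(days.max())
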