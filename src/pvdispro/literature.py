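"""Literature-case summaries and FAERS-vs-literature concordance.

Published single-case reports of the drug-event pair are summarised on
the same dimensions as the spontaneous-report cohort — drug mix, elderly
share, female share, hospitalization rate, latency median and range — and
the two sources are compared dimension by dimension with absolute
differences. No inferential test is applied: concordance here is a
descriptive coherence check, with a configurable flagging threshold
(default 25 percentage points) for dimensions where the sources diverge.

The bundled 9-case table (``literature_cases_synthetic.csv``) is a
synthetic stand-in constructed to match the marginal summaries of the
published case series for quinolone-associated pemphigoid; it is not the
original supplementary case listing.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import ConfigError, FormatError

__all__ = [
    "load_literature_cases",
    "summarize_literature",
    "faers_summary",
    "concordance",
    "TOP_DRUGS",
]

# the three agents dominating both sources; "drug mix" concordance is
# their combined share
TOP_DRUGS = ("CIPROFLOXACIN", "LEVOFLOXACIN", "OFLOXACIN")

REQUIRED_COLUMNS = ("drug", "age_years", "sex", "latency_days", "hospitalized", "outcome")

DIMENSIONS = (
    "top3_drug_share_percent",
    "elderly_percent",
    "young_percent",
    "female_percent",
    "hospitalized_percent",
    "latency_median_days",
    "latency_min_days",
    "latency_max_days",
)


def load_literature_cases(path: str | Path | None = None) -> pd.DataFrame:
    """Load a literature case table (bundled synthetic fixture by default)."""
    if path is None:
        ref = resources.files("pvdispro.data") / "literature_cases_synthetic.csv"
        with resources.as_file(ref) as p:
            cases = pd.read_csv(p)
    else:
        cases = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in cases.columns]
    if missing:
        raise FormatError(f"literature table lacks columns: {missing}")
    if len(cases) == 0:
        raise ConfigError("literature table is empty")
    if (cases["latency_days"] < 1).any():
        raise ConfigError("latency_days must be >= 1 for every case")
    if (cases["age_years"] <= 0).any():
        raise ConfigError("age_years must be positive for every case")
    cases["hospitalized"] = cases["hospitalized"].astype(bool)
    return cases


def summarize_literature(cases: pd.DataFrame) -> dict[str, float]:
    """Dimension summary of a literature case table.

    Percentages are rounded half-up to one decimal; the median for an
    even case count is the mean of the two central values.
    """
    if len(cases) == 0:
        raise ConfigError("cannot summarize an empty case table")
    n = len(cases)
    drugs = cases["drug"].astype(str).str.upper()
    lat = cases["latency_days"].to_numpy()
    return {
        "top3_drug_share_percent": round_half_up(100.0 * drugs.isin(TOP_DRUGS).sum() / n),
        "elderly_percent": round_half_up(100.0 * (cases["age_years"] >= 65).sum() / n),
        "young_percent": round_half_up(100.0 * (cases["age_years"] < 45).sum() / n),
        "female_percent": round_half_up(100.0 * (cases["sex"].astype(str).str.upper() == "F").sum() / n),
        "hospitalized_percent": round_half_up(100.0 * cases["hospitalized"].sum() / n),
        "latency_median_days": float(np.median(lat)),
        "latency_min_days": float(lat.min()),
        "latency_max_days": float(lat.max()),
    }


def faers_summary(cohort: pd.DataFrame, latency_records: pd.DataFrame) -> dict[str, float]:
    """The same dimension summary computed from the reporting cohort.

    Shares use the full cohort (NS included in the denominator, matching
    how such tables are reported); latency uses the records with
    computable onset times.
    """
    if len(cohort) == 0:
        raise ConfigError("cannot summarize an empty cohort")
    n = len(cohort)
    lat = latency_records["latency_days"].to_numpy()
    if len(lat) == 0:
        raise ConfigError("no latency records for the FAERS summary")
    return {
        "top3_drug_share_percent": round_half_up(
            100.0 * cohort["drug"].isin(TOP_DRUGS).sum() / n
        ),
        "elderly_percent": round_half_up(100.0 * (cohort["age_band"] == ">=65").sum() / n),
        "young_percent": round_half_up(
            100.0 * cohort["age_band"].isin(("<18", "18-44")).sum() / n
        ),
        "female_percent": round_half_up(100.0 * (cohort["sex"] == "F").sum() / n),
        "hospitalized_percent": round_half_up(100.0 * (cohort["outc_cod"] == "HO").sum() / n),
        "latency_median_days": float(np.median(lat)),
        "latency_min_days": float(lat.min()),
        "latency_max_days": float(lat.max()),
    }


def concordance(
    lit_summary: dict[str, float],
    faers_summary: dict[str, float],
    threshold: float = 25.0,
) -> pd.DataFrame:
    """Dimension-by-dimension comparison with absolute differences.

    Percentage dimensions diverging by more than ``threshold`` points are
    flagged as incoherent; latency dimensions are reported unflagged
    (days and percentage points are not comparable units).
    """
    missing = [k for k in DIMENSIONS if k not in lit_summary or k not in faers_summary]
    if missing:
        raise ConfigError(f"summaries lack dimensions: {missing}")
    rows = []
    for dim in DIMENSIONS:
        lit, fae = float(lit_summary[dim]), float(faers_summary[dim])
        diff = abs(lit - fae)
        is_pct = dim.endswith("percent")
        rows.append(
            {
                "dimension": dim,
                "literature": lit,
                "faers": fae,
                "abs_difference": diff,
                "flagged": bool(is_pct and diff > threshold),
            }
        )
    return pd.DataFrame(rows)
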