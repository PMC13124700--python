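"""Cohort construction: drug standardization, event matching, 2x2 counts.

Builds the analysis universe from deduplicated quarterly tables: verbatim
drug names are standardized against a configurable synonym dictionary
(exact match, case- and whitespace-insensitive — no fuzzy matching, no
licensed dictionary content), the target event is a configurable set of
preferred terms (default {"Pemphigoid"}), and each study drug's 2x2
universe is restricted to reports received on or after that drug's
approval date (drug-specific reporting period, applied to exposed and
comparator reports alike).

The comparator for drug D is every in-window report that does not list D
as a primary suspect. A report listing several study drugs as primary
suspects enters each drug's own cohort, but contributes exactly once to
any single 2x2 table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, IntegrityError
from .ingest import NormalizedTables
from .signals import ContingencyTable

__all__ = [
    "DrugDictionary",
    "EventTermSet",
    "standardize_drug",
    "build_analysis_frame",
    "build_cohort",
    "contingency",
    "default_drug_dictionary",
    "default_event_terms",
]

AGE_BANDS = ("<18", "18-44", "45-64", ">=65", "NS")
WEIGHT_BANDS = ("<80", ">=80", "NS")


def _norm_name(name: str) -> str:
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


@dataclass(frozen=True)
class DrugDictEntry:
    canonical: str
    synonyms: tuple[str, ...]
    approval_date: int
    include: bool = True


class DrugDictionary:
    """Canonical drug names, their synonyms and approval dates.

    Synonym sets must be disjoint across canonical names (a verbatim name
    that mapped to two drugs would be ambiguous).
    """

    def __init__(self, entries: Iterable[DrugDictEntry]):
        self.entries: dict[str, DrugDictEntry] = {}
        self._lookup: dict[str, str] = {}
        for e in entries:
            if e.canonical in self.entries:
                raise ConfigError(f"duplicate canonical drug {e.canonical!r}")
            self.entries[e.canonical] = e
            for name in (e.canonical, *e.synonyms):
                key = _norm_name(name)
                owner = self._lookup.get(key)
                if owner is not None and owner != e.canonical:
                    raise ConfigError(
                        f"synonym {name!r} maps to both {owner!r} and {e.canonical!r}"
                    )
                self._lookup[key] = e.canonical
        if not self.entries:
            raise ConfigError("drug dictionary is empty")

    @property
    def included(self) -> list[str]:
        return [name for name, e in self.entries.items() if e.include]

    def approval_dates(self) -> dict[str, int]:
        return {name: e.approval_date for name, e in self.entries.items() if e.include}

    def lookup(self, verbatim: str) -> str | None:
        return self._lookup.get(_norm_name(verbatim))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DrugDictionary":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "DrugDictionary":
        drugs = data.get("drugs", data)
        entries = [
            DrugDictEntry(
                canonical=str(name).upper(),
                synonyms=tuple(spec.get("synonyms", ())),
                approval_date=int(spec["approval_date"]),
                include=bool(spec.get("include", True)),
            )
            for name, spec in drugs.items()
        ]
        return cls(entries)


class EventTermSet(frozenset):
    """Case-insensitive exact-match preferred terms defining the outcome."""

    def __new__(cls, terms: Iterable[str]):
        normed = frozenset(_norm_name(t) for t in terms if str(t).strip())
        if not normed:
            raise ConfigError("event term set is empty")
        return super().__new__(cls, normed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EventTermSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(data.get("terms", data) if isinstance(data, Mapping) else data)


def default_drug_dictionary() -> DrugDictionary:
    with resources.as_file(resources.files("pvdispro.data") / "drug_dictionary.yaml") as p:
        return DrugDictionary.from_yaml(p)


def default_event_terms() -> EventTermSet:
    with resources.as_file(resources.files("pvdispro.data") / "event_terms.yaml") as p:
        return EventTermSet.from_yaml(p)


def standardize_drug(verbatim: str, dictionary: DrugDictionary) -> str | None:
    """Map a verbatim drug name to its canonical form; None when unmapped.

    Matching is exact after case folding and whitespace collapsing;
    unmapped names are a value (None), not an error — callers keep the
    verbatim string and flag the row.
    """
    return dictionary.lookup(verbatim)


def ps_column(drug: str) -> str:
    return "ps_" + re.sub(r"\W+", "_", drug.strip().upper())


def _age_band(age_years: pd.Series) -> pd.Series:
    bins = pd.cut(
        age_years,
        bins=[-np.inf, 17.999999, 44.999999, 64.999999, np.inf],
        labels=["<18", "18-44", "45-64", ">=65"],
    ).astype(object)
    return pd.Series(np.where(age_years.notna(), bins, "NS"), index=age_years.index)


def _weight_band(weight_kg: pd.Series) -> pd.Series:
    band = np.where(weight_kg < 80, "<80", ">=80")
    return pd.Series(np.where(weight_kg.notna(), band, "NS"), index=weight_kg.index)


def _reporter_group(occp: pd.Series) -> pd.Series:
    out = pd.Series("non-HCP", index=occp.index, dtype=object)
    out[occp.isin(("MD", "PH"))] = "HCP"
    out[occp == "NS"] = "NS"
    return out


def build_analysis_frame(
    tables: NormalizedTables,
    dictionary: DrugDictionary,
    events: EventTermSet,
) -> pd.DataFrame:
    """One row per deduplicated report, with exposure and event flags.

    Requires deduplicated input (one DEMO row per case). Adds a boolean
    ``event`` column (any reaction PT in the event set), one boolean
    primary-suspect flag column per included drug, derived demographic
    bands, and ``fda_int`` (YYYYMMDD integer) for approval windowing.
    """
    if not dictionary.included:
        raise ConfigError("drug dictionary contains no included drugs")
    demo = tables.demo
    frame = demo.copy()
    frame["age_band"] = _age_band(frame["age_years"])
    frame["weight_band"] = _weight_band(frame["weight_kg"])
    frame["reporter_group"] = _reporter_group(frame["occp_cod"])
    fda = frame["fda_date"]
    frame["fda_int"] = pd.array(
        np.where(
            fda.notna(),
            fda.dt.year.fillna(0) * 10000 + fda.dt.month.fillna(0) * 100 + fda.dt.day.fillna(0),
            np.nan,
        ),
        dtype="Int64",
    )

    event_ids = set(tables.reac.loc[tables.reac["pt_norm"].isin(events), "primaryid"])
    frame["event"] = frame["primaryid"].isin(event_ids)

    drug = tables.drug
    canon = drug["drugname"].map(lambda v: dictionary.lookup(v))
    ps = drug["role_cod"] == "PS"
    for name in dictionary.included:
        ids = set(drug.loc[ps & (canon == name), "primaryid"])
        frame[ps_column(name)] = frame["primaryid"].isin(ids)
    return frame.reset_index(drop=True)


def build_cohort(
    tables: NormalizedTables,
    dictionary: DrugDictionary,
    events: EventTermSet,
) -> pd.DataFrame:
    """Pair-level analysis cohort: one row per (report, included drug).

    A report enters drug D's cohort iff it lists D as primary suspect and
    its receipt date falls on/after D's approval date; the ``event`` flag
    marks reports with any target-event preferred term. Therapy start is
    the earliest start date among that drug's therapy episodes (first
    exposure defines induction time).
    """
    frame = build_analysis_frame(tables, dictionary, events)
    approvals = dictionary.approval_dates()

    drug = tables.drug
    canon = drug["drugname"].map(lambda v: dictionary.lookup(v))
    ps = drug[(drug["role_cod"] == "PS") & canon.notna()].copy()
    ps["drug"] = canon[ps.index]
    ps = ps[ps["drug"].isin(approvals)]

    # earliest therapy start per (report, drug): THER links via drug_seq
    ther = tables.ther.merge(
        ps[["primaryid", "drug_seq", "drug"]],
        left_on=["primaryid", "dsg_drug_seq"],
        right_on=["primaryid", "drug_seq"],
        how="inner",
    )
    starts = ther.groupby(["primaryid", "drug"], as_index=False)["start_date"].min()

    pairs = ps[["primaryid", "drug"]].drop_duplicates()
    cohort = pairs.merge(frame, on="primaryid", how="inner")
    cohort = cohort.merge(starts, on=["primaryid", "drug"], how="left")
    window = cohort["drug"].map(approvals)
    cohort = cohort[cohort["fda_int"].notna() & (cohort["fda_int"] >= window)]
    cols = [
        "primaryid", "caseid", "drug", "event",
        "fda_date", "fda_int", "report_year", "event_date", "start_date",
        "sex", "age_years", "age_band", "weight_kg", "weight_band",
        "occp_cod", "reporter_group", "region", "outc_cod",
    ]
    return cohort[cols].sort_values(["drug", "primaryid"], kind="stable").reset_index(drop=True)


def contingency(
    frame: pd.DataFrame,
    drug: str,
    approval_date: int | None = None,
) -> ContingencyTable:
    """The a/b/c/d counts for one drug from a report-level frame.

    With ``approval_date`` the whole universe (both margins) is restricted
    to reports with a known receipt date on/after it. Cells always sum to
    the universe size.
    """
    col = ps_column(drug)
    if col not in frame.columns:
        raise ConfigError(f"frame has no primary-suspect flags for drug {drug!r}")
    sub = frame
    if approval_date is not None:
        sub = frame[frame["fda_int"].notna() & (frame["fda_int"] >= int(approval_date))]
    exposed = sub[col].to_numpy(dtype=bool)
    event = sub["event"].to_numpy(dtype=bool)
    table = ContingencyTable.from_flags(exposed, event)
    if table.n != len(sub):  # pragma: no cover - conservation guard
        raise IntegrityError("contingency cells do not sum to the universe size")
    return table
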