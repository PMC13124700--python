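"""Reading FAERS-dialect quarterly files and FDA-style deduplication.

The quarterly extract is four "$"-delimited ASCII tables with one header
line: DEMO (demographics and administration), DRUG (per-report drug
mentions with role codes), REAC (reaction preferred terms) and THER
(therapy dates). This module parses them into typed frames, normalises
units and code sets (unknown/missing codes become "NS"), and applies the
FDA-recommended deduplication: reports sharing a CASEID are duplicate
versions of one case, and only the version with the largest PRIMARYID is
retained.

Dialect decisions: dates are YYYYMMDD; entries with fewer than 8 digits
are treated as missing for any day-level arithmetic (no fabricated
precision) but a >=4-digit prefix still populates the report year. Ages
are normalised to years (decades x10, months /12, days /365.25), weights
to kilograms (lbs x0.45359237). Legacy pre-2012 LAERS layouts and the XML
dialect are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import parse_yyyymmdd
from .errors import FormatError, IntegrityError

__all__ = ["NormalizedTables", "IngestReport", "read_quarter", "normalize_tables", "deduplicate"]

SEX_CODES = frozenset({"F", "M"})
OCCP_CODES = frozenset({"CN", "MD", "PH", "OT"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
# FAERS outcome codes beyond death/hospitalization collapse into "other
# serious"; anything unrecognised is NS
OUTCOME_MAP = {"DE": "DE", "HO": "HO", "LT": "OT", "DS": "OT", "CA": "OT", "RI": "OT", "OT": "OT"}

MANDATORY = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "ther": ("primaryid", "start_dt"),
}

_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "DY": 1.0 / 365.25}
_LBS_TO_KG = 0.45359237


@dataclass
class IngestReport:
    """Counters for rows/fields that could not be used as-is."""

    malformed_rows: dict[str, int] = field(default_factory=dict)
    partial_dates: dict[str, int] = field(default_factory=dict)
    unknown_units: dict[str, int] = field(default_factory=dict)
    unknown_roles: int = 0

    def total_warnings(self) -> int:
        return (
            sum(self.malformed_rows.values())
            + sum(self.partial_dates.values())
            + sum(self.unknown_units.values())
            + self.unknown_roles
        )


@dataclass
class NormalizedTables:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("demo", "drug", "reac", "ther"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)


def _read_table(path: str | Path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{name} file not found: {path}")
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in MANDATORY[name]:
        if col not in df.columns:
            raise FormatError(f"{name} file {path} is missing mandatory column {col!r}")
    return df


def read_quarter(
    demo: str | Path,
    drug: str | Path,
    reac: str | Path,
    ther: str | Path,
    strict: bool = False,
) -> tuple[NormalizedTables, IngestReport]:
    """Read one quarterly file set and normalise it.

    With ``strict=True`` any malformed row (empty primaryid, empty
    reaction term) raises instead of being counted and dropped.
    """
    raw = {
        "demo": _read_table(demo, "demo"),
        "drug": _read_table(drug, "drug"),
        "reac": _read_table(reac, "reac"),
        "ther": _read_table(ther, "ther"),
    }
    return normalize_tables(strict=strict, **raw)


def normalize_tables(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    ther: pd.DataFrame,
    strict: bool = False,
) -> tuple[NormalizedTables, IngestReport]:
    """Normalise raw string tables (from disk or from the generator)."""
    report = IngestReport()

    def get(df: pd.DataFrame, col: str) -> pd.Series:
        if col in df.columns:
            return df[col].fillna("").astype(str).str.strip()
        return pd.Series("", index=df.index, dtype=str)

    # ---- DEMO -----------------------------------------------------------
    d = pd.DataFrame(index=demo.index)
    d["primaryid"] = get(demo, "primaryid")
    d["caseid"] = get(demo, "caseid")
    bad = (d["primaryid"] == "") | (d["caseid"] == "")
    if bad.any():
        if strict:
            raise IntegrityError(f"{int(bad.sum())} demo rows lack primaryid/caseid")
        report.malformed_rows["demo"] = int(bad.sum())
        d = d[~bad]
        demo = demo[~bad]

    fda_date, fda_year, n_part = parse_yyyymmdd(get(demo, "fda_dt"))
    report.partial_dates["fda_dt"] = n_part
    ev_date, _, n_part = parse_yyyymmdd(get(demo, "event_dt"))
    report.partial_dates["event_dt"] = n_part
    d["fda_date"] = fda_date
    d["event_date"] = ev_date
    d["report_year"] = fda_year

    sex = get(demo, "sex").str.upper()
    d["sex"] = sex.where(sex.isin(SEX_CODES), "NS")

    age_val = pd.to_numeric(get(demo, "age"), errors="coerce")
    age_cod = get(demo, "age_cod").str.upper()
    factor = age_cod.map(_AGE_FACTORS)
    unknown_unit = age_val.notna() & (age_cod != "") & factor.isna()
    report.unknown_units["age_cod"] = int(unknown_unit.sum())
    factor = factor.fillna(1.0)  # blank unit defaults to years
    age_years = age_val * factor
    age_years[unknown_unit] = np.nan
    d["age_years"] = age_years

    wt_val = pd.to_numeric(get(demo, "wt"), errors="coerce")
    wt_cod = get(demo, "wt_cod").str.upper()
    kg = wt_val.where(~wt_cod.isin(("LBS", "LB")), wt_val * _LBS_TO_KG)
    unknown_wt = wt_val.notna() & ~wt_cod.isin(("", "KG", "KGS", "LBS", "LB"))
    report.unknown_units["wt_cod"] = int(unknown_wt.sum())
    kg[unknown_wt] = np.nan
    d["weight_kg"] = kg

    occp = get(demo, "occp_cod").str.upper()
    d["occp_cod"] = occp.where(occp.isin(OCCP_CODES), "NS")
    region = get(demo, "occr_country")
    d["region"] = region.where(region != "", "NS")
    outc = get(demo, "outc_cod").str.upper().map(OUTCOME_MAP)
    d["outc_cod"] = outc.fillna("NS")
    demo_n = d.reset_index(drop=True)

    # ---- DRUG -----------------------------------------------------------
    g = pd.DataFrame(index=drug.index)
    g["primaryid"] = get(drug, "primaryid")
    g["drug_seq"] = get(drug, "drug_seq") if "drug_seq" in drug.columns else get(drug, "dsg_drug_seq")
    g["drugname"] = get(drug, "drugname")
    role = get(drug, "role_cod").str.upper()
    g["role_cod"] = role.where(role.isin(ROLE_CODES), pd.NA)
    report.unknown_roles = int((role != "").sum() - role.isin(ROLE_CODES).sum())
    bad = (g["primaryid"] == "") | (g["drugname"] == "")
    if bad.any():
        if strict:
            raise IntegrityError(f"{int(bad.sum())} drug rows lack primaryid/drugname")
        report.malformed_rows["drug"] = int(bad.sum())
        g = g[~bad]
    drug_n = g.reset_index(drop=True)

    # ---- REAC -----------------------------------------------------------
    rc = pd.DataFrame(index=reac.index)
    rc["primaryid"] = get(reac, "primaryid")
    pt = get(reac, "pt")
    rc["pt"] = pt
    rc["pt_norm"] = pt.str.casefold()
    bad = (rc["primaryid"] == "") | (rc["pt"] == "")
    if bad.any():
        if strict:
            raise IntegrityError(f"{int(bad.sum())} reac rows lack primaryid/pt")
        report.malformed_rows["reac"] = int(bad.sum())
        rc = rc[~bad]
    reac_n = rc.reset_index(drop=True)

    # ---- THER -----------------------------------------------------------
    t = pd.DataFrame(index=ther.index)
    t["primaryid"] = get(ther, "primaryid")
    t["dsg_drug_seq"] = (
        get(ther, "dsg_drug_seq") if "dsg_drug_seq" in ther.columns else get(ther, "drug_seq")
    )
    start, _, n_part = parse_yyyymmdd(get(ther, "start_dt"))
    report.partial_dates["start_dt"] = n_part
    t["start_date"] = start
    ther_n = t[t["primaryid"] != ""].reset_index(drop=True)

    return NormalizedTables(demo_n, drug_n, reac_n, ther_n), report


def _primaryid_key(primaryid: pd.Series) -> pd.Series:
    """Numeric ordering for primaryid strings.

    FAERS primaryids are numeric; if any value is non-numeric the whole
    column falls back to (length, lexicographic) ordering, which agrees
    with numeric order on digit strings.
    """
    key = pd.to_numeric(primaryid, errors="coerce")
    if key.isna().any():
        order = primaryid.to_frame("pid").assign(ln=primaryid.str.len())
        order = order.sort_values(["ln", "pid"], kind="stable")
        rank = pd.Series(np.arange(len(order)), index=order.index, dtype=float)
        return rank.reindex(primaryid.index)
    return key


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per caseid: the one with the largest PRIMARYID.

    Retention depends only on the maximal primaryid within each case
    (FDA_DT is carried along but does not decide retention). Idempotent;
    the result is sorted by (caseid, primaryid) and row order of the
    input never changes the retained set. Duplicate primaryid values are
    a structural violation and raise.
    """
    if demo["primaryid"].duplicated().any():
        dupes = demo["primaryid"][demo["primaryid"].duplicated()].unique()[:5]
        raise IntegrityError(f"duplicate primaryid values, e.g. {list(dupes)}")
    key = _primaryid_key(demo["primaryid"])
    keep = key.groupby(demo["caseid"]).idxmax()
    out = demo.loc[keep]
    out = out.iloc[np.lexsort((key.loc[keep.values].to_numpy(), out["caseid"].to_numpy()))]
    return out.reset_index(drop=True)


def restrict_to(tables: NormalizedTables, demo_dedup: pd.DataFrame) -> NormalizedTables:
    """Filter DRUG/REAC/THER to the retained report versions."""
    kept = set(demo_dedup["primaryid"])
    return NormalizedTables(
        demo=demo_dedup,
        drug=tables.drug[tables.drug["primaryid"].isin(kept)].reset_index(drop=True),
        reac=tables.reac[tables.reac["primaryid"].isin(kept)].reset_index(drop=True),
        ther=tables.ther[tables.ther["primaryid"].isin(kept)].reset_index(drop=True),
    )
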