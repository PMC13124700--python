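"""Synthetic FAERS-style spontaneous-report generator.

Emulates the data-generating situation behind a quarterly spontaneous
reporting system so the whole analysis pipeline is testable without any
download: duplicate case versions sharing a CASEID, primary-suspect role
codes, drug-name synonyms needing standardization, a target preferred term
("Pemphigoid" by default), demographic fields with realistic missingness,
therapy-start/event dates yielding mostly short (<30 day) latencies, and a
configurable true drug-event association strength.

The generative model: each *case* is independently exposed to each study
drug with that drug's background probability; exposed drugs are listed as
primary suspects. The target event occurs with probability
``event_base_rate`` for unexposed cases and ``event_base_rate x
relative_risk`` when exposed (the maximum relative risk across exposed
drugs applies; ``relative_risk = 1`` encodes the null). At low base rates
the reporting odds ratio consistently estimates the odds-ratio analogue
of the configured relative risk. A configurable fraction of cases emit an
earlier, superseded report version (smaller PRIMARYID, earlier-or-equal
FDA_DT, possibly different demographics); the last version is ground
truth, matching the retention rule the deduplication stage applies.

Randomness is split into per-table streams spawned from the master seed,
so adding one table's draws never perturbs another's; equal seeds produce
byte-identical serialized tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import quota_counts
from .errors import ConfigError

__all__ = [
    "DrugProfile",
    "LatencyModel",
    "SimulationConfig",
    "RawTables",
    "LiteratureProfile",
    "generate",
    "generate_literature_cases",
]

FAERS_SEP = "$"
TABLE_FILES = {"demo": "DEMO.txt", "drug": "DRUG.txt", "reac": "REAC.txt", "ther": "THER.txt"}

# noise terms so every report has at least one reaction and most have no
# target event; concomitant drugs exercise the unmapped-name path
_BACKGROUND_PTS = (
    "Nausea", "Headache", "Rash", "Dizziness", "Pyrexia",
    "Diarrhoea", "Fatigue", "Pruritus", "Vomiting", "Insomnia",
)
_BACKGROUND_DRUGS = ("PARACETAMOL", "OMEPRAZOLE", "METFORMIN", "AMOXICILLIN", "IBUPROFEN")

_AGE_BAND_RANGES = {"<18": (5, 17), "18-44": (18, 44), "45-64": (45, 64), ">=65": (65, 94)}
_WEIGHT_BAND_RANGES = {"<80": (45.0, 79.5), ">=80": (80.0, 130.0)}


@dataclass(frozen=True)
class DrugProfile:
    """One study drug: identity, exposure and its true association strength."""

    name: str
    synonyms: tuple[str, ...] = ()
    exposure_prob: float = 0.01
    approval_date: int = 19900101
    relative_risk: float = 1.0
    relative_risk_by_sex: Mapping[str, float] | None = None

    def rr_for(self, sex: np.ndarray) -> np.ndarray:
        if not self.relative_risk_by_sex:
            return np.full(len(sex), float(self.relative_risk))
        out = np.full(len(sex), float(self.relative_risk))
        for code, rr in self.relative_risk_by_sex.items():
            out[sex == code] = float(rr)
        return out


@dataclass(frozen=True)
class LatencyModel:
    """Days from therapy start to event onset.

    ``lognormal`` with a median (days) and log-scale sigma, or ``fixed``
    with a single point-mass value.
    """

    family: str = "lognormal"
    median_days: float = 14.0
    sigma: float = 0.8
    value: float | None = None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            if self.value is None:
                raise ConfigError("latency_model.value required for family='fixed'")
            return np.full(n, int(round(self.value)))
        if self.family == "lognormal":
            days = rng.lognormal(np.log(self.median_days), self.sigma, n)
            return np.maximum(np.rint(days).astype(int), 0)
        raise ConfigError(f"latency_model.family {self.family!r} not recognised")


_DEFAULT_DRUGS = (
    DrugProfile("OFLOXACIN", ("Floxin", "Tarivid", "Ofloxacine"), 0.030, 19901228, 2.75),
    DrugProfile("CIPROFLOXACIN", ("Cipro", "Cipro XR", "Ciproxin"), 0.030, 19871022, 2.31),
    DrugProfile("LEVOFLOXACIN", ("Levaquin", "Cravit"), 0.025, 19961220, 2.53),
    DrugProfile("MOXIFLOXACIN", ("Avelox",), 0.010, 19991210, 1.0),
    DrugProfile("NORFLOXACIN", ("Noroxin",), 0.002, 19861031, 25.14),
)

# marginal distributions of the *observed* (non-missing) demographic levels
# in the studied quinolone-pemphigoid reporting cohort
_DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"F": 0.642, "M": 0.358},
    "age_band": {"<18": 0.013, "18-44": 0.179, "45-64": 0.225, ">=65": 0.583},
    "weight_band": {"<80": 0.70, ">=80": 0.30},
    "occupation": {"CN": 0.041, "MD": 0.413, "OT": 0.430, "PH": 0.116},
    "region": {"Others": 0.929, "Europe": 0.049, "North America": 0.016, "Asia": 0.006},
    "outcome": {"DE": 0.006, "HO": 0.741, "OT": 0.253},
}

# per-field blanking probabilities (the NS shares observed in that cohort;
# date fields emulate the large share of reports without usable timing)
_DEFAULT_MISSINGNESS: dict[str, float] = {
    "sex": 0.131,
    "age": 0.175,
    "weight": 0.727,
    "occp_cod": 0.060,
    "outc_cod": 0.093,
    "event_dt": 0.25,
    "start_dt": 0.25,
}


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic quarterly extract.

    ``n_reports`` counts raw (pre-deduplication) report *versions*;
    ``duplicate_fraction`` is the probability that a case emits a second,
    superseded version. All probabilities live in [0, 1]; categorical
    distributions must sum to 1 (tolerance 1e-9).
    """

    n_reports: int = 50_000
    drugs: Sequence[DrugProfile] = _DEFAULT_DRUGS
    event_term: str = "Pemphigoid"
    event_base_rate: float = 0.01
    duplicate_fraction: float = 0.10
    missingness: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MISSINGNESS))
    demographics: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_DEMOGRAPHICS.items()}
    )
    latency_model: LatencyModel = field(default_factory=LatencyModel)
    year_range: tuple[int, int] = (2004, 2024)
    partial_event_dt_fraction: float = 0.02
    seed: int = 0

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if int(self.n_reports) != self.n_reports or self.n_reports < 1:
            raise ConfigError(f"n_reports must be a positive integer, got {self.n_reports!r}")
        if not self.drugs:
            raise ConfigError("drugs must be non-empty")
        if not (0.0 <= self.event_base_rate <= 1.0):
            raise ConfigError(f"event_base_rate={self.event_base_rate!r} outside [0, 1]")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ConfigError(f"duplicate_fraction={self.duplicate_fraction!r} outside [0, 1)")
        if not (0.0 <= self.partial_event_dt_fraction <= 1.0):
            raise ConfigError("partial_event_dt_fraction outside [0, 1]")
        for d in self.drugs:
            if not (0.0 <= d.exposure_prob <= 1.0):
                raise ConfigError(f"drugs[{d.name}].exposure_prob outside [0, 1]")
            if d.relative_risk < 0:
                raise ConfigError(f"drugs[{d.name}].relative_risk must be >= 0")
            for rr in (d.relative_risk_by_sex or {}).values():
                if rr < 0:
                    raise ConfigError(f"drugs[{d.name}].relative_risk_by_sex values must be >= 0")
        for fld, p in self.missingness.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"missingness[{fld}]={p!r} outside [0, 1]")
        for name, dist in self.demographics.items():
            if not dist:
                raise ConfigError(f"demographics[{name}] is empty")
            tot = float(sum(dist.values()))
            if any(p < 0 for p in dist.values()):
                raise ConfigError(f"demographics[{name}] has a negative probability")
            if abs(tot - 1.0) > 1e-9:
                raise ConfigError(f"demographics[{name}] sums to {tot!r}, not 1")
        y0, y1 = self.year_range
        if y0 > y1:
            raise ConfigError("year_range must be (first, last) with first <= last")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["drugs"] = [dataclasses.asdict(d) for d in self.drugs]
        out["latency_model"] = dataclasses.asdict(self.latency_model)
        out["year_range"] = list(self.year_range)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "drugs" in data:
            data["drugs"] = tuple(
                d if isinstance(d, DrugProfile) else DrugProfile(
                    name=d["name"],
                    synonyms=tuple(d.get("synonyms", ())),
                    exposure_prob=float(d.get("exposure_prob", 0.01)),
                    approval_date=int(d.get("approval_date", 19900101)),
                    relative_risk=float(d.get("relative_risk", 1.0)),
                    relative_risk_by_sex=d.get("relative_risk_by_sex"),
                )
                for d in data["drugs"]
            )
        if "latency_model" in data and not isinstance(data["latency_model"], LatencyModel):
            data["latency_model"] = LatencyModel(**data["latency_model"])
        if "year_range" in data:
            data["year_range"] = tuple(data["year_range"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RawTables:
    """The four FAERS-dialect quarterly tables as string-typed frames."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame

    def write(self, outdir: str | Path, fmt: str = "faers") -> dict[str, Path]:
        """Write DEMO/DRUG/REAC/THER as "$"-delimited ASCII (or parquet)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for name, fname in TABLE_FILES.items():
            df: pd.DataFrame = getattr(self, name)
            if fmt == "faers":
                path = outdir / fname
                df.to_csv(path, sep=FAERS_SEP, index=False)
            elif fmt == "parquet":
                path = outdir / (fname.replace(".txt", ".parquet"))
                df.to_parquet(path, index=False)
            else:
                raise ConfigError(f"unknown output format {fmt!r}")
            written[name] = path
        return written


# ---------------------------------------------------------------------------
# generation


def _draw_cat(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    levels = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()  # guard 1e-9 slack
    return rng.choice(levels, size=n, p=probs)


def _dates_to_int(dates: pd.DatetimeIndex) -> np.ndarray:
    return (dates.year * 10000 + dates.month * 100 + dates.day).to_numpy()


def _blank(rng: np.random.Generator, values: np.ndarray, p: float) -> np.ndarray:
    out = values.astype(object).copy()
    out[rng.random(len(values)) < p] = ""
    return out


def generate(config: SimulationConfig) -> RawTables:
    """Generate one synthetic quarterly extract per the configuration.

    Deterministic: identical configs (including seed) give bit-identical
    tables. The DEMO table holds exactly ``config.n_reports`` rows.
    """
    config.validate()
    ss = np.random.SeedSequence(int(config.seed))
    names = ("cases", "demo", "exposure", "latency", "dup", "missing", "reac")
    rngs = {n: np.random.default_rng(s) for n, s in zip(names, ss.spawn(len(names)))}

    # ---- cases and version counts (exactly n_reports versions) ----------
    n_rep = int(config.n_reports)
    r = rngs["cases"]
    dup_flags = r.random(n_rep) < config.duplicate_fraction
    versions = 1 + dup_flags.astype(int)
    cum = np.cumsum(versions)
    n_cases = int(np.searchsorted(cum, n_rep)) + 1
    versions = versions[:n_cases].copy()
    versions[-1] -= int(cum[n_cases - 1] - n_rep)
    n_cases = len(versions)

    # ---- ground-truth demographics per case ------------------------------
    r = rngs["demo"]
    demo = config.demographics
    sex = _draw_cat(r, demo["sex"], n_cases)
    band = _draw_cat(r, demo["age_band"], n_cases)
    age_years = np.empty(n_cases, dtype=int)
    for b, (lo, hi) in _AGE_BAND_RANGES.items():
        m = band == b
        age_years[m] = r.integers(lo, hi + 1, int(m.sum()))
    wband = _draw_cat(r, demo["weight_band"], n_cases)
    weight_kg = np.empty(n_cases)
    for b, (lo, hi) in _WEIGHT_BAND_RANGES.items():
        m = wband == b
        weight_kg[m] = np.round(r.uniform(lo, hi, int(m.sum())), 1)
    occp = _draw_cat(r, demo["occupation"], n_cases)
    region = _draw_cat(r, demo["region"], n_cases)
    outcome = _draw_cat(r, demo["outcome"], n_cases)

    y0, y1 = config.year_range
    fda = pd.to_datetime(
        {
            "year": r.integers(y0, y1 + 1, n_cases),
            "month": r.integers(1, 13, n_cases),
            "day": r.integers(1, 29, n_cases),
        }
    )
    fda = pd.DatetimeIndex(fda)

    # mixed units for downstream normalisation to exercise
    age_cod = r.choice(np.array(["YR", "DEC", "MON"], dtype=object), n_cases, p=[0.90, 0.05, 0.05])
    wt_cod = r.choice(np.array(["KG", "LBS"], dtype=object), n_cases, p=[0.85, 0.15])

    # ---- exposure and target-event assignment ----------------------------
    r = rngs["exposure"]
    n_drugs = len(config.drugs)
    exposed = np.empty((n_cases, n_drugs), dtype=bool)
    rr_mat = np.ones((n_cases, n_drugs))
    for j, dprof in enumerate(config.drugs):
        exposed[:, j] = r.random(n_cases) < dprof.exposure_prob
        rr_mat[:, j] = dprof.rr_for(sex)
    mult = np.where(exposed, rr_mat, 1.0).max(axis=1)
    p_event = np.clip(config.event_base_rate * mult, 0.0, 1.0)
    event = r.random(n_cases) < p_event

    # verbatim drug names: canonical or a synonym, uniformly
    verbatim = np.empty((n_cases, n_drugs), dtype=object)
    for j, dprof in enumerate(config.drugs):
        variants = np.array([dprof.name, *dprof.synonyms], dtype=object)
        verbatim[:, j] = variants[r.integers(0, len(variants), n_cases)]
    has_comed = r.random(n_cases) < 0.5
    comed = np.array(_BACKGROUND_DRUGS, dtype=object)[
        r.integers(0, len(_BACKGROUND_DRUGS), n_cases)
    ]

    # ---- timing ----------------------------------------------------------
    r = rngs["latency"]
    latency = config.latency_model.draw(r, n_cases)
    report_delay = r.integers(0, 61, n_cases)
    start = fda - pd.to_timedelta(latency + report_delay, unit="D")
    event_date = start + pd.to_timedelta(latency, unit="D")

    # ---- background reactions -------------------------------------------
    r = rngs["reac"]
    bg_pt = np.array(_BACKGROUND_PTS, dtype=object)[r.integers(0, len(_BACKGROUND_PTS), n_cases)]

    # ---- assemble version-level DEMO ------------------------------------
    caseid = (10_000_001 + np.arange(n_cases)).astype(str)
    case_final = pd.DataFrame(
        {
            "case_idx": np.arange(n_cases),
            "version": 1,
            "fda_date": fda,
            "sex": sex.copy(),
            "age_years": age_years.astype(object),
            "age_cod": age_cod,
            "weight_kg": weight_kg.astype(object),
            "wt_cod": wt_cod,
            "occp_cod": occp,
            "region": region,
            "outcome": outcome,
        }
    )
    r = rngs["dup"]
    dup_idx = np.flatnonzero(versions == 2)
    if len(dup_idx):
        v1 = case_final.iloc[dup_idx].copy()
        v1["version"] = 0
        v1["fda_date"] = v1["fda_date"] - pd.to_timedelta(
            r.integers(1, 91, len(dup_idx)), unit="D"
        )
        # superseded versions often carry sparser demographics
        blank_sex = r.random(len(dup_idx)) < 0.3
        blank_age = r.random(len(dup_idx)) < 0.3
        v1.loc[v1.index[blank_sex], "sex"] = ""
        v1.loc[v1.index[blank_age], "age_years"] = ""
        all_versions = pd.concat([case_final, v1], ignore_index=True)
    else:
        all_versions = case_final

    all_versions = all_versions.sort_values(
        ["fda_date", "case_idx", "version"], kind="stable"
    ).reset_index(drop=True)
    all_versions["primaryid"] = (100_000_001 + np.arange(len(all_versions))).astype(str)

    # ---- render DEMO strings with missingness ----------------------------
    r = rngs["missing"]
    miss = config.missingness
    nv = len(all_versions)
    ev_for_version = pd.DatetimeIndex(event_date[all_versions["case_idx"].to_numpy()])
    event_dt_str = _dates_to_int(ev_for_version).astype(str).astype(object)
    partial = r.random(nv) < config.partial_event_dt_fraction
    event_dt_str[partial] = ev_for_version.year.astype(str).to_numpy(dtype=object)[partial]
    event_dt_str[r.random(nv) < miss.get("event_dt", 0.0)] = ""

    sex_out = _blank(r, all_versions["sex"].to_numpy(), miss.get("sex", 0.0))
    age_out = all_versions["age_years"].to_numpy(object).copy()
    cod_out = all_versions["age_cod"].to_numpy(object).copy()
    # render in the coded unit (decades / months) before blanking
    numeric = np.array([v != "" for v in age_out])
    dec = numeric & (cod_out == "DEC")
    mon = numeric & (cod_out == "MON")
    age_out[dec] = [round(int(v) / 10.0, 1) for v in age_out[dec]]
    age_out[mon] = [int(v) * 12 for v in age_out[mon]]
    age_blank = r.random(nv) < miss.get("age", 0.0)
    age_out[age_blank] = ""
    cod_out[age_blank | ~numeric] = ""

    wt_out = all_versions["weight_kg"].to_numpy(object).copy()
    wtc_out = all_versions["wt_cod"].to_numpy(object).copy()
    lbs = wtc_out == "LBS"
    wt_out[lbs] = [round(float(v) / 0.45359237, 1) for v in wt_out[lbs]]
    wt_blank = r.random(nv) < miss.get("weight", 0.0)
    wt_out[wt_blank] = ""
    wtc_out[wt_blank] = ""

    occp_out = _blank(r, all_versions["occp_cod"].to_numpy(), miss.get("occp_cod", 0.0))
    outc_out = _blank(r, all_versions["outcome"].to_numpy(), miss.get("outc_cod", 0.0))

    demo_df = pd.DataFrame(
        {
            "primaryid": all_versions["primaryid"],
            "caseid": caseid[all_versions["case_idx"].to_numpy()],
            "fda_dt": _dates_to_int(pd.DatetimeIndex(all_versions["fda_date"])).astype(str),
            "event_dt": event_dt_str,
            "sex": sex_out,
            "age": [str(v) for v in age_out],
            "age_cod": cod_out,
            "wt": [str(v) for v in wt_out],
            "wt_cod": wtc_out,
            "occp_cod": occp_out,
            "occr_country": all_versions["region"].to_numpy(),
            "outc_cod": outc_out,
        }
    ).astype(str)

    # ---- DRUG / THER / REAC (case-level rows fanned out per version) -----
    start_int = _dates_to_int(pd.DatetimeIndex(start)).astype(str)
    start_blank = rngs["missing"].random(n_cases) < miss.get("start_dt", 0.0)

    seq_mat = np.cumsum(exposed, axis=1)  # drug_seq for each exposed (case, drug)
    exp_case, exp_drug = np.nonzero(exposed)
    ps_seq = seq_mat[exp_case, exp_drug]
    comed_case = np.flatnonzero(has_comed)
    drug_case = pd.DataFrame(
        {
            "case_idx": np.concatenate([exp_case, comed_case]),
            "drug_seq": np.concatenate([ps_seq, seq_mat[comed_case, -1] + 1]),
            "drugname": np.concatenate([verbatim[exp_case, exp_drug], comed[comed_case]]),
            "role_cod": np.concatenate(
                [np.full(len(exp_case), "PS", object), np.full(len(comed_case), "C", object)]
            ),
        }
    )
    ther_case = pd.DataFrame(
        {
            "case_idx": exp_case,
            "dsg_drug_seq": ps_seq,
            "start_dt": np.where(start_blank[exp_case], "", start_int[exp_case]),
        }
    )

    reac_rows = pd.DataFrame({"case_idx": np.arange(n_cases), "pt": bg_pt})
    target = pd.DataFrame({"case_idx": np.flatnonzero(event), "pt": config.event_term})
    reac_case = pd.concat([reac_rows, target], ignore_index=True)

    version_key = all_versions[["case_idx", "primaryid"]]

    def fan_out(case_df: pd.DataFrame) -> pd.DataFrame:
        out = version_key.merge(case_df, on="case_idx", how="inner")
        out["caseid"] = caseid[out["case_idx"].to_numpy()]
        return out.drop(columns="case_idx")

    drug_df = fan_out(drug_case)[["primaryid", "caseid", "drug_seq", "drugname", "role_cod"]]
    ther_df = fan_out(ther_case)[["primaryid", "caseid", "dsg_drug_seq", "start_dt"]]
    reac_df = fan_out(reac_case)[["primaryid", "caseid", "pt"]]

    sort_key = lambda df: df.sort_values(  # noqa: E731 - stable output ordering
        ["primaryid"] + [c for c in ("drug_seq", "dsg_drug_seq", "pt") if c in df.columns],
        kind="stable",
    ).reset_index(drop=True)
    return RawTables(
        demo=demo_df.reset_index(drop=True),
        drug=sort_key(drug_df).astype(str),
        reac=sort_key(reac_df).astype(str),
        ther=sort_key(ther_df).astype(str),
    )


# ---------------------------------------------------------------------------
# literature-case generator


@dataclass(frozen=True)
class LiteratureProfile:
    """Distributional profile for published single-case reports."""

    drug_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "CIPROFLOXACIN": 3 / 9,
            "LEVOFLOXACIN": 2 / 9,
            "OFLOXACIN": 2 / 9,
            "MOXIFLOXACIN": 1 / 9,
            "NORFLOXACIN": 1 / 9,
        }
    )
    p_female: float = 5 / 9
    age_band_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"<45": 1 / 9, "45-64": 1 / 9, ">=65": 7 / 9}
    )
    p_hospitalized: float = 5 / 9
    latency_model: LatencyModel = dataclasses.field(
        default_factory=lambda: LatencyModel("lognormal", median_days=18.0, sigma=0.5)
    )
    outcome_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "Recovered after drug withdrawal": 0.7,
            "Improved with topical corticosteroids": 0.3,
        }
    )


_LIT_AGE_RANGES = {"<45": (25, 44), "45-64": (45, 64), ">=65": (65, 90)}


def generate_literature_cases(
    n: int, profile: LiteratureProfile | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw `n` synthetic published-case rows.

    Categorical fields use largest-remainder quota allocation so the
    realised counts match the profile exactly at small n (a profile with
    P(>=65) = 7/9 yields exactly 7 elderly cases out of 9); column order
    within the table is then shuffled independently per field.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    profile = profile or LiteratureProfile()
    rng = np.random.default_rng(int(seed))

    def quota_column(dist: Mapping[str, float]) -> np.ndarray:
        levels = list(dist.keys())
        counts = quota_counts(np.array(list(dist.values())), n)
        col = np.repeat(np.array(levels, dtype=object), counts)
        rng.shuffle(col)
        return col

    drug = quota_column(profile.drug_probs)
    sex = quota_column({"F": profile.p_female, "M": 1 - profile.p_female})
    band = quota_column(profile.age_band_probs)
    hosp = quota_column({"true": profile.p_hospitalized, "false": 1 - profile.p_hospitalized})
    outcome = quota_column(profile.outcome_probs)

    age = np.empty(n, dtype=int)
    for b, (lo, hi) in _LIT_AGE_RANGES.items():
        m = band == b
        age[m] = rng.integers(lo, hi + 1, int(m.sum()))
    latency = np.maximum(profile.latency_model.draw(rng, n), 1)

    return pd.DataFrame(
        {
            "drug": drug,
            "age_years": age,
            "sex": sex,
            "latency_days": latency,
            "hospitalized": hosp == "true",
            "outcome": outcome,
        }
    )
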