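import numpy as np
import pandas as pd
import pytest

from pvdispro.cohort import default_drug_dictionary, default_event_terms
from pvdispro.ingest import normalize_tables
from pvdispro.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def drug_dictionary():
    return default_drug_dictionary()


@pytest.fixture(scope="session")
def event_terms():
    return default_event_terms()


@pytest.fixture(scope="session")
def small_raw():
    """One deterministic 8,000-version synthetic extract."""
    return generate(SimulationConfig(n_reports=8_000, seed=2024))


@pytest.fixture(scope="session")
def small_tables(small_raw):
    tables, _ = normalize_tables(
        small_raw.demo, small_raw.drug, small_raw.reac, small_raw.ther
    )
    return tables


def make_tables(demo_rows, drug_rows=(), reac_rows=(), ther_rows=()):
    """Hand-built raw tables: sequences of dicts, everything stringly typed."""

    def df(rows, cols):
        if not rows:
            return pd.DataFrame({c: pd.Series(dtype=str) for c in cols})
        out = pd.DataFrame(list(rows)).astype(str)
        for c in cols:
            if c not in out.columns:
                out[c] = ""
        return out

    demo = df(demo_rows, ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
                          "age_cod", "wt", "wt_cod", "occp_cod", "occr_country", "outc_cod"])
    drug = df(drug_rows, ["primaryid", "caseid", "drug_seq", "drugname", "role_cod"])
    reac = df(reac_rows, ["primaryid", "caseid", "pt"])
    ther = df(ther_rows, ["primaryid", "caseid", "dsg_drug_seq", "start_dt"])
    return normalize_tables(demo, drug, reac, ther)


@pytest.fixture
def tiny_tables_factory():
    return make_tables


def random_demo(rng: np.random.Generator, n_cases: int, max_versions: int = 3) -> pd.DataFrame:
    """Random deduplication input: unique primaryids, shared caseids."""
    rows = []
    pid = 1
    for c in range(n_cases):
        for _ in range(int(rng.integers(1, max_versions + 1))):
            rows.append({"primaryid": str(pid), "caseid": f"C{c}"})
            pid += 1
    demo = pd.DataFrame(rows)
    demo["fda_date"] = pd.NaT
    return demo.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
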