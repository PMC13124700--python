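"""Monte-Carlo calibration of the signal-detection pipeline.

Runs the full in-memory pipeline (generate -> normalise -> deduplicate ->
analysis frame -> 2x2 -> disproportionality) over replicate seeds to
measure operating characteristics against known ground truth:

* null calibration — with relative risk 1 for every drug, the fraction of
  replicates whose ROR meets the signal criterion (a >= 3 and lower 95%
  bound > 1) should stay near the one-sided nominal 2.5%;
* recovery — with an injected relative risk, the replicate-median ROR
  should sit near the odds-ratio analogue of the injected risk;
* subgroup recovery — a sex-specific injected risk should surface in the
  matching stratum only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import (
    DrugDictionary,
    EventTermSet,
    build_analysis_frame,
    default_drug_dictionary,
    default_event_terms,
)
from .ingest import deduplicate, normalize_tables, restrict_to
from .signals import Disproportionality, stratified_signals
from .simulate import SimulationConfig, generate

__all__ = [
    "null_config",
    "effect_config",
    "sex_effect_config",
    "frame_from_config",
    "ror_replicates",
    "stratified_replicates",
    "replicate_seeds",
]


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds (< 2^31) from one master seed."""
    return np.random.SeedSequence(int(master_seed)).generate_state(n) % (2**31)


def _with_rr(config: SimulationConfig, rr_map: dict[str, float | dict]) -> SimulationConfig:
    drugs = []
    for d in config.drugs:
        rr = rr_map.get(d.name, 1.0)
        if isinstance(rr, dict):
            drugs.append(dataclasses.replace(d, relative_risk=1.0, relative_risk_by_sex=rr))
        else:
            drugs.append(dataclasses.replace(d, relative_risk=float(rr), relative_risk_by_sex=None))
    return dataclasses.replace(config, drugs=tuple(drugs))


def null_config(n_reports: int = 50_000, seed: int = 0) -> SimulationConfig:
    """Every drug at relative risk 1 (no true association)."""
    return _with_rr(SimulationConfig(n_reports=n_reports, seed=seed), {})


def effect_config(
    drug: str = "OFLOXACIN", relative_risk: float = 5.0, n_reports: int = 50_000, seed: int = 0
) -> SimulationConfig:
    """One drug carries the injected relative risk; the rest are null."""
    return _with_rr(
        SimulationConfig(n_reports=n_reports, seed=seed), {drug: relative_risk}
    )


def sex_effect_config(
    drug: str = "OFLOXACIN",
    rr_female: float = 5.0,
    rr_male: float = 1.0,
    n_reports: int = 50_000,
    seed: int = 0,
) -> SimulationConfig:
    """Sex-specific injected risk (effect-modification scenario)."""
    return _with_rr(
        SimulationConfig(n_reports=n_reports, seed=seed),
        {drug: {"F": rr_female, "M": rr_male}},
    )


def frame_from_config(
    config: SimulationConfig,
    dictionary: DrugDictionary | None = None,
    events: EventTermSet | None = None,
) -> pd.DataFrame:
    """Generate one replicate and carry it to the report-level frame."""
    dictionary = dictionary or default_drug_dictionary()
    events = events or default_event_terms()
    raw = generate(config)
    tables, _ = normalize_tables(raw.demo, raw.drug, raw.reac, raw.ther)
    demo = deduplicate(tables.demo)
    tables = restrict_to(tables, demo)
    return build_analysis_frame(tables, dictionary, events)


def ror_replicates(
    base_config: SimulationConfig,
    drug: str,
    n_replicates: int,
    master_seed: int = 0,
    approval_date: int | None = None,
) -> pd.DataFrame:
    """Fit the drug's 2x2 on `n_replicates` independent datasets."""
    dictionary = default_drug_dictionary()
    events = default_event_terms()
    approval = approval_date if approval_date is not None else dictionary.approval_dates().get(drug)
    rows = []
    for seed in replicate_seeds(master_seed, n_replicates):
        cfg = dataclasses.replace(base_config, seed=int(seed))
        frame = frame_from_config(cfg, dictionary, events)
        r = Disproportionality.from_frame(frame, drug, approval_date=approval).fit().result
        rows.append({"seed": int(seed), **r.as_dict()})
    return pd.DataFrame(rows)


def stratified_replicates(
    base_config: SimulationConfig,
    drug: str,
    strata: str,
    n_replicates: int,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Stratified fits per replicate (one row per replicate x stratum)."""
    dictionary = default_drug_dictionary()
    events = default_event_terms()
    approval = dictionary.approval_dates().get(drug)
    frames = []
    for seed in replicate_seeds(master_seed, n_replicates):
        cfg = dataclasses.replace(base_config, seed=int(seed))
        frame = frame_from_config(cfg, dictionary, events)
        tab = stratified_signals(frame, drug, strata, approval)
        tab.insert(0, "seed", int(seed))
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
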