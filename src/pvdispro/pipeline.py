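"""End-to-end orchestration: simulate -> ingest -> cohort -> statistics.

Runs the stages in roadmap order against one configuration and seed,
collecting a machine-readable run manifest (config hash, per-stage row
counts, exclusion counters, version, timestamps). The same functions back
the ``pvdispro run-all`` command and the in-memory replicate loops used
for calibration studies, so the command line and the Monte-Carlo path
exercise identical code.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    DrugDictionary,
    EventTermSet,
    build_analysis_frame,
    build_cohort,
    default_drug_dictionary,
    default_event_terms,
)
from .describe import profile, yearly_counts
from .ingest import deduplicate, normalize_tables, restrict_to
from .literature import concordance, faers_summary, load_literature_cases, summarize_literature
from .signals import forest_table, signal_table, stratified_signals
from .simulate import RawTables, SimulationConfig, generate
from .tto import compute_latency, cumulative_curve

__all__ = ["RunManifest", "PipelineResult", "run_all", "analyze_tables"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        self.stages[stage] = {"n_in": int(n_in), "n_out": int(n_out), **extra}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class PipelineResult:
    manifest: RunManifest
    frame: pd.DataFrame
    cohort: pd.DataFrame
    signals: pd.DataFrame
    stratified: dict[str, pd.DataFrame]
    profile: pd.DataFrame
    yearly: pd.Series
    latency: pd.DataFrame
    tto: pd.DataFrame | None
    concordance: pd.DataFrame


def _hash_config(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def analyze_tables(
    raw: RawTables,
    dictionary: DrugDictionary | None = None,
    events: EventTermSet | None = None,
    manifest: RunManifest | None = None,
    strata: tuple[str, ...] = ("age", "sex", "reporter"),
) -> PipelineResult:
    """All analysis stages downstream of raw quarterly tables."""
    dictionary = dictionary or default_drug_dictionary()
    events = events or default_event_terms()
    manifest = manifest or RunManifest(config_hash="external", seed=-1)

    tables, report = normalize_tables(raw.demo, raw.drug, raw.reac, raw.ther)
    manifest.record(
        "ingest", len(raw.demo), len(tables.demo), warnings=report.total_warnings()
    )
    demo_dd = deduplicate(tables.demo)
    manifest.record("deduplicate", len(tables.demo), len(demo_dd))
    tables = restrict_to(tables, demo_dd)

    frame = build_analysis_frame(tables, dictionary, events)
    cohort = build_cohort(tables, dictionary, events)
    manifest.record("cohort", len(frame), len(cohort))

    drugs = dictionary.included
    approvals = dictionary.approval_dates()
    sig = signal_table(frame, drugs, approvals)
    strat = {
        s: pd.concat(
            [stratified_signals(frame, d, s, approvals.get(d)) for d in drugs],
            ignore_index=True,
        )
        for s in strata
    }
    manifest.record("signal", len(frame), len(sig))

    event_cohort = cohort[cohort["event"]]
    if len(event_cohort) == 0:
        raise_empty = profile(cohort)  # still profile exposure cohort
        prof = raise_empty
    else:
        prof = profile(event_cohort)
    yearly = yearly_counts(event_cohort if len(event_cohort) else cohort)
    manifest.record("profile", len(event_cohort), len(prof))

    latency, excl = compute_latency(event_cohort if len(event_cohort) else cohort)
    tto_tab = cumulative_curve(latency) if len(latency) else None
    manifest.record(
        "tto", len(event_cohort), len(latency),
        excluded_missing_start=excl.missing_start,
        excluded_missing_event=excl.missing_event,
        excluded_negative=excl.negative,
    )

    lit = load_literature_cases()
    lit_sum = summarize_literature(lit)
    fae_sum = faers_summary(event_cohort if len(event_cohort) else cohort, latency)
    conc = concordance(lit_sum, fae_sum)
    manifest.record("concordance", len(lit), len(conc))

    return PipelineResult(
        manifest=manifest,
        frame=frame,
        cohort=cohort,
        signals=sig,
        stratified=strat,
        profile=prof,
        yearly=yearly,
        latency=latency,
        tto=tto_tab,
        concordance=conc,
    )


def run_all(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    dictionary: DrugDictionary | None = None,
    events: EventTermSet | None = None,
) -> PipelineResult:
    """Simulate one quarterly extract and run every analysis stage.

    With ``outdir`` every stage output is persisted (raw tables as
    "$"-delimited ASCII, analysis outputs as CSV, manifest as JSON).
    """
    manifest = RunManifest(config_hash=_hash_config(config), seed=int(config.seed))
    manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")
    raw = generate(config)
    manifest.record("simulate", 0, len(raw.demo))
    result = analyze_tables(raw, dictionary, events, manifest)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        raw.write(outdir / "raw")
        result.cohort.to_csv(outdir / "cohort.csv", index=False)
        result.signals.to_csv(outdir / "signals.csv", index=False)
        forest_table(result.signals).to_csv(outdir / "forest.csv", index=False)
        for name, tab in result.stratified.items():
            tab.to_csv(outdir / f"signals_by_{name}.csv", index=False)
        result.profile.to_csv(outdir / "profile.csv", index=False)
        result.yearly.rename_axis("year").to_csv(outdir / "yearly_counts.csv")
        result.latency.to_csv(outdir / "latency_records.csv", index=False)
        if result.tto is not None:
            result.tto.to_csv(outdir / "tto.csv", index=False)
        result.concordance.to_csv(outdir / "concordance.csv", index=False)
        manifest.to_json(outdir / "manifest.json")
    return result
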