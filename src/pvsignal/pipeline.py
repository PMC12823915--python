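"""End-to-end driver: ingest -> screen -> replication gate -> strata -> TTO
-> scenarios, with a run manifest accounting for every record and exclusion.

The two databases are analysed in parallel and a drug advances to the
stratified and time-to-onset stages only when it meets at least one signal
criterion in *both* (the replication gate; a strict all-criteria mode is
configurable).  All stochastic stages draw their seeds from the master seed
by fixed offsets, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


import pandas as pd

from . import __version__
from .disprop import MetricResult, SignalCriteria, results_to_frame, screen
from .icsr_io import (
    DEFAULT_ROLE_FILTER,
    FAERS,
    JADER,
    EventTarget,
    PlidCase,
    build_plid,
    deduplicate_faers,
    read_tables,
    write_plid,
)
from .scenarios import negative_control_report, run_all_scenarios
from .stratify import stratified_screen, volcano_points
from .synthetic import (
    AF_PT_CODE,
    AF_PT_NAME,
    NEGATIVE_CONTROL,
    OAB_DRUGS,
    default_synonyms,
    generate,
    oab_af_config,
)
from .tto import collect_tto, fit_tto, histogram_boxplot_data, km_cumulative

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31
# fixed per-task seed offsets from the master seed
_OFFSETS = {"gen_jader": 11, "gen_faers": 23, "tto_bootstrap": 37}


def derive_seed(master_seed: int, task: str) -> int:
    return (master_seed * 1009 + _OFFSETS[task]) % _SEED_MOD


def passes_replication_gate(a: MetricResult, b: MetricResult,
                            mode: str = "any") -> bool:
    """Does a drug's pair of per-database results clear the gate?

    ``any``: at least one signal criterion met in *both* databases (the
    default reading — a drug with a signal in one database only does not
    advance); ``all``: every criterion met in both.
    """
    if mode == "any":
        return a.any_signal and b.any_signal
    if mode == "all":
        return (a.met_ror and a.met_prr and a.met_ic
                and b.met_ror and b.met_prr and b.met_ic)
    raise ValueError(f"unknown replication mode {mode!r}")


@dataclass(slots=True)
class PipelineConfig:
    """Configuration of one full run (defaults are the study conditions)."""

    mode: str = "synthetic"  # synthetic | real
    outdir: str = "results/pipeline"
    master_seed: int = 0
    drug_list: tuple[str, ...] = OAB_DRUGS
    negative_control: str = NEGATIVE_CONTROL
    event_pt_code: int = AF_PT_CODE
    event_terms: tuple[str, ...] = (AF_PT_NAME,)
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    role_filter: frozenset = DEFAULT_ROLE_FILTER
    yates: bool = True
    replication_mode: str = "any"  # any | all criteria met in both databases
    run_scenarios: bool = True
    tto_bootstrap_B: int = 10000
    tto_min_n: int = 3
    km_window_days: int = 730
    n_cases: int = 20000  # synthetic mode, per database
    rho_planted: float = 3.0
    history_plant_rate: float = 0.0
    # real mode: per-database table paths, e.g. {"JADER": {"demo": ..., ...}}
    real_paths: dict = field(default_factory=dict)

    @property
    def event_target(self) -> EventTarget:
        return EventTarget.of(self.event_pt_code, self.event_terms)


@dataclass(slots=True)
class RunManifest:
    config: dict
    version: str
    master_seed: int
    counts: dict = field(default_factory=dict)
    advanced_drugs: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _load_database(config: PipelineConfig, source_system: str
                   ) -> tuple[list[PlidCase], dict]:
    """One database's PLID plus stage counts for the manifest."""
    counts: dict = {}
    if config.mode == "synthetic":
        seed = derive_seed(config.master_seed,
                           "gen_jader" if source_system == JADER else "gen_faers")
        raw, _truth = generate(oab_af_config(
            source_system, seed, n_cases=config.n_cases,
            rho_planted=config.rho_planted,
            history_plant_rate=config.history_plant_rate))
    elif config.mode == "real":
        raw = read_tables(config.real_paths[source_system], source_system)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    counts["demo_records_read"] = len(raw.demo)
    counts["parse_issues"] = raw.parse_log.n_issues
    if source_system == FAERS:
        counts["cases_after_dedup"] = len(deduplicate_faers(raw.demo))
    else:
        counts["cases_after_dedup"] = len(raw.demo)
    plid, build_log = build_plid(raw, synonyms=default_synonyms())
    counts["plid_cases"] = len(plid)
    counts["orphan_records"] = dict(build_log.orphan_records)
    return plid, counts


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write every output table.

    Stage order: ingest/integrate per database -> primary screen (all
    drugs) -> replication gate -> stratified screen and TTO for advanced
    drugs -> sensitivity scenarios with the negative control.  Any stage
    error aborts the run with the stage named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    target = config.event_target
    manifest = RunManifest(
        config={k: v for k, v in dataclasses.asdict(config).items()
                if k != "real_paths"},
        version=__version__, master_seed=config.master_seed)

    plids: dict[str, list[PlidCase]] = {}
    primary: dict[str, pd.DataFrame] = {}
    signals: dict[str, dict[str, MetricResult]] = {}
    for db in (JADER, FAERS):
        stage = f"ingest[{db}]"
        try:
            plid, counts = _load_database(config, db)
        except Exception as exc:  # re-raise with stage context
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        plids[db] = plid
        manifest.counts[db] = counts

        stage = f"screen[{db}]"
        results = screen(plid, config.drug_list, target,
                         criteria=config.criteria,
                         role_filter=config.role_filter, yates=config.yates)
        df = results_to_frame(results)
        path = outdir / f"screen_{db}.csv"
        df.to_csv(path, index=False)
        manifest.outputs[f"screen_{db}"] = {"path": str(path), "rows": len(df)}
        primary[db] = df
        signals[db] = {r.drug: r for r in results}

    # --- replication gate ---
    advanced = [
        drug for drug in config.drug_list
        if passes_replication_gate(signals[JADER][drug], signals[FAERS][drug],
                                   config.replication_mode)
    ]
    manifest.advanced_drugs = list(advanced)
    logger.info("replication gate: %s advanced", advanced or "no drug")

    # --- stratified screening and volcano coordinates ---
    strat_rows, volcano_rows = [], []
    for db in (JADER, FAERS):
        for drug in advanced:
            results, dropped = stratified_screen(
                plids[db], drug, target, criteria=config.criteria,
                role_filter=config.role_filter, yates=config.yates)
            manifest.counts[db].setdefault("stratum_exclusions", {})[drug] = dict(dropped)
            df = results_to_frame(results)
            df.insert(0, "database", db)
            strat_rows.append(df)
            overall = [r for r in screen(plids[db], [drug], target,
                                         criteria=config.criteria,
                                         role_filter=config.role_filter,
                                         yates=config.yates)]
            pts, meta = volcano_points(overall + results)
            vdf = pd.DataFrame([dataclasses.asdict(p) for p in pts])
            if not vdf.empty:
                vdf.insert(0, "drug", drug)
                vdf.insert(0, "database", db)
                volcano_rows.append(vdf)
    if strat_rows:
        df = pd.concat(strat_rows, ignore_index=True)
        path = outdir / "stratified.csv"
        df.to_csv(path, index=False)
        manifest.outputs["stratified"] = {"path": str(path), "rows": len(df)}
    if volcano_rows:
        df = pd.concat(volcano_rows, ignore_index=True)
        path = outdir / "volcano.csv"
        df.to_csv(path, index=False)
        manifest.outputs["volcano"] = {"path": str(path), "rows": len(df)}

    # --- time-to-onset ---
    tto_rows, km_rows = [], []
    boot_seed = derive_seed(config.master_seed, "tto_bootstrap")
    for db in (JADER, FAERS):
        for drug in advanced:
            recs = collect_tto(plids[db], drug, target, db,
                               role_filter=config.role_filter)
            days = [r.days for r in recs]
            manifest.counts[db].setdefault("tto_date_complete", {})[drug] = len(days)
            if len(days) < config.tto_min_n:
                logger.info("%s/%s: only %d date-complete TTO records; skipped",
                            db, drug, len(days))
                continue
            fit = fit_tto(days, B=config.tto_bootstrap_B, seed=boot_seed)
            tto_rows.append({
                "database": db, "drug": drug, "n": fit.n,
                "median_days": fit.median_days,
                "q1_days": fit.iqr_days[0], "q3_days": fit.iqr_days[1],
                "beta": fit.shape, "beta_lo": fit.shape_ci[0],
                "beta_hi": fit.shape_ci[1], "scale_days": fit.scale,
                "failure_type": fit.failure_type,
                "pct_within_365": fit.pct_within_365,
            })
            steps, _ = km_cumulative(days, window_days=config.km_window_days)
            km_rows.extend({"database": db, "drug": drug, "t_days": t,
                            "cum_pct": c} for t, c in steps)
            hist = histogram_boxplot_data(days, window=config.km_window_days)
            (outdir / f"tto_hist_{db}_{drug}.json").write_text(
                json.dumps(hist, indent=2))
    if tto_rows:
        df = pd.DataFrame(tto_rows)
        path = outdir / "tto_summary.csv"
        df.to_csv(path, index=False)
        manifest.outputs["tto_summary"] = {"path": str(path), "rows": len(df)}
    if km_rows:
        df = pd.DataFrame(km_rows)
        path = outdir / "km_curves.csv"
        df.to_csv(path, index=False)
        manifest.outputs["km_curves"] = {"path": str(path), "rows": len(df)}

    # --- sensitivity scenarios + negative control ---
    if config.run_scenarios:
        all_rows = []
        for db in (JADER, FAERS):
            tables = run_all_scenarios(
                plids[db], config.drug_list, target, db,
                base_criteria=config.criteria, stratified_drugs=advanced,
                yates=config.yates)
            for sid, df in tables.items():
                df = df.copy()
                df.insert(0, "database", db)
                path = outdir / f"scenario_{sid}_{db}.csv"
                df.to_csv(path, index=False)
                manifest.outputs[f"scenario_{sid}_{db}"] = {
                    "path": str(path), "rows": len(df)}
                all_rows.append(df)
        combined = pd.concat(all_rows, ignore_index=True)
        nc = negative_control_report(combined, config.negative_control)
        ncpath = outdir / "negative_control.json"
        ncpath.write_text(json.dumps({
            "control_drug": nc["control_drug"],
            "overall_flag": nc["overall_flag"],
            "grid": nc["grid"].to_dict("records"),
        }, indent=2))
        manifest.outputs["negative_control"] = {
            "path": str(ncpath), "rows": len(nc["grid"])}

    # --- PLID snapshots and manifest ---
    for db in (JADER, FAERS):
        path = outdir / f"plid_{db}.tsv"
        write_plid(plids[db], path)
        manifest.outputs[f"plid_{db}"] = {"path": str(path),
                                          "rows": len(plids[db])}
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
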