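"""Sensitivity scenarios and the negative-control track.

The screening and stratified analyses are repeated under three alternative
specifications and compared with the main one:

* ``prr_conventional`` — the conventional PRR criterion (PRR025 > 1 with
  chi2 > 4) instead of the stringent main threshold of 2;
* ``primary_suspected_only`` — exposure restricted to primary-suspected
  drug records (in a JADER-style source, whose role vocabulary has a single
  suspected category, that category plays the primary-suspected part);
* ``history_indication_excluded`` — cases with the target event in their
  medical history (JADER HIST) or listed as a treatment indication (FAERS
  INDI) are dropped before table construction.

A designated negative-control drug runs through every scenario with the
same handling and thresholds as the targets; its report summarizes whether
any criterion was met anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .disprop import (
    DEFAULT_ROLE_FILTER,
    MetricResult,
    SignalCriteria,
    results_to_frame,
    screen,
)
from .icsr_io import (
    FAERS,
    JADER,
    PRIMARY_SUSPECTED,
    SUSPECTED,
    EventTarget,
    PlidCase,
)
from .stratify import stratified_screen

MAIN = "main"
PRR_CONVENTIONAL = "prr_conventional"
PRIMARY_SUSPECTED_ONLY = "primary_suspected_only"
HISTORY_INDICATION_EXCLUDED = "history_indication_excluded"
SCENARIO_IDS = (MAIN, PRR_CONVENTIONAL, PRIMARY_SUSPECTED_ONLY,
                HISTORY_INDICATION_EXCLUDED)

EXCL_PRIOR_HISTORY = "prior_event_history"  # JADER HIST
EXCL_EVENT_INDICATION = "event_as_indication"  # FAERS INDI


@dataclass(slots=True, frozen=True)
class ScenarioSpec:
    id: str
    criteria: SignalCriteria
    role_filter: frozenset = DEFAULT_ROLE_FILTER
    exclusion_rule: str | None = None  # None / prior_event_history / event_as_indication


def scenario_specs(base: SignalCriteria = SignalCriteria(),
                   source_system: str | None = None) -> list[ScenarioSpec]:
    """The four pre-specified scenarios for one source system.

    The exclusion scenario picks the history rule for JADER-style sources
    and the indication rule for FAERS-style sources.
    """
    if source_system == JADER:
        excl = EXCL_PRIOR_HISTORY
    elif source_system == FAERS:
        excl = EXCL_EVENT_INDICATION
    else:
        raise ValueError(f"source system required, got {source_system!r}")
    primary_roles = frozenset(
        {PRIMARY_SUSPECTED} if source_system == FAERS else {SUSPECTED})
    return [
        ScenarioSpec(MAIN, base),
        ScenarioSpec(PRR_CONVENTIONAL, replace(base, prr_lower_gt=1.0)),
        ScenarioSpec(PRIMARY_SUSPECTED_ONLY, base, role_filter=primary_roles),
        ScenarioSpec(HISTORY_INDICATION_EXCLUDED, base, exclusion_rule=excl),
    ]


def apply_exclusion(plid: Sequence[PlidCase], rule: str | None,
                    target: EventTarget, source_system: str
                    ) -> tuple[list[PlidCase], int]:
    """Drop cases matching the exclusion rule; returns (kept, n_dropped)."""
    if rule is None:
        return list(plid), 0
    if rule == EXCL_PRIOR_HISTORY:
        if source_system != JADER:
            raise ValueError(
                "prior-event-history exclusion requires a HIST table "
                f"(JADER); source is {source_system}")
        terms = lambda c: c.history_terms  # noqa: E731
    elif rule == EXCL_EVENT_INDICATION:
        if source_system != FAERS:
            raise ValueError(
                "event-as-indication exclusion requires an INDI table "
                f"(FAERS); source is {source_system}")
        terms = lambda c: c.indication_terms  # noqa: E731
    else:
        raise ValueError(f"unknown exclusion rule {rule!r}")
    kept = [c for c in plid if not any(target.matches_pair(t) for t in terms(c))]
    return kept, len(plid) - len(kept)


def run_scenario(plid: Sequence[PlidCase], spec: ScenarioSpec,
                 drug_list: Sequence[str], target: EventTarget,
                 source_system: str,
                 stratified_drugs: Sequence[str] = (),
                 yates: bool = True) -> pd.DataFrame:
    """One scenario: overall screening for every drug, stratified screening
    for the requested drugs, all under the scenario's criteria, role filter
    and exclusion rule.  The shared PLID is never mutated."""
    kept, n_dropped = apply_exclusion(plid, spec.exclusion_rule, target,
                                      source_system)
    results: list[MetricResult] = list(screen(
        kept, drug_list, target, criteria=spec.criteria,
        role_filter=spec.role_filter, yates=yates))
    for drug in stratified_drugs:
        strat, _ = stratified_screen(
            kept, drug, target, criteria=spec.criteria,
            role_filter=spec.role_filter, yates=yates)
        results.extend(strat)
    df = results_to_frame(results)
    df.insert(0, "scenario", spec.id)
    df.attrs["n_excluded_cases"] = n_dropped
    return df


def run_all_scenarios(plid: Sequence[PlidCase], drug_list: Sequence[str],
                      target: EventTarget, source_system: str,
                      base_criteria: SignalCriteria = SignalCriteria(),
                      stratified_drugs: Sequence[str] = (),
                      yates: bool = True) -> dict[str, pd.DataFrame]:
    """All four scenarios as a scenario-id -> table mapping (the delimited
    'workbook': one sheet-like file per scenario when written out)."""
    return {
        spec.id: run_scenario(plid, spec, drug_list, target, source_system,
                              stratified_drugs=stratified_drugs, yates=yates)
        for spec in scenario_specs(base_criteria, source_system)
    }


def negative_control_report(results: pd.DataFrame, control_drug: str) -> dict:
    """Per-scenario/stratum signal grid for the negative control.

    ``results`` is a concatenation of scenario tables (columns ``scenario``,
    ``drug``, ``variable``, ``level``, ``met_*``).  Returns the grid plus a
    single overall flag: True iff the control met any criterion anywhere.
    Excluded (low-count) rows are non-signals.
    """
    sub = results[results["drug"] == control_drug]
    if sub.empty:
        raise ValueError(f"negative control {control_drug!r} absent from results")
    grid = sub[["scenario", "variable", "level",
                "met_ROR", "met_PRR", "met_IC"]].copy()
    grid["any_signal"] = grid[["met_ROR", "met_PRR", "met_IC"]].any(axis=1)
    return {
        "control_drug": control_drug,
        "grid": grid.reset_index(drop=True),
        "overall_flag": bool(grid["any_signal"].any()),
    }
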