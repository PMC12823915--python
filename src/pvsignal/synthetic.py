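"""Synthetic spontaneous-report generator with planted ground truth.

Emulates the relational structure of JADER-style and FAERS-style extracts —
versioned case identifiers, drug rows with role codes and sequence numbers,
reaction rows with MedDRA PT fields, therapy start dates, decade-band or
integer ages — while controlling the quantities the downstream analyses
estimate: per drug-event reporting-rate ratios, stratum composition,
Weibull-distributed onset times, and missing-date mechanisms.

Generative model, per case and independently across cases:

* demographics: sex and age band from configured proportions; the maximum
  drug sequence number (medication count proxy) from a configured
  distribution;
* exposures: each catalogued drug independently with its marginal
  probability; remaining sequence slots are filled with background
  co-medications;
* the target event is reported with probability ``baseline * rho`` (capped
  at 1) for cases exposed to an associated drug — when several associated
  drugs are co-reported the largest rho applies — and ``baseline``
  otherwise;
* onset dates for planted drug-event pairs are the therapy start plus a
  Weibull(shape, scale) draw rounded half-up to whole days (the downstream
  +1-day convention is applied by the TTO extractor, not here);
* missingness is applied last, so the ground truth is complete.

Identical configurations produce byte-identical output (seeded).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from .icsr_io import (
    CONCOMITANT,
    FAERS,
    INTERACTING,
    PRIMARY_SUSPECTED,
    SUSPECTED,
    DemoRecord,
    DrugRecord,
    HistRecord,
    IndiRecord,
    RawTables,
    ReacRecord,
    TherRecord,
)

logger = logging.getLogger(__name__)

_EPOCH = date(2015, 1, 1)
_WINDOW_DAYS = 3000  # therapy starts drawn uniformly over this window

#: background reaction attached to every report so the reaction table is
#: never empty for a case (reports always carry at least one event)
BACKGROUND_PT = (99000001, "Drug ineffective")


@dataclass(slots=True, frozen=True)
class DrugSpec:
    name: str
    p_exposure: float


@dataclass(slots=True, frozen=True)
class EventSpec:
    pt_code: int
    name: str
    baseline: float  # report probability absent any associated exposure


@dataclass(slots=True, frozen=True)
class Association:
    drug: str
    event: str
    rho: float  # reporting-rate ratio (>= 0)


@dataclass(slots=True)
class SyntheticConfig:
    """Full description of one synthetic database draw."""

    n_cases: int
    seed: int
    dialect: str  # JADER or FAERS
    drug_catalog: tuple[DrugSpec, ...]
    event_catalog: tuple[EventSpec, ...]
    associations: tuple[Association, ...] = ()
    # strata mix
    sex_probs: tuple[float, float] = (0.35, 0.65)  # male, female
    age_band_probs: Mapping[str, float] = field(default_factory=lambda: {
        "20s": 0.04, "30s": 0.06, "40s": 0.10, "50s": 0.15,
        "60s": 0.20, "70s": 0.25, "80s": 0.15, "90s": 0.05,
    })
    med_count_probs: Mapping[int, float] = field(default_factory=lambda: {
        1: 0.25, 2: 0.17, 3: 0.13, 4: 0.11, 5: 0.10,
        6: 0.08, 7: 0.07, 8: 0.05, 9: 0.02, 10: 0.02,
    })
    # Weibull onset model per (drug, event): (shape, scale in days)
    tto_model: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict)
    # missingness probabilities
    p_missing_start: float = 0.3
    p_missing_onset: float = 0.3
    p_missing_sex: float = 0.05
    p_missing_age: float = 0.1
    faers_version_dup_rate: float = 0.1
    # role assignment for catalogued drugs: suspected / concomitant / interacting
    role_probs: tuple[float, float, float] = (0.7, 0.25, 0.05)
    # among "suspected", fraction coded primary-suspected (FAERS PS vs SS)
    p_primary_within_suspected: float = 0.7
    # fraction of event-positive cases planted with a prior-event history
    # (JADER HIST) or event-as-indication (FAERS INDI) entry
    history_plant_rate: float = 0.0

    def __post_init__(self):
        probs = [self.p_missing_start, self.p_missing_onset,
                 self.p_missing_sex, self.p_missing_age,
                 self.faers_version_dup_rate, self.history_plant_rate,
                 *(d.p_exposure for d in self.drug_catalog),
                 *(e.baseline for e in self.event_catalog)]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(a.rho < 0 for a in self.associations):
            raise ValueError("reporting-rate ratios must be >= 0")
        for (b, lam) in self.tto_model.values():
            if b <= 0 or lam <= 0:
                raise ValueError("Weibull shape and scale must be positive")
        for name, tot in (("sex", sum(self.sex_probs)),
                          ("age band", sum(self.age_band_probs.values())),
                          ("med count", sum(self.med_count_probs.values()))):
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")

    def drug(self, name: str) -> DrugSpec:
        for d in self.drug_catalog:
            if d.name == name:
                return d
        raise KeyError(f"unknown drug {name!r}")

    def event(self, name: str) -> EventSpec:
        for e in self.event_catalog:
            if e.name == name:
                return e
        raise KeyError(f"unknown event {name!r}")


@dataclass(slots=True)
class GroundTruth:
    """What the generator actually planted, for oracle-style checks."""

    case_ids: list[str]
    exposure: dict[str, np.ndarray]  # drug name -> bool per case
    events: dict[str, np.ndarray]  # event name -> bool per case
    strata: pd.DataFrame  # case_id, sex, age_level, med_count (pre-missingness)
    tto_true: dict[tuple[str, str], tuple[float, float]]
    tto_days: dict[tuple[str, str], np.ndarray]  # planted day counts (pre +1)
    expected_cells: dict[tuple[str, str], tuple[float, float, float, float]]


# ---------------------------------------------------------------------------
# closed-form expectations
# ---------------------------------------------------------------------------


def _event_prob_given(config: SyntheticConfig, event: str,
                      fixed: Mapping[str, bool]) -> float:
    """E[min(1, baseline * max rho of exposed associated drugs)], with the
    exposure status of the drugs in ``fixed`` conditioned on."""
    ev = config.event(event)
    assoc = [a for a in config.associations if a.event == event]
    free = [a for a in assoc if a.drug not in fixed]
    fixed_rhos = [a.rho for a in assoc if fixed.get(a.drug)]
    # enumerate exposure subsets of the free associated drugs (few of them)
    total = 0.0
    m = len(free)
    for mask in range(1 << m):
        p = 1.0
        rhos = list(fixed_rhos)
        for i, a in enumerate(free):
            pe = config.drug(a.drug).p_exposure
            if mask >> i & 1:
                p *= pe
                rhos.append(a.rho)
            else:
                p *= 1 - pe
        factor = max(rhos) if rhos else 1.0
        total += p * min(1.0, ev.baseline * factor)
    return total


def expected_contingency(config: SyntheticConfig, drug: str, event: str
                         ) -> tuple[float, float, float, float]:
    """Closed-form expected (n11, n12, n21, n22) under the generative model."""
    d = config.drug(drug)  # raises on unknown drug
    config.event(event)  # raises on unknown event
    n = config.n_cases
    p_ev_exposed = _event_prob_given(config, event, {drug: True})
    p_ev_unexposed = _event_prob_given(config, event, {drug: False})
    e11 = n * d.p_exposure * p_ev_exposed
    e12 = n * d.p_exposure - e11
    e21 = n * (1 - d.p_exposure) * p_ev_unexposed
    e22 = n * (1 - d.p_exposure) - e21
    return e11, e12, e21, e22


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def generate(config: SyntheticConfig, assemble_tables: bool = True
             ) -> tuple[RawTables, GroundTruth]:
    """Draw one synthetic database according to the configuration.

    ``assemble_tables=False`` skips building the relational records and
    returns an empty :class:`RawTables` alongside the full ground truth —
    useful for calibration studies that only consume the truth arrays (the
    truth is drawn first, so it is identical either way).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    is_faers = config.dialect == FAERS

    case_ids = [f"C{i:07d}" for i in range(1, n + 1)]

    # --- demographics (truth, before missingness) ---
    sex_true = np.where(rng.random(n) < config.sex_probs[0], "male", "female")
    bands = list(config.age_band_probs)
    band_idx = rng.choice(len(bands), size=n, p=list(config.age_band_probs.values()))
    band_true = np.array(bands)[band_idx]
    decade = np.array([int(b[:-1]) for b in bands])[band_idx]
    age_true = decade + rng.integers(0, 10, size=n)
    ks = list(config.med_count_probs)
    med_count = np.array(ks)[rng.choice(
        len(ks), size=n, p=list(config.med_count_probs.values()))]

    # --- exposures ---
    exposure: dict[str, np.ndarray] = {
        d.name: rng.random(n) < d.p_exposure for d in config.drug_catalog
    }

    # --- events ---
    events: dict[str, np.ndarray] = {}
    for ev in config.event_catalog:
        # rate factor: max rho over the exposed associated drugs, 1 if none
        assoc_max = np.full(n, -np.inf)
        any_assoc = np.zeros(n, dtype=bool)
        for a in config.associations:
            if a.event != ev.name:
                continue
            m = exposure[a.drug]
            assoc_max = np.where(m, np.maximum(assoc_max, a.rho), assoc_max)
            any_assoc |= m
        factor = np.where(any_assoc, assoc_max, 1.0)
        p = ev.baseline * factor
        if np.any(p > 1):
            warnings.warn(
                f"event {ev.name!r}: reporting probability capped at 1 "
                f"(max uncapped {p.max():.3f})")
            p = np.minimum(p, 1.0)
        events[ev.name] = rng.random(n) < p

    # --- therapy start dates (complete truth) ---
    start_ord: dict[str, np.ndarray] = {}
    epoch = _EPOCH.toordinal()
    for d in config.drug_catalog:
        start_ord[d.name] = epoch + rng.integers(0, _WINDOW_DAYS, size=n)

    # --- planted onset days ---
    tto_days: dict[tuple[str, str], np.ndarray] = {}
    onset_ord: dict[str, np.ndarray] = {}  # per event, the case's onset date
    for ev in config.event_catalog:
        onset = epoch + rng.integers(0, _WINDOW_DAYS, size=n)  # background
        for (dname, ename), (shape, scale) in config.tto_model.items():
            if ename != ev.name:
                continue
            mask = exposure[dname] & events[ev.name]
            draw = scale * rng.weibull(shape, size=int(mask.sum()))
            dd = _round_half_up(draw).astype(int)
            tto_days[(dname, ename)] = dd
            onset[mask] = start_ord[dname][mask] + dd
        onset_ord[ev.name] = onset

    # --- missingness masks ---
    sex_obs = np.where(rng.random(n) < config.p_missing_sex, "unknown", sex_true)
    age_missing = rng.random(n) < config.p_missing_age
    start_missing: dict[str, np.ndarray] = {
        d.name: rng.random(n) < config.p_missing_start for d in config.drug_catalog
    }
    onset_missing: dict[str, np.ndarray] = {
        ev.name: rng.random(n) < config.p_missing_onset for ev in config.event_catalog
    }

    # --- roles for catalogued drugs ---
    role_draw: dict[str, np.ndarray] = {}
    su, co, inter = config.role_probs
    for d in config.drug_catalog:
        u = rng.random(n)
        roles = np.where(u < su, SUSPECTED,
                         np.where(u < su + co, CONCOMITANT, INTERACTING))
        if is_faers:
            ps = rng.random(n) < config.p_primary_within_suspected
            roles = np.where((roles == SUSPECTED) & ps, PRIMARY_SUSPECTED, roles)
        role_draw[d.name] = roles

    # --- versioning (FAERS) ---
    dup_mask = (rng.random(n) < config.faers_version_dup_rate) if is_faers \
        else np.zeros(n, dtype=bool)

    # --- history / indication planting ---
    plant: dict[str, np.ndarray] = {}
    for ev in config.event_catalog:
        plant[ev.name] = events[ev.name] & (
            rng.random(n) < config.history_plant_rate)

    # --- assemble records ---
    raw = RawTables(source_system=config.dialect)
    catalog_names = [d.name for d in config.drug_catalog]
    exp_mat = np.column_stack([exposure[nm] for nm in catalog_names])
    n_exposed = exp_mat.sum(axis=1)
    total_rows = np.maximum(med_count, n_exposed)
    ev_names = [e.name for e in config.event_catalog]
    ev_specs = {e.name: e for e in config.event_catalog}

    ord_to_date = date.fromordinal
    for i in range(n if assemble_tables else 0):
        cid = case_ids[i]
        version = 2 if dup_mask[i] else 1
        rid = f"{cid}-{version}" if is_faers else cid
        band = None if age_missing[i] else str(band_true[i])
        age_years = None if age_missing[i] else int(age_true[i])
        # FAERS event date: earliest reported event onset
        ev_dates = [
            onset_ord[e][i] for e in ev_names
            if events[e][i] and not onset_missing[e][i]
        ]
        event_date = ord_to_date(int(min(ev_dates))) if (is_faers and ev_dates) else None
        raw.demo.append(DemoRecord(
            case_id=cid, report_id=rid, case_version=version if is_faers else 0,
            sex=str(sex_obs[i]),
            age_years=age_years if is_faers else None,
            age_band=band if not is_faers else None,
            event_date=event_date,
        ))
        if dup_mask[i]:
            raw.demo.append(DemoRecord(
                case_id=cid, report_id=f"{cid}-1", case_version=1,
                sex=str(sex_obs[i]),
                age_years=age_years if is_faers else None,
                age_band=band if not is_faers else None,
                event_date=event_date,
            ))

        # drug rows: catalogued exposures in shuffled sequence slots, the
        # rest filled with background co-medications
        k = int(total_rows[i])
        seqs = rng.permutation(k) + 1
        slot = 0
        for j, nm in enumerate(catalog_names):
            if not exp_mat[i, j]:
                continue
            seq = int(seqs[slot]); slot += 1
            sdate = None if start_missing[nm][i] else ord_to_date(int(start_ord[nm][i]))
            raw.drug.append(DrugRecord(
                case_id=rid, drug_name_raw=nm.upper(),
                role=str(role_draw[nm][i]), drug_seq=seq,
                start_date=None if is_faers else sdate,
            ))
            if is_faers and sdate is not None:
                raw.ther.append(TherRecord(case_id=rid, drug_seq=seq,
                                           start_date=sdate))
        for f in range(k - int(n_exposed[i])):
            seq = int(seqs[slot]); slot += 1
            raw.drug.append(DrugRecord(
                case_id=rid, drug_name_raw=f"CO-DRUG-{(i + f) % 97:02d}",
                role=CONCOMITANT, drug_seq=seq, start_date=None,
            ))

        # reaction rows: every report carries a background reaction; target
        # events add their own rows
        raw.reac.append(ReacRecord(
            case_id=rid,
            pt_code=None if is_faers else BACKGROUND_PT[0],
            pt_name=BACKGROUND_PT[1], onset_date=None,
        ))
        for e in ev_names:
            if not events[e][i]:
                continue
            spec = ev_specs[e]
            odate = None
            if not is_faers and not onset_missing[e][i]:
                odate = ord_to_date(int(onset_ord[e][i]))
            raw.reac.append(ReacRecord(
                case_id=rid,
                pt_code=None if is_faers else spec.pt_code,
                pt_name=spec.name,
                onset_date=odate,
            ))
            if plant[e][i]:
                if is_faers:
                    raw.indi.append(IndiRecord(case_id=rid, drug_seq=None,
                                               pt_code=None, term=spec.name))
                else:
                    raw.hist.append(HistRecord(case_id=rid, pt_code=None,
                                               term=spec.name))

    age_level = np.where((age_true >= 20) & (age_true <= 69), "y20_69",
                         np.where((age_true >= 70) & (age_true <= 99),
                                  "y70_99", "excluded"))
    truth = GroundTruth(
        case_ids=case_ids,
        exposure=exposure,
        events=events,
        strata=pd.DataFrame({
            "case_id": case_ids,
            "sex": sex_true,
            "age_level": age_level,
            "med_count": total_rows,
        }),
        tto_true=dict(config.tto_model),
        tto_days=tto_days,
        expected_cells={
            (a.drug, a.event): expected_contingency(config, a.drug, a.event)
            for a in config.associations
        },
    )
    return raw, truth


# ---------------------------------------------------------------------------
# the study configuration: eight screened drugs plus a negative control
# ---------------------------------------------------------------------------

OAB_DRUGS = (
    "oxybutynin", "propiverine", "solifenacin", "imidafenacin",
    "tolterodine", "fesoterodine", "mirabegron", "vibegron",
)
NEGATIVE_CONTROL = "vibegron"
PLANTED_DRUGS = ("solifenacin", "mirabegron")
AF_PT_CODE = 10003658
AF_PT_NAME = "Atrial fibrillation"


def oab_af_config(dialect: str, seed: int, n_cases: int = 20000,
                  rho_planted: float = 3.0,
                  history_plant_rate: float = 0.0) -> SyntheticConfig:
    """The default study conditions for one database draw.

    Two drugs carry a planted reporting-rate ratio of 3 for the target
    event; the other six, including the designated negative control, report
    it at the baseline rate (rho = 1).  Onset times for the planted pairs
    follow Weibull(0.56, 120 days), an early-failure pattern.
    """
    drugs = tuple(DrugSpec(nm, 0.03) for nm in OAB_DRUGS)
    event = EventSpec(AF_PT_CODE, AF_PT_NAME, baseline=0.015)
    assoc = tuple(
        Association(nm, AF_PT_NAME, rho_planted if nm in PLANTED_DRUGS else 1.0)
        for nm in OAB_DRUGS
    )
    tto = {(nm, AF_PT_NAME): (0.56, 120.0) for nm in PLANTED_DRUGS}
    return SyntheticConfig(
        n_cases=n_cases, seed=seed, dialect=dialect,
        drug_catalog=drugs, event_catalog=(event,), associations=assoc,
        tto_model=tto, history_plant_rate=history_plant_rate,
    )


def default_synonyms() -> dict[str, str]:
    """Synonym dictionary matching the generator's raw drug-name casing."""
    return {nm: nm for nm in OAB_DRUGS}


def config_from_file(path) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a structured (YAML) text file.

    Sections mirror the dataclass: scalars at the top level; ``drugs`` as a
    name -> exposure-probability map; ``events`` as a list of
    ``{pt_code, name, baseline}``; ``associations`` as a list of
    ``{drug, event, rho}``; ``tto`` as a list of
    ``{drug, event, shape, scale}``.
    """
    import yaml

    raw = yaml.safe_load(open(path, encoding="utf-8"))
    drugs = tuple(DrugSpec(k, float(v)) for k, v in raw.pop("drugs").items())
    events = tuple(EventSpec(int(e["pt_code"]), e["name"], float(e["baseline"]))
                   for e in raw.pop("events"))
    assoc = tuple(Association(a["drug"], a["event"], float(a["rho"]))
                  for a in raw.pop("associations", []))
    tto = {(t["drug"], t["event"]): (float(t["shape"]), float(t["scale"]))
           for t in raw.pop("tto", [])}
    for key in ("sex_probs", "role_probs"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticConfig(drug_catalog=drugs, event_catalog=events,
                           associations=assoc, tto_model=tto, **raw)
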