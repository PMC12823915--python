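"""Reading, deduplicating and integrating individual case safety reports.

Spontaneous reporting systems publish quarterly relational extracts: a
demographics table keyed by a case identifier, plus drug, reaction and
auxiliary tables keyed to the same identifier.  Two dialects are supported:

* **JADER-style** — comma-separated tables (demo/drug/reac/hist); one row per
  case in demo (no versioning); ages published as decade bands ("20s" ... "90s").
* **FAERS-style** — ``$``-delimited ASCII tables (DEMO/DRUG/REAC/THER/OUTC/INDI);
  a case may appear under several ``caseversion`` values and only the latest
  version is analysed; therapy start dates live in THER keyed by drug sequence
  number, and the event date lives in DEMO.

The output of this module is the patient-level integrated dataset (PLID):
exactly one :class:`PlidCase` per retained case, carrying the merged drug
exposures, reported events, and history/indication terms.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

JADER = "JADER"
FAERS = "FAERS"

# canonical drug-role vocabulary
PRIMARY_SUSPECTED = "primary_suspected"
SUSPECTED = "suspected"
CONCOMITANT = "concomitant"
INTERACTING = "interacting"
UNKNOWN_ROLE = "unknown"
ROLES = (PRIMARY_SUSPECTED, SUSPECTED, CONCOMITANT, INTERACTING, UNKNOWN_ROLE)

#: roles counted as exposure in the main analysis (suspected, concomitant or
#: interacting, i.e. everything except unclassifiable roles)
DEFAULT_ROLE_FILTER = frozenset(
    {PRIMARY_SUSPECTED, SUSPECTED, CONCOMITANT, INTERACTING}
)

_WS = re.compile(r"\s+")


def normalize_term(s: str) -> str:
    """Trim, collapse internal whitespace and casefold a free-text term."""
    return _WS.sub(" ", s.strip()).casefold()


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(slots=True, frozen=True)
class DemoRecord:
    case_id: str
    report_id: str
    case_version: int = 0
    sex: str = "unknown"  # male / female / unknown
    age_years: int | None = None
    age_band: str | None = None  # decade band, e.g. "20s" (JADER)
    event_date: date | None = None  # FAERS event date (used for TTO)


@dataclass(slots=True, frozen=True)
class DrugRecord:
    case_id: str
    drug_name_raw: str
    drug_name_std: str | None = None
    role: str = UNKNOWN_ROLE
    drug_seq: int = 1
    start_date: date | None = None


@dataclass(slots=True, frozen=True)
class ReacRecord:
    case_id: str
    pt_code: int | None = None
    pt_name: str = ""
    onset_date: date | None = None


@dataclass(slots=True, frozen=True)
class HistRecord:
    case_id: str
    pt_code: int | None = None
    term: str = ""


@dataclass(slots=True, frozen=True)
class IndiRecord:
    case_id: str
    drug_seq: int | None = None
    pt_code: int | None = None
    term: str = ""


@dataclass(slots=True, frozen=True)
class TherRecord:
    case_id: str
    drug_seq: int
    start_date: date | None = None


@dataclass(slots=True, frozen=True)
class OutcRecord:
    case_id: str
    outcome_code: str = ""


@dataclass(slots=True)
class ParseLog:
    """Tallies of parse issues encountered while reading raw tables."""

    partial_dates: int = 0
    bad_dates: int = 0
    bad_ages: int = 0
    empty_tables: list[str] = field(default_factory=list)
    notes: Counter = field(default_factory=Counter)

    @property
    def n_issues(self) -> int:
        return self.partial_dates + self.bad_dates + self.bad_ages


@dataclass(slots=True)
class RawTables:
    """Relational bundle of one database extract."""

    source_system: str
    demo: list[DemoRecord] = field(default_factory=list)
    drug: list[DrugRecord] = field(default_factory=list)
    reac: list[ReacRecord] = field(default_factory=list)
    hist: list[HistRecord] = field(default_factory=list)
    indi: list[IndiRecord] = field(default_factory=list)
    ther: list[TherRecord] = field(default_factory=list)
    outc: list[OutcRecord] = field(default_factory=list)
    parse_log: ParseLog = field(default_factory=ParseLog)


# ---------------------------------------------------------------------------
# date / age parsing
# ---------------------------------------------------------------------------


def parse_complete_date(value: str | None, log: ParseLog | None = None) -> date | None:
    """Parse a complete year-month-day date; anything partial maps to missing.

    Accepts ``YYYYMMDD`` and ``YYYY-MM-DD`` / ``YYYY/MM/DD``.  Partial inputs
    (``YYYY`` or ``YYYYMM``) are counted in the parse log and return ``None``
    — a partial date must never become a sentinel date.
    """
    if value is None:
        return None
    s = value.strip().replace("-", "").replace("/", "")
    if not s:
        return None
    if not s.isdigit():
        if log is not None:
            log.bad_dates += 1
        return None
    if len(s) in (4, 6):  # year-only or year-month
        if log is not None:
            log.partial_dates += 1
        return None
    if len(s) != 8:
        if log is not None:
            log.bad_dates += 1
        return None
    try:
        return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        if log is not None:
            log.bad_dates += 1
        return None


_AGE_UNIT_YEARS = {"yr": 1.0, "year": 1.0, "years": 1.0, "": 1.0}
_AGE_UNIT_FRACT = {"mon": 12.0, "month": 12.0, "wk": 52.0, "week": 52.0, "dy": 365.25, "day": 365.25, "hr": 8766.0}
_DECADE_BAND = re.compile(r"^(\d{1,3})\s*s$", re.IGNORECASE)


def parse_age_years(value: str | None, unit: str | None = None,
                    log: ParseLog | None = None) -> int | None:
    """Normalize a FAERS (value, unit) age pair to integer years (floor)."""
    if value is None:
        return None
    s = value.strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        if log is not None:
            log.bad_ages += 1
        return None
    u = (unit or "").strip().casefold()
    if u in _AGE_UNIT_YEARS:
        years = v
    elif u in _AGE_UNIT_FRACT:
        years = v / _AGE_UNIT_FRACT[u]
    elif u == "dec":
        years = v * 10.0
    else:
        if log is not None:
            log.bad_ages += 1
        return None
    if years < 0:
        if log is not None:
            log.bad_ages += 1
        return None
    return int(years)


def parse_age_band(value: str | None) -> str | None:
    """Normalize a decade-band string ("20s", "20 s") to canonical "20s"."""
    if value is None:
        return None
    m = _DECADE_BAND.match(value.strip())
    if not m:
        return None
    return f"{int(m.group(1))}s"


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class DialectConfig:
    """File conventions and column mappings for one source system.

    ``columns`` maps, per table, each logical field to the physical column
    name; ``role_map`` maps raw role codes to the canonical role vocabulary.
    """

    source_system: str
    delimiter: str
    encoding: str = "utf-8"
    columns: dict[str, dict[str, str]] = field(default_factory=dict)
    role_map: dict[str, str] = field(default_factory=dict)
    sex_map: dict[str, str] = field(default_factory=dict)


def faers_dialect() -> DialectConfig:
    return DialectConfig(
        source_system=FAERS,
        delimiter="$",
        columns={
            "demo": {
                "report_id": "primaryid",
                "case_id": "caseid",
                "case_version": "caseversion",
                "sex": "sex",
                "age": "age",
                "age_unit": "age_cod",
                "event_date": "event_dt",
            },
            "drug": {
                "report_id": "primaryid",
                "drug_seq": "drug_seq",
                "drug_name": "drugname",
                "role": "role_cod",
            },
            "reac": {"report_id": "primaryid", "pt_name": "pt"},
            "ther": {
                "report_id": "primaryid",
                "drug_seq": "dsg_drug_seq",
                "start_date": "start_dt",
            },
            "indi": {
                "report_id": "primaryid",
                "drug_seq": "indi_drug_seq",
                "term": "indi_pt",
            },
            "outc": {"report_id": "primaryid", "outcome_code": "outc_cod"},
        },
        role_map={"PS": PRIMARY_SUSPECTED, "SS": SUSPECTED, "C": CONCOMITANT, "I": INTERACTING},
        sex_map={"M": "male", "F": "female"},
    )


def jader_dialect(encoding: str = "utf-8") -> DialectConfig:
    # Column names are configurable; the defaults below are the ASCII logical
    # names used by the synthetic writer.  Real JADER extracts use Japanese
    # headers (and CP932 encoding): pass a translated mapping and encoding.
    return DialectConfig(
        source_system=JADER,
        delimiter=",",
        encoding=encoding,
        columns={
            "demo": {"case_id": "case_id", "sex": "sex", "age_band": "age"},
            "drug": {
                "case_id": "case_id",
                "drug_name": "drug_name",
                "role": "role",
                "drug_seq": "drug_seq",
                "start_date": "start_date",
            },
            "reac": {
                "case_id": "case_id",
                "pt_code": "pt_code",
                "pt_name": "pt_name",
                "onset_date": "onset_date",
            },
            "hist": {"case_id": "case_id", "term": "term"},
        },
        role_map={
            "被疑薬": SUSPECTED,
            "併用薬": CONCOMITANT,
            "相互作用": INTERACTING,
            "suspected": SUSPECTED,
            "concomitant": CONCOMITANT,
            "interacting": INTERACTING,
        },
        sex_map={"男性": "male", "女性": "female", "male": "male", "female": "female", "M": "male", "F": "female"},
    )


def dialect_for(source_system: str) -> DialectConfig:
    if source_system == FAERS:
        return faers_dialect()
    if source_system == JADER:
        return jader_dialect()
    raise ValueError(f"unknown source system: {source_system!r}")


# ---------------------------------------------------------------------------
# table reading
# ---------------------------------------------------------------------------


def _read_frame(path: str | Path, cfg: DialectConfig, table: str,
                mandatory: Sequence[str], log: ParseLog) -> pd.DataFrame | None:
    colmap = cfg.columns.get(table, {})
    try:
        df = pd.read_csv(path, sep=cfg.delimiter, dtype=str, encoding=cfg.encoding,
                         keep_default_na=False, engine="python")
    except pd.errors.EmptyDataError:
        logger.warning("table %s at %s is empty", table, path)
        log.empty_tables.append(table)
        return None
    for logical in mandatory:
        col = colmap.get(logical, logical)
        if col not in df.columns:
            raise ValueError(
                f"table {table!r}: mandatory column {col!r} (field {logical!r}) missing"
            )
    return df


def _get(row, colmap: Mapping[str, str], field_name: str) -> str | None:
    col = colmap.get(field_name)
    if col is None:
        return None
    v = row.get(col)
    if v is None:
        return None
    v = str(v).strip()
    return v or None


def _to_int(v: str | None, default: int | None = None) -> int | None:
    if v is None:
        return default
    try:
        return int(float(v))
    except ValueError:
        return default


def read_tables(paths: Mapping[str, str | Path], source_system: str,
                dialect: DialectConfig | None = None) -> RawTables:
    """Read raw relational tables into domain records.

    ``paths`` maps table names (``demo``, ``drug``, ``reac``, and optionally
    ``hist``/``indi``/``ther``/``outc``) to files.  Unparseable dates map to
    missing, never to a sentinel; a parse log rides on the returned bundle.
    """
    cfg = dialect or dialect_for(source_system)
    log = ParseLog()
    raw = RawTables(source_system=source_system, parse_log=log)
    is_faers = source_system == FAERS
    key_field = "report_id" if is_faers else "case_id"

    # --- demo ---
    dcols = cfg.columns.get("demo", {})
    mandatory = [key_field, "sex"]
    df = _read_frame(paths["demo"], cfg, "demo", mandatory, log)
    if df is not None:
        for row in df.to_dict("records"):
            rid = _get(row, dcols, "report_id") or _get(row, dcols, "case_id") or ""
            cid = _get(row, dcols, "case_id") or rid
            sex = cfg.sex_map.get(_get(row, dcols, "sex") or "", "unknown")
            raw.demo.append(DemoRecord(
                case_id=cid,
                report_id=rid,
                case_version=_to_int(_get(row, dcols, "case_version"), 0) or 0,
                sex=sex,
                age_years=parse_age_years(_get(row, dcols, "age"),
                                          _get(row, dcols, "age_unit"), log),
                age_band=parse_age_band(_get(row, dcols, "age_band")),
                event_date=parse_complete_date(_get(row, dcols, "event_date"), log),
            ))

    # --- drug ---
    gcols = cfg.columns.get("drug", {})
    df = _read_frame(paths["drug"], cfg, "drug", [key_field, "drug_name"], log)
    if df is not None:
        for row in df.to_dict("records"):
            cid = _get(row, gcols, key_field) or ""
            raw.drug.append(DrugRecord(
                case_id=cid,
                drug_name_raw=_get(row, gcols, "drug_name") or "",
                role=cfg.role_map.get(_get(row, gcols, "role") or "", UNKNOWN_ROLE),
                drug_seq=_to_int(_get(row, gcols, "drug_seq"), 1) or 1,
                start_date=parse_complete_date(_get(row, gcols, "start_date"), log),
            ))

    # --- reac ---
    rcols = cfg.columns.get("reac", {})
    df = _read_frame(paths["reac"], cfg, "reac", [key_field], log)
    if df is not None:
        for row in df.to_dict("records"):
            raw.reac.append(ReacRecord(
                case_id=_get(row, rcols, key_field) or "",
                pt_code=_to_int(_get(row, rcols, "pt_code")),
                pt_name=_get(row, rcols, "pt_name") or "",
                onset_date=parse_complete_date(_get(row, rcols, "onset_date"), log),
            ))

    # --- optional tables ---
    if "hist" in paths:
        hcols = cfg.columns.get("hist", {})
        df = _read_frame(paths["hist"], cfg, "hist", [key_field], log)
        if df is not None:
            for row in df.to_dict("records"):
                raw.hist.append(HistRecord(
                    case_id=_get(row, hcols, key_field) or "",
                    pt_code=_to_int(_get(row, hcols, "pt_code")),
                    term=_get(row, hcols, "term") or "",
                ))
    if "indi" in paths:
        icols = cfg.columns.get("indi", {})
        df = _read_frame(paths["indi"], cfg, "indi", [key_field], log)
        if df is not None:
            for row in df.to_dict("records"):
                raw.indi.append(IndiRecord(
                    case_id=_get(row, icols, key_field) or "",
                    drug_seq=_to_int(_get(row, icols, "drug_seq")),
                    pt_code=_to_int(_get(row, icols, "pt_code")),
                    term=_get(row, icols, "term") or "",
                ))
    if "ther" in paths:
        tcols = cfg.columns.get("ther", {})
        df = _read_frame(paths["ther"], cfg, "ther", [key_field, "drug_seq"], log)
        if df is not None:
            for row in df.to_dict("records"):
                raw.ther.append(TherRecord(
                    case_id=_get(row, tcols, key_field) or "",
                    drug_seq=_to_int(_get(row, tcols, "drug_seq"), 1) or 1,
                    start_date=parse_complete_date(_get(row, tcols, "start_date"), log),
                ))
    if "outc" in paths:
        ocols = cfg.columns.get("outc", {})
        df = _read_frame(paths["outc"], cfg, "outc", [key_field], log)
        if df is not None:
            for row in df.to_dict("records"):
                raw.outc.append(OutcRecord(
                    case_id=_get(row, ocols, key_field) or "",
                    outcome_code=_get(row, ocols, "outcome_code") or "",
                ))
    return raw


# ---------------------------------------------------------------------------
# table writing (round-trip of the same dialects)
# ---------------------------------------------------------------------------


def _fmt_date(d: date | None) -> str:
    return d.strftime("%Y%m%d") if d is not None else ""


def write_tables(raw: RawTables, outdir: str | Path,
                 dialect: DialectConfig | None = None) -> dict[str, Path]:
    """Write a :class:`RawTables` bundle as dialect-formatted text files.

    Produces files that :func:`read_tables` parses back into identical
    records (the round-trip contract used by the synthetic generator).
    Returns the mapping of table name to file path.
    """
    cfg = dialect or dialect_for(raw.source_system)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    is_faers = raw.source_system == FAERS
    sex_inv = {"male": "M", "female": "F"} if is_faers else {
        "male": "male", "female": "female"}
    role_inv_map = {FAERS: {PRIMARY_SUSPECTED: "PS", SUSPECTED: "SS",
                            CONCOMITANT: "C", INTERACTING: "I"},
                    JADER: {SUSPECTED: "suspected", CONCOMITANT: "concomitant",
                            INTERACTING: "interacting",
                            PRIMARY_SUSPECTED: "suspected"}}[raw.source_system]
    sep = cfg.delimiter
    ext = "txt" if is_faers else "csv"
    paths: dict[str, Path] = {}

    def emit(table: str, header: list[str], rows: list[list[str]]):
        p = outdir / f"{table}.{ext}"
        lines = [sep.join(header)] + [sep.join(r) for r in rows]
        p.write_text("\n".join(lines) + "\n", encoding=cfg.encoding)
        paths[table] = p

    dc = cfg.columns["demo"]
    if is_faers:
        emit("demo",
             [dc["report_id"], dc["case_id"], dc["case_version"], dc["sex"],
              dc["age"], dc["age_unit"], dc["event_date"]],
             [[r.report_id, r.case_id, str(r.case_version),
               sex_inv.get(r.sex, ""),
               "" if r.age_years is None else str(r.age_years),
               "" if r.age_years is None else "YR",
               _fmt_date(r.event_date)] for r in raw.demo])
    else:
        emit("demo", [dc["case_id"], dc["sex"], dc["age_band"]],
             [[r.case_id, sex_inv.get(r.sex, ""), r.age_band or ""]
              for r in raw.demo])

    gc = cfg.columns["drug"]
    key = "report_id" if is_faers else "case_id"
    if is_faers:
        emit("drug", [gc[key], gc["drug_seq"], gc["drug_name"], gc["role"]],
             [[r.case_id, str(r.drug_seq), r.drug_name_raw,
               role_inv_map.get(r.role, "")] for r in raw.drug])
    else:
        emit("drug",
             [gc["case_id"], gc["drug_name"], gc["role"], gc["drug_seq"],
              gc["start_date"]],
             [[r.case_id, r.drug_name_raw, role_inv_map.get(r.role, ""),
               str(r.drug_seq), _fmt_date(r.start_date)] for r in raw.drug])

    rc = cfg.columns["reac"]
    if is_faers:
        emit("reac", [rc[key], rc["pt_name"]],
             [[r.case_id, r.pt_name] for r in raw.reac])
    else:
        emit("reac",
             [rc["case_id"], rc["pt_code"], rc["pt_name"], rc["onset_date"]],
             [[r.case_id, "" if r.pt_code is None else str(r.pt_code),
               r.pt_name, _fmt_date(r.onset_date)] for r in raw.reac])

    if is_faers:
        tc = cfg.columns["ther"]
        emit("ther", [tc[key], tc["drug_seq"], tc["start_date"]],
             [[r.case_id, str(r.drug_seq), _fmt_date(r.start_date)]
              for r in raw.ther])
        ic = cfg.columns["indi"]
        emit("indi", [ic[key], ic["drug_seq"], ic["term"]],
             [[r.case_id, "" if r.drug_seq is None else str(r.drug_seq),
               r.term] for r in raw.indi])
        oc = cfg.columns["outc"]
        emit("outc", [oc[key], oc["outcome_code"]],
             [[r.case_id, r.outcome_code] for r in raw.outc])
    else:
        hc = cfg.columns["hist"]
        emit("hist", [hc["case_id"], hc["term"]],
             [[r.case_id, r.term] for r in raw.hist])
    return paths


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def deduplicate_faers(demo: Iterable[DemoRecord]) -> list[DemoRecord]:
    """Keep, per ``case_id``, the record with the highest ``case_version``.

    Ties on version are broken by the lexicographically greatest ``report_id``
    so the output is deterministic under input shuffling.  Idempotent.
    """
    best: dict[str, DemoRecord] = {}
    for rec in demo:
        cur = best.get(rec.case_id)
        if cur is None or (rec.case_version, rec.report_id) > (cur.case_version, cur.report_id):
            best[rec.case_id] = rec
    return list(best.values())


# ---------------------------------------------------------------------------
# drug-name standardization
# ---------------------------------------------------------------------------


def load_synonyms(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Load a two-column synonym → canonical dictionary file."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(delimiter)]
        if len(parts) < 2:
            continue
        mapping[normalize_term(parts[0])] = normalize_term(parts[1])
    return mapping


def standardize_drug_name(raw_name: str, dictionary: Mapping[str, str]) -> str | None:
    """Map a raw drug-name string to its canonical name, or missing.

    Matching is case-insensitive after trimming and collapsing whitespace:
    first an exact normalized match, then the longest dictionary synonym that
    is a prefix of the normalized name ending at a word boundary (so
    ``"MIRABEGRON."`` and ``"MIRABEGRON 50 MG"`` hit ``"mirabegron"``).
    Never guesses by fuzzy similarity.
    """
    norm = normalize_term(raw_name)
    if not norm:
        return None
    hit = dictionary.get(norm)
    if hit is not None:
        return hit
    best = None
    for syn, canon in dictionary.items():
        if norm.startswith(syn):
            rest = norm[len(syn):]
            if rest and rest[0].isalnum():
                continue  # not a word boundary
            if best is None or len(syn) > best[0]:
                best = (len(syn), canon)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# PLID
# ---------------------------------------------------------------------------


@dataclass(slots=True, frozen=True)
class DrugExposure:
    name: str  # standardized when the dictionary hits, else normalized raw
    name_std: str | None
    role: str
    seq: int
    start_dates: tuple[date, ...]  # complete therapy-start dates


@dataclass(slots=True, frozen=True)
class CaseEvent:
    pt_code: int | None
    pt_name: str
    onset_date: date | None


@dataclass(slots=True)
class PlidCase:
    """One deduplicated case of the patient-level integrated dataset."""

    case_id: str
    sex: str = "unknown"
    age_years: int | None = None
    age_band: str | None = None
    event_date: date | None = None
    drugs: tuple[DrugExposure, ...] = ()
    events: tuple[CaseEvent, ...] = ()
    history_terms: frozenset = frozenset()     # (pt_code, normalized term)
    indication_terms: frozenset = frozenset()
    max_drug_seq: int = 0


@dataclass(slots=True)
class PlidBuildLog:
    orphan_records: Counter = field(default_factory=Counter)

    @property
    def n_orphans(self) -> int:
        return sum(self.orphan_records.values())


def build_plid(raw: RawTables, synonyms: Mapping[str, str] | None = None,
               ) -> tuple[list[PlidCase], PlidBuildLog]:
    """Integrate raw tables into one record per retained case.

    For FAERS input, :func:`deduplicate_faers` must have been applied (the
    function applies it defensively and raises if duplicate case ids survive).
    Non-demo records whose case id is absent from demo are orphans: dropped
    and counted, never an error.  Cases present in demo but absent from the
    drug table are retained with an empty exposure set.
    """
    demo = raw.demo
    if raw.source_system == FAERS:
        demo = deduplicate_faers(demo)
    seen: set[str] = set()
    for rec in demo:
        if rec.case_id in seen:
            raise ValueError(f"duplicate case_id {rec.case_id!r} after deduplication")
        seen.add(rec.case_id)

    # In FAERS all non-demo tables are keyed by primaryid (report_id); the
    # retained report's id is the linkage key.  In JADER the case id is the key.
    if raw.source_system == FAERS:
        key_of = {rec.report_id: rec.case_id for rec in demo}
    else:
        key_of = {rec.case_id: rec.case_id for rec in demo}

    log = PlidBuildLog()
    drugs_by_case: dict[str, list[DrugRecord]] = defaultdict(list)
    for r in raw.drug:
        cid = key_of.get(r.case_id)
        if cid is None:
            log.orphan_records["drug"] += 1
            continue
        drugs_by_case[cid].append(r)

    events_by_case: dict[str, list[ReacRecord]] = defaultdict(list)
    for r in raw.reac:
        cid = key_of.get(r.case_id)
        if cid is None:
            log.orphan_records["reac"] += 1
            continue
        events_by_case[cid].append(r)

    ther_by_case_seq: dict[tuple[str, int], list[date]] = defaultdict(list)
    for r in raw.ther:
        cid = key_of.get(r.case_id)
        if cid is None:
            log.orphan_records["ther"] += 1
            continue
        if r.start_date is not None:
            ther_by_case_seq[(cid, r.drug_seq)].append(r.start_date)

    hist_by_case: dict[str, set] = defaultdict(set)
    for r in raw.hist:
        cid = key_of.get(r.case_id)
        if cid is None:
            log.orphan_records["hist"] += 1
            continue
        hist_by_case[cid].add((r.pt_code, normalize_term(r.term)))

    indi_by_case: dict[str, set] = defaultdict(set)
    for r in raw.indi:
        cid = key_of.get(r.case_id)
        if cid is None:
            log.orphan_records["indi"] += 1
            continue
        indi_by_case[cid].add((r.pt_code, normalize_term(r.term)))

    for r in raw.outc:
        if key_of.get(r.case_id) is None:
            log.orphan_records["outc"] += 1

    plid: list[PlidCase] = []
    for rec in demo:
        cid = rec.case_id
        exposures = []
        max_seq = 0
        for dr in drugs_by_case.get(cid, ()):  # one exposure per drug row
            max_seq = max(max_seq, dr.drug_seq)
            std = dr.drug_name_std
            if std is None and synonyms is not None:
                std = standardize_drug_name(dr.drug_name_raw, synonyms)
            if raw.source_system == FAERS:
                starts = tuple(sorted(ther_by_case_seq.get((cid, dr.drug_seq), ())))
            else:
                starts = (dr.start_date,) if dr.start_date is not None else ()
            exposures.append(DrugExposure(
                name=std if std is not None else normalize_term(dr.drug_name_raw),
                name_std=std,
                role=dr.role,
                seq=dr.drug_seq,
                start_dates=starts,
            ))
        events = tuple(
            CaseEvent(r.pt_code, r.pt_name, r.onset_date)
            for r in events_by_case.get(cid, ())
        )
        plid.append(PlidCase(
            case_id=cid,
            sex=rec.sex,
            age_years=rec.age_years,
            age_band=rec.age_band,
            event_date=rec.event_date,
            drugs=tuple(exposures),
            events=events,
            history_terms=frozenset(hist_by_case.get(cid, ())),
            indication_terms=frozenset(indi_by_case.get(cid, ())),
            max_drug_seq=max_seq,
        ))
    if log.n_orphans:
        logger.info("dropped %d orphan records: %s", log.n_orphans, dict(log.orphan_records))
    return plid, log


# ---------------------------------------------------------------------------
# event matching
# ---------------------------------------------------------------------------


@dataclass(slots=True, frozen=True)
class EventTarget:
    """A target adverse event, specified by MedDRA PT code and/or term strings."""

    pt_code: int | None = None
    terms: frozenset = frozenset()

    @staticmethod
    def of(pt_code: int | None = None, terms: Iterable[str] = ()) -> "EventTarget":
        return EventTarget(pt_code=pt_code,
                           terms=frozenset(normalize_term(t) for t in terms))

    def matches_term(self, pt_code: int | None, name: str) -> bool:
        if self.pt_code is not None and pt_code is not None:
            return pt_code == self.pt_code
        return normalize_term(name) in self.terms

    def matches_pair(self, pair: tuple[int | None, str]) -> bool:
        code, term = pair
        if self.pt_code is not None and code is not None:
            return code == self.pt_code
        return term in self.terms  # pairs are stored normalized


def match_event(case: PlidCase, target: EventTarget) -> bool:
    """True iff any reported event of the case matches the target.

    Matching is by PT code when both sides carry one, otherwise by normalized
    term equality.
    """
    return any(target.matches_term(ev.pt_code, ev.pt_name) for ev in case.events)


# ---------------------------------------------------------------------------
# PLID serialization (flat delimited table, nested fields JSON-encoded)
# ---------------------------------------------------------------------------

_D = "%Y-%m-%d"


def _dstr(d: date | None) -> str | None:
    return d.strftime(_D) if d is not None else None


def _dparse(s) -> date | None:
    if s is None or s != s or s == "":
        return None
    y, m, dd = str(s).split("-")
    return date(int(y), int(m), int(dd))


def plid_to_frame(plid: Sequence[PlidCase]) -> pd.DataFrame:
    rows = []
    for c in plid:
        rows.append({
            "case_id": c.case_id,
            "sex": c.sex,
            "age_years": c.age_years,
            "age_band": c.age_band,
            "event_date": _dstr(c.event_date),
            "max_drug_seq": c.max_drug_seq,
            "drugs": json.dumps([
                [d.name, d.name_std, d.role, d.seq, [_dstr(s) for s in d.start_dates]]
                for d in c.drugs
            ]),
            "events": json.dumps([
                [e.pt_code, e.pt_name, _dstr(e.onset_date)] for e in c.events
            ]),
            "history_terms": json.dumps(sorted(
                [list(t) for t in c.history_terms], key=str)),
            "indication_terms": json.dumps(sorted(
                [list(t) for t in c.indication_terms], key=str)),
        })
    return pd.DataFrame(rows)


def write_plid(plid: Sequence[PlidCase], path: str | Path) -> None:
    plid_to_frame(plid).to_csv(path, sep="\t", index=False)


def read_plid(path: str | Path) -> list[PlidCase]:
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str})
    out = []
    for row in df.to_dict("records"):
        drugs = tuple(
            DrugExposure(name=d[0], name_std=d[1], role=d[2], seq=int(d[3]),
                         start_dates=tuple(_dparse(s) for s in d[4] if s))
            for d in json.loads(row["drugs"])
        )
        events = tuple(
            CaseEvent(pt_code=None if e[0] is None else int(e[0]),
                      pt_name=e[1], onset_date=_dparse(e[2]))
            for e in json.loads(row["events"])
        )
        age = row.get("age_years")
        band = row.get("age_band")
        out.append(PlidCase(
            case_id=str(row["case_id"]),
            sex=row["sex"],
            age_years=None if pd.isna(age) else int(age),
            age_band=None if (band is None or band != band) else str(band),
            event_date=_dparse(row.get("event_date")),
            drugs=drugs,
            events=events,
            history_terms=frozenset(
                (None if t[0] is None else int(t[0]), t[1])
                for t in json.loads(row["history_terms"])),
            indication_terms=frozenset(
                (None if t[0] is None else int(t[0]), t[1])
                for t in json.loads(row["indication_terms"])),
            max_drug_seq=int(row["max_drug_seq"]),
        ))
    return out
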