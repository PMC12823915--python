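"""Stratified screening by sex, age band and concomitant-medication count.

Strata follow the pre-specified cuts: sex male/female; age 20-69 years
(non-elderly) versus 70-99 years (elderly), with ages outside 20-99
excluded; and polypharmacy defined as a maximum drug sequence number of 5
or more (the sequence number approximates the count of reported
medications, not simultaneous use).  A case missing the variable required
for a stratification is excluded from that stratification only — it still
contributes to the others (a listwise mode is available).

Volcano coordinates (x = ln ROR, y = -log10 p, size = n11) are emitted for
each non-excluded result, with reference lines at x = 0 and y = 1.30103
(p = 0.05).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .disprop import (
    ContingencyTable,
    MetricResult,
    SignalCriteria,
    compute_metrics,
)
from .icsr_io import DEFAULT_ROLE_FILTER, EventTarget, PlidCase

logger = logging.getLogger(__name__)

SEX = "sex"
AGE_BAND = "age_band"
MED_COUNT = "med_count"
VARIABLES = (SEX, AGE_BAND, MED_COUNT)

LEVELS = {
    SEX: ("male", "female"),
    AGE_BAND: ("y20_69", "y70_99"),
    MED_COUNT: ("lt5", "ge5"),
}

#: decade bands nesting inside the 70-year cut
_BANDS_NONELDERLY = {"20s", "30s", "40s", "50s", "60s"}
_BANDS_ELDERLY = {"70s", "80s", "90s"}


@dataclass(slots=True, frozen=True)
class StratumLabel:
    variable: str
    level: str

    def __post_init__(self):
        if self.variable not in LEVELS or self.level not in LEVELS[self.variable]:
            raise ValueError(f"invalid stratum {self.variable}={self.level}")


def age_band_level(case: PlidCase) -> str | None:
    """Age stratum of a case, or None when unknown / outside 20-99 years.

    Exact ages use the 20-69 / 70-99 cut directly; decade-band ages (JADER
    publishes decades only) map 20s-60s to the non-elderly band and
    70s-90s to the elderly band, other decades being excluded.
    """
    if case.age_years is not None:
        if 20 <= case.age_years <= 69:
            return "y20_69"
        if 70 <= case.age_years <= 99:
            return "y70_99"
        return None
    if case.age_band is not None:
        if case.age_band in _BANDS_NONELDERLY:
            return "y20_69"
        if case.age_band in _BANDS_ELDERLY:
            return "y70_99"
    return None


def assign_strata(case: PlidCase) -> dict[str, str | None]:
    """Stratum level per variable; None marks exclusion for that variable."""
    sex = case.sex if case.sex in ("male", "female") else None
    med = None
    if case.max_drug_seq >= 1:
        med = "ge5" if case.max_drug_seq >= 5 else "lt5"
    return {SEX: sex, AGE_BAND: age_band_level(case), MED_COUNT: med}


def stratified_screen(plid: Sequence[PlidCase], drug: str, target: EventTarget,
                      criteria: SignalCriteria = SignalCriteria(),
                      role_filter: frozenset = DEFAULT_ROLE_FILTER,
                      variables: Sequence[str] = VARIABLES,
                      yates: bool = True,
                      listwise: bool = False,
                      comparator: str = "within",
                      ) -> tuple[list[MetricResult], Counter]:
    """Screen one drug within each stratum level.

    Both rows of the 2x2 are restricted to the cases of the stratum (the
    default, ``comparator="within"``); ``comparator="full"`` keeps the
    exposed row stratum-restricted but draws the comparator row from every
    non-exposed case with the variable non-missing.  The n11 < 3 exclusion
    applies per stratum.  Returns the results and a per-variable tally of
    cases excluded for missingness.
    """
    if comparator not in ("within", "full"):
        raise ValueError(f"unknown comparator mode {comparator!r}")
    labels = [assign_strata(c) for c in plid]
    exposed = [
        any(d.role in role_filter and d.name == drug for d in c.drugs)
        for c in plid
    ]
    has_event = [
        any(target.matches_term(e.pt_code, e.pt_name) for e in c.events)
        for c in plid
    ]
    dropped: Counter = Counter()
    complete = [all(lab[v] is not None for v in variables) for lab in labels]
    results = []
    for var in variables:
        for c, lab in zip(plid, labels):
            if lab[var] is None:
                dropped[var] += 1
        for level in LEVELS[var]:
            n11 = n12 = n21 = n22 = 0
            for lab, comp, exp, ev in zip(labels, complete, exposed, has_event):
                if listwise and not comp:
                    continue
                if lab[var] is None:
                    continue
                in_level = lab[var] == level
                if exp:
                    if not in_level:
                        continue
                    if ev:
                        n11 += 1
                    else:
                        n12 += 1
                else:
                    if comparator == "within" and not in_level:
                        continue
                    if ev:
                        n21 += 1
                    else:
                        n22 += 1
            res = compute_metrics(drug, ContingencyTable(n11, n12, n21, n22),
                                  criteria, yates=yates)
            res.variable = var
            res.level = level
            results.append(res)
    return results, dropped


# ---------------------------------------------------------------------------
# volcano coordinates
# ---------------------------------------------------------------------------

P05_LINE = -math.log10(0.05)  # 1.30103, the p = 0.05 reference line


@dataclass(slots=True, frozen=True)
class VolcanoPoint:
    label: str  # "overall" or "variable=level"
    x: float  # ln(ROR)
    y: float  # -log10(fisher p)
    size: int  # n11


def volcano_points(results: Sequence[MetricResult]
                   ) -> tuple[list[VolcanoPoint], dict]:
    """Volcano coordinates for non-excluded results, plus reference lines."""
    pts = []
    for r in results:
        if r.excluded_low_count or r.ror is None or r.fisher_p is None:
            logger.info("volcano: skipping %s %s=%s (excluded or undefined)",
                        r.drug, r.variable, r.level)
            continue
        label = "overall" if r.variable == "overall" else f"{r.variable}={r.level}"
        y = -math.log10(r.fisher_p) if r.fisher_p > 0 else math.inf
        pts.append(VolcanoPoint(label=label, x=math.log(r.ror), y=y, size=r.n11))
    meta = {"x_reference": 0.0, "y_reference": P05_LINE}
    return pts, meta
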