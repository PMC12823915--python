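"""Disproportionality metrics and signal classification for 2x2 report tables.

Each screened drug is summarized against a target event by the table

             with event   without event
  drug          n11           n12
  comparator    n21           n22

where the comparator row is, by default, every case in the database not
exposed to the drug ("drug versus rest").  Three measures are computed:

* **ROR** — reporting odds ratio ``(n11 n22)/(n12 n21)`` with a lognormal
  Wald 95% CI, paired with a two-sided Fisher exact test.
* **PRR** — proportional reporting ratio ``(n11/n1+)/(n21/n2+)`` with a
  lognormal CI and the Yates-corrected chi-square statistic.
* **BCPNN IC** — the Bayesian information component, a shrunk
  ``log2(observed/expected)`` with a closed-form normal-approximation CI.

Signal criteria (all on the lower 95% bound): ROR025 > 1 with Fisher
p < 0.05; PRR025 > 2 with chi2 > 4 (a deliberately stringent corroboration
threshold; the conventional PRR025 > 1 is available as a sensitivity
setting); IC025 > 0, with strength bands weak / medium / strong cut at 1.5
and 3.0.  Drugs with fewer than three co-reports (n11 < 3) are excluded from
metric computation for minimum statistical stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma

from .icsr_io import DEFAULT_ROLE_FILTER, EventTarget, PlidCase

Z95 = 1.959964  # two-sided 95% standard-normal quantile, fixed


# ---------------------------------------------------------------------------
# contingency table
# ---------------------------------------------------------------------------


@dataclass(slots=True, frozen=True)
class ContingencyTable:
    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self):
        for v in (self.n11, self.n12, self.n21, self.n22):
            if v < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n1p(self) -> int:
        return self.n11 + self.n12

    @property
    def n2p(self) -> int:
        return self.n21 + self.n22

    @property
    def np1(self) -> int:
        return self.n11 + self.n21

    @property
    def np2(self) -> int:
        return self.n12 + self.n22

    @property
    def npp(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    def cells(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)


def build_contingency(plid: Sequence[PlidCase], target_drugs: Iterable[str],
                      target: EventTarget,
                      role_filter: frozenset = DEFAULT_ROLE_FILTER,
                      ) -> ContingencyTable:
    """Classify each case once into one of the four cells.

    A case is in the exposed row iff any of its drug records, in an allowed
    role, carries one of the target (canonical) names; in the event column
    iff any reported event matches the target.  Cells sum to ``len(plid)``.
    """
    targets = set(target_drugs)
    n11 = n12 = n21 = n22 = 0
    for case in plid:
        exposed = any(
            d.role in role_filter and d.name in targets for d in case.drugs
        )
        has_event = any(
            target.matches_term(e.pt_code, e.pt_name) for e in case.events
        )
        if exposed:
            if has_event:
                n11 += 1
            else:
                n12 += 1
        elif has_event:
            n21 += 1
        else:
            n22 += 1
    if not plid:
        import logging
        logging.getLogger(__name__).warning("empty PLID: all-zero table")
    return ContingencyTable(n11, n12, n21, n22)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def ror_ci(tab: ContingencyTable, level: float = 0.95,
           haldane: bool = False) -> tuple[float, float, float] | None:
    """Reporting odds ratio with lognormal Wald CI; None on any zero cell.

    ``haldane`` adds 0.5 to every cell when any cell is zero (off by
    default: the n11 gate removes the cases where it would matter).
    """
    a, b, c, d = (float(v) for v in tab.cells())
    if min(a, b, c, d) == 0:
        if not haldane:
            return None
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    z = Z95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def prr_ci(tab: ContingencyTable, level: float = 0.95
           ) -> tuple[float, float, float] | None:
    """Proportional reporting ratio with lognormal CI; None when undefined."""
    if tab.n11 == 0 or tab.n21 == 0 or tab.n1p == 0 or tab.n2p == 0:
        return None
    z = Z95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2)
    prr = (tab.n11 / tab.n1p) / (tab.n21 / tab.n2p)
    se = math.sqrt(1 / tab.n11 - 1 / tab.n1p + 1 / tab.n21 - 1 / tab.n2p)
    return prr, prr * math.exp(-z * se), prr * math.exp(z * se)


def chi_square_yates(tab: ContingencyTable) -> float | None:
    """Yates-corrected Pearson chi-square, clamped at zero.

    ``chi2 = sum (max(|O - E| - 0.5, 0))^2 / E`` with E the independence
    expectations; None when any margin is zero (expectations undefined).
    """
    if min(tab.n1p, tab.n2p, tab.np1, tab.np2) == 0:
        return None
    npp = tab.npp
    obs = tab.cells()
    exp = (tab.n1p * tab.np1 / npp, tab.n1p * tab.np2 / npp,
           tab.n2p * tab.np1 / npp, tab.n2p * tab.np2 / npp)
    return sum(max(abs(o - e) - 0.5, 0.0) ** 2 / e for o, e in zip(obs, exp))


def chi_square_pearson(tab: ContingencyTable) -> float | None:
    """Uncorrected Pearson chi-square (selectable alternative)."""
    if min(tab.n1p, tab.n2p, tab.np1, tab.np2) == 0:
        return None
    npp = tab.npp
    obs = tab.cells()
    exp = (tab.n1p * tab.np1 / npp, tab.n1p * tab.np2 / npp,
           tab.n2p * tab.np1 / npp, tab.n2p * tab.np2 / npp)
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


_EXACT_INT_LIMIT = 2000  # exact integer enumeration up to this grand total


def fisher_exact_two_sided(tab: ContingencyTable) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables with the observed margins no more probable than the observed
    one.

    For small tables the hypergeometric weights are compared as exact
    integers, so ties are exact; for large totals the computation moves to
    log space with a 1e-7 relative tie tolerance.
    """
    n1p, np1, npp = tab.n1p, tab.np1, tab.npp
    if npp == 0 or n1p == 0 or np1 == 0 or tab.np2 == 0 or tab.n2p == 0:
        return 1.0
    lo = max(0, n1p + np1 - npp)
    hi = min(n1p, np1)
    if npp <= _EXACT_INT_LIMIT:
        np2 = npp - np1
        w_obs = math.comb(np1, tab.n11) * math.comb(np2, n1p - tab.n11)
        num = sum(
            w for k in range(lo, hi + 1)
            if (w := math.comb(np1, k) * math.comb(np2, n1p - k)) <= w_obs
        )
        return num / math.comb(npp, n1p)
    ks = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(ks, npp, np1, n1p)
    log_obs = stats.hypergeom.logpmf(tab.n11, npp, np1, n1p)
    mask = logpmf <= log_obs + 1e-7
    return float(min(1.0, np.exp(logpmf[mask]).sum()))


def bcpnn_ic(tab: ContingencyTable, level: float = 0.95
             ) -> tuple[float, float, float]:
    """Closed-form BCPNN information component with 95% credibility bounds.

    The Bayesian model puts independent Beta posteriors on the joint and
    marginal reporting probabilities with the classic priors
    alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1 and
    gamma = gamma11 (N+alpha)(N+beta) / ((n1+ + alpha1)(n+1 + beta1)),
    which centres the prior IC at zero; the priors regularize zero cells,
    so the IC is always defined.

    IC = log2 p11 - log2 p1+ - log2 p+1 is then a sum of independent
    log-Beta variables whose cumulants are polygamma functions, so the
    posterior mean and variance are exact, and the credibility bounds use a
    Cornish-Fisher skewness correction — the posterior of the joint term is
    visibly skewed at the small co-report counts this analysis gates on.
    """
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    n11, n1p, np1, npp = tab.n11, tab.n1p, tab.np1, tab.npp
    if npp == 0:
        raise ValueError("empty table")
    z = Z95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2)
    g = g11 * (npp + al) * (npp + be) / ((n1p + a1) * (np1 + b1))
    ln2 = math.log(2)
    # (shape pair, sign) of each independent log-Beta term of the IC
    terms = (
        ((n11 + g11, npp - n11 + g - g11), 1.0),
        ((n1p + a1, npp - n1p + al - a1), -1.0),
        ((np1 + b1, npp - np1 + be - b1), -1.0),
    )
    ic = k2 = k3 = 0.0
    for (a, b), s in terms:
        ic += s * (digamma(a) - digamma(a + b)) / ln2
        k2 += (polygamma(1, a) - polygamma(1, a + b)) / ln2**2
        k3 += s * (polygamma(2, a) - polygamma(2, a + b)) / ln2**3
    sd = math.sqrt(k2)
    skew_shift = (z * z - 1) * (k3 / k2**1.5) / 6
    return ic, ic + sd * (-z + skew_shift), ic + sd * (z + skew_shift)


# ---------------------------------------------------------------------------
# criteria and results
# ---------------------------------------------------------------------------


@dataclass(slots=True, frozen=True)
class SignalCriteria:
    """Pre-specified signal thresholds (strict '>' comparisons throughout)."""

    ror_lower_gt: float = 1.0
    fisher_alpha: float = 0.05
    prr_lower_gt: float = 2.0
    chi2_gt: float = 4.0
    ic_lower_gt: float = 0.0
    min_n11: int = 3


IC_NONE = "none"
IC_WEAK = "weak"
IC_MEDIUM = "medium"
IC_STRONG = "strong"


def ic_strength(ic_lo: float | None) -> str:
    """Strength band of the IC lower bound: weak/medium/strong at 1.5, 3.0."""
    if ic_lo is None or ic_lo <= 0:
        return IC_NONE
    if ic_lo < 1.5:
        return IC_WEAK
    if ic_lo < 3.0:
        return IC_MEDIUM
    return IC_STRONG


@dataclass(slots=True)
class MetricResult:
    """All metrics, CI bounds and criterion flags for one drug (x stratum)."""

    drug: str
    n11: int
    n12: int
    n21: int
    n22: int
    excluded_low_count: bool = False
    ror: float | None = None
    ror_lo: float | None = None
    ror_hi: float | None = None
    fisher_p: float | None = None
    prr: float | None = None
    prr_lo: float | None = None
    prr_hi: float | None = None
    chi2: float | None = None
    ic: float | None = None
    ic_lo: float | None = None
    ic_hi: float | None = None
    met_ror: bool = False
    met_prr: bool = False
    met_ic: bool = False
    ic_strength: str = IC_NONE
    variable: str = "overall"
    level: str = "overall"

    @property
    def any_signal(self) -> bool:
        return self.met_ror or self.met_prr or self.met_ic

    @property
    def table(self) -> ContingencyTable:
        return ContingencyTable(self.n11, self.n12, self.n21, self.n22)


def classify_signal(res: MetricResult, criteria: SignalCriteria) -> MetricResult:
    """Apply the pre-specified criteria to computed metrics, in place."""
    if res.excluded_low_count:
        res.met_ror = res.met_prr = res.met_ic = False
        res.ic_strength = IC_NONE
        return res
    res.met_ror = (
        res.ror_lo is not None and res.fisher_p is not None
        and res.ror_lo > criteria.ror_lower_gt
        and res.fisher_p < criteria.fisher_alpha
    )
    res.met_prr = (
        res.prr_lo is not None and res.chi2 is not None
        and res.prr_lo > criteria.prr_lower_gt
        and res.chi2 > criteria.chi2_gt
    )
    res.met_ic = res.ic_lo is not None and res.ic_lo > criteria.ic_lower_gt
    res.ic_strength = ic_strength(res.ic_lo)
    return res


def compute_metrics(drug: str, tab: ContingencyTable, criteria: SignalCriteria,
                    yates: bool = True) -> MetricResult:
    """Compute every metric for a table, honouring the low-count exclusion."""
    res = MetricResult(drug=drug, n11=tab.n11, n12=tab.n12,
                       n21=tab.n21, n22=tab.n22)
    if tab.n11 < criteria.min_n11:
        res.excluded_low_count = True
        return classify_signal(res, criteria)
    r = ror_ci(tab)
    if r is not None:
        res.ror, res.ror_lo, res.ror_hi = r
    res.fisher_p = fisher_exact_two_sided(tab)
    p = prr_ci(tab)
    if p is not None:
        res.prr, res.prr_lo, res.prr_hi = p
    res.chi2 = chi_square_yates(tab) if yates else chi_square_pearson(tab)
    res.ic, res.ic_lo, res.ic_hi = bcpnn_ic(tab)
    return classify_signal(res, criteria)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def case_labels(plid: Sequence[PlidCase], target: EventTarget,
                role_filter: frozenset = DEFAULT_ROLE_FILTER,
                ) -> tuple[list[frozenset], np.ndarray]:
    """Per-case (exposed drug-name set under the role filter, event flag)."""
    exposed_sets = [
        frozenset(d.name for d in c.drugs if d.role in role_filter)
        for c in plid
    ]
    has_event = np.array([
        any(target.matches_term(e.pt_code, e.pt_name) for e in c.events)
        for c in plid
    ], dtype=bool)
    return exposed_sets, has_event


def screen(plid: Sequence[PlidCase], drug_list: Sequence[str],
           target: EventTarget,
           criteria: SignalCriteria = SignalCriteria(),
           role_filter: frozenset = DEFAULT_ROLE_FILTER,
           yates: bool = True,
           comparator_excludes: Iterable[str] | None = None,
           ) -> list[MetricResult]:
    """Screen each drug against the rest of the database.

    By default the comparator row keeps all other cases, including those
    exposed to the other screened drugs (drug-versus-rest).  Passing
    ``comparator_excludes`` removes cases exposed to any of those drugs from
    the comparator row instead.
    """
    exposed_sets, has_event = case_labels(plid, target, role_filter)
    results = []
    excl = set(comparator_excludes) if comparator_excludes else None
    for drug in drug_list:
        n11 = n12 = n21 = n22 = 0
        for s, ev in zip(exposed_sets, has_event):
            if drug in s:
                if ev:
                    n11 += 1
                else:
                    n12 += 1
            else:
                if excl is not None and drug not in excl and (s & excl):
                    continue  # removed from comparator in exclusive mode
                if ev:
                    n21 += 1
                else:
                    n22 += 1
        results.append(compute_metrics(
            drug, ContingencyTable(n11, n12, n21, n22), criteria, yates=yates))
    return results


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "drug", "variable", "level", "n11", "n12", "n21", "n22",
    "ROR", "ROR_lo", "ROR_hi", "fisher_p",
    "PRR", "PRR_lo", "PRR_hi", "chi2",
    "IC", "IC_lo", "IC_hi",
    "met_ROR", "met_PRR", "met_IC", "ic_strength", "excluded_low_count",
]


def results_to_frame(results: Sequence[MetricResult]):
    """Screening results as a DataFrame in the documented column order."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "drug": r.drug, "variable": r.variable, "level": r.level,
            "n11": r.n11, "n12": r.n12, "n21": r.n21, "n22": r.n22,
            "ROR": r.ror, "ROR_lo": r.ror_lo, "ROR_hi": r.ror_hi,
            "fisher_p": r.fisher_p,
            "PRR": r.prr, "PRR_lo": r.prr_lo, "PRR_hi": r.prr_hi,
            "chi2": r.chi2,
            "IC": r.ic, "IC_lo": r.ic_lo, "IC_hi": r.ic_hi,
            "met_ROR": r.met_ror, "met_PRR": r.met_prr, "met_IC": r.met_ic,
            "ic_strength": r.ic_strength,
            "excluded_low_count": r.excluded_low_count,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
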