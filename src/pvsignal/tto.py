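"""Time-to-onset extraction, Weibull shape modelling and descriptive curves.

Time-to-onset (TTO) is the number of days from drug initiation to event
onset, with one day added so a same-day onset counts as day 1 rather than
zero (the Weibull density is singular at zero for shapes below one).  Only
date-complete pairs contribute; implausible pairs (onset before start) are
discarded and counted.

The Weibull shape parameter beta summarizes the hazard of reporting over
time since initiation: beta < 1 indicates early failure (decreasing hazard,
onsets cluster just after initiation), beta near 1 a random, memoryless
pattern, and beta > 1 wear-out failure (hazard increasing with time on
drug).  beta is estimated by maximum likelihood via the profile score
equation, its 95% CI by nonparametric bootstrap (percentile interval,
10,000 resamples by default), and the failure type is read off the CI's
position relative to 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .icsr_io import FAERS, EventTarget, PlidCase

logger = logging.getLogger(__name__)

#: pairing rules for cases carrying several start/onset dates
EARLIEST_START_THEN_ONSET = "earliest_start_then_onset"
EARLIEST_START_EARLIEST_ONSET = "earliest_start_earliest_onset"


@dataclass(slots=True, frozen=True)
class TTORecord:
    case_id: str
    drug: str
    days: int  # >= 1 by the +1 convention

    def __post_init__(self):
        if self.days < 1:
            raise ValueError("TTO days must be >= 1")


def extract_tto(case: PlidCase, drug: str, target: EventTarget,
                source_system: str,
                pairing: str = EARLIEST_START_THEN_ONSET,
                ) -> TTORecord | None:
    """Extract the case's TTO for one drug-event pair, or missing.

    Start dates come from the drug's therapy records (JADER drug table /
    FAERS THER); the onset date comes from the matching reaction records in
    JADER and from the demographic event date in FAERS.  Among multiple
    complete dates the earliest initiation and onset pair is used: by
    default the earliest start is paired with the earliest onset on or
    after it; the alternative rule pairs the earliest start with the overall
    earliest onset and discards the pair if negative.  ``days`` is the
    difference plus one.
    """
    starts = sorted(
        s for d in case.drugs if d.name == drug for s in d.start_dates
    )
    if not starts:
        return None
    if source_system == FAERS:
        onsets = [case.event_date] if case.event_date is not None else []
    else:
        onsets = [
            e.onset_date for e in case.events
            if e.onset_date is not None and target.matches_term(e.pt_code, e.pt_name)
        ]
    onsets = sorted(onsets)
    if not onsets:
        return None
    start = starts[0]
    if pairing == EARLIEST_START_THEN_ONSET:
        onset = next((o for o in onsets if o >= start), None)
        if onset is None:
            logger.info("case %s drug %s: all onsets precede start; discarded",
                        case.case_id, drug)
            return None
    elif pairing == EARLIEST_START_EARLIEST_ONSET:
        onset = onsets[0]
        if onset < start:
            logger.info("case %s drug %s: negative interval discarded",
                        case.case_id, drug)
            return None
    else:
        raise ValueError(f"unknown pairing rule {pairing!r}")
    return TTORecord(case.case_id, drug, (onset - start).days + 1)


def collect_tto(plid: Sequence[PlidCase], drug: str, target: EventTarget,
                source_system: str,
                pairing: str = EARLIEST_START_THEN_ONSET,
                role_filter: frozenset | None = None,
                ) -> list[TTORecord]:
    """All date-complete TTO records for a drug among event-matching cases."""
    from .icsr_io import DEFAULT_ROLE_FILTER

    roles = role_filter or DEFAULT_ROLE_FILTER
    out = []
    for case in plid:
        if not any(d.name == drug and d.role in roles for d in case.drugs):
            continue
        if not any(target.matches_term(e.pt_code, e.pt_name) for e in case.events):
            continue
        rec = extract_tto(case, drug, target, source_system, pairing)
        if rec is not None:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_tto(days: Sequence[int]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation between order statistics."""
    if len(days) == 0:
        raise ValueError("cannot summarize an empty TTO list")
    x = np.asarray(days, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Weibull maximum likelihood
# ---------------------------------------------------------------------------


def _shape_score_terms(logx: np.ndarray, beta: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Profile score g(beta) and derivative, vectorized over rows.

    With w_i = x_i^beta computed on max-normalized data (stable for large
    beta): g(beta) = sum w ln x / sum w - 1/beta - mean(ln x), which is
    strictly increasing in beta; g' = Var_w(ln x) + 1/beta^2 > 0.
    """
    b = beta[:, None]
    w = np.exp(b * (logx - logx.max(axis=1, keepdims=True)))
    sw = w.sum(axis=1)
    m1 = (w * logx).sum(axis=1) / sw
    m2 = (w * logx * logx).sum(axis=1) / sw
    g = m1 - 1.0 / beta - logx.mean(axis=1)
    gprime = (m2 - m1 * m1) + 1.0 / beta**2
    return g, gprime


def weibull_shape_batch(samples: np.ndarray, tol: float = 1e-12,
                        max_iter: int = 200) -> np.ndarray:
    """Solve the Weibull profile score equation for each row of ``samples``.

    Safeguarded Newton iteration inside an expanding bisection bracket;
    rows with zero spread (all values equal) have no finite MLE and yield
    NaN.  Returns the shape estimates.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if np.any(x <= 0):
        raise ValueError("Weibull data must be positive")
    logx = np.log(x)
    spread = logx.max(axis=1) > logx.min(axis=1)
    beta = np.ones(x.shape[0])
    lo = np.full(x.shape[0], 1e-6)
    hi = np.full(x.shape[0], 1e3)
    active = spread.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        g, gp = _shape_score_terms(logx, beta)
        # maintain bracket: g increasing, so g<0 -> root above, g>0 -> below
        lo = np.where(active & (g < 0), np.maximum(lo, beta), lo)
        hi = np.where(active & (g > 0), np.minimum(hi, beta), hi)
        step = g / gp
        nxt = beta - step
        bad = (nxt <= lo) | (nxt >= hi) | ~np.isfinite(nxt)
        nxt = np.where(bad, 0.5 * (lo + hi), nxt)
        conv = np.abs(nxt - beta) <= tol * np.maximum(np.abs(nxt), 1.0)
        beta = np.where(active, nxt, beta)
        active = active & ~conv
    beta = np.where(spread, beta, np.nan)
    return beta


def weibull_mle(days: Sequence[int]) -> tuple[float, float, float]:
    """Maximum-likelihood Weibull (shape, scale, log-likelihood) for TTO days.

    The shape solves the profile score equation to a relative tolerance of
    1e-10 by safeguarded Newton iteration; the scale then has the closed
    form ``(mean of x^beta)^(1/beta)``.  Raises on fewer than two values or
    on zero spread (no finite MLE).
    """
    x = np.asarray(days, dtype=float)
    if x.size < 2:
        raise ValueError("Weibull MLE requires at least two observations")
    if np.any(x <= 0):
        raise ValueError("Weibull data must be positive")
    if x.max() == x.min():
        raise ValueError(
            "degenerate sample: all values identical, no finite Weibull MLE")
    beta = float(weibull_shape_batch(x[None, :])[0])
    # scale via max-normalized moments for overflow safety
    xm = x.max()
    lam = xm * float(np.mean((x / xm) ** beta)) ** (1.0 / beta)
    n = x.size
    loglik = float(
        n * (math.log(beta) - beta * math.log(lam))
        + (beta - 1) * np.log(x).sum()
        - ((x / lam) ** beta).sum()
    )
    return beta, lam, loglik


def bootstrap_shape_ci(days: Sequence[int], B: int = 10000,
                       seed: int | np.random.Generator | None = 0,
                       level: float = 0.95,
                       ) -> tuple[float, float, int]:
    """Percentile bootstrap CI for the Weibull shape.

    Draws ``B`` resamples with replacement, re-estimates the shape on each,
    and takes the (2.5, 97.5) percentiles of the successful resamples.
    Degenerate resamples (all values equal) are skipped and counted; more
    than 20% of them triggers a warning.  Returns (lo, hi, n_degenerate).
    """
    x = np.asarray(days, dtype=float)
    weibull_mle(x)  # validates the original sample
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.size
    betas = np.empty(0)
    n_deg = 0
    chunk = max(1, min(B, int(4e6 // max(n, 1))))
    done = 0
    parts = []
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        est = weibull_shape_batch(x[idx])
        parts.append(est)
        done += b
    betas = np.concatenate(parts)
    ok = np.isfinite(betas)
    n_deg = int((~ok).sum())
    if n_deg > 0.2 * B:
        logger.warning("bootstrap: %d/%d degenerate resamples skipped", n_deg, B)
    alpha = (1 - level) / 2
    lo, hi = np.percentile(betas[ok], [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi), n_deg


EARLY = "early"
RANDOM = "random"
WEAR_OUT = "wear_out"


def classify_failure(ci: tuple[float, float]) -> str:
    """Failure type from the shape CI: wear-out if the lower bound exceeds 1,
    early if the upper bound is below 1, random when the CI includes 1."""
    lo, hi = ci
    if lo > hi:
        raise ValueError("CI lower bound exceeds upper bound")
    if lo > 1.0:
        return WEAR_OUT
    if hi < 1.0:
        return EARLY
    return RANDOM


@dataclass(slots=True)
class WeibullFit:
    """Complete TTO summary for one drug x database."""

    n: int
    shape: float
    scale: float
    loglik: float
    shape_ci: tuple[float, float]
    failure_type: str
    median_days: float
    iqr_days: tuple[float, float]
    pct_within_365: float
    n_degenerate_resamples: int = 0


def fit_tto(days: Sequence[int], B: int = 10000,
            seed: int | np.random.Generator | None = 0) -> WeibullFit:
    """End-to-end TTO model: MLE, bootstrap CI, failure type, summaries."""
    x = np.asarray(days, dtype=float)
    beta, lam, ll = weibull_mle(x)
    lo, hi, n_deg = bootstrap_shape_ci(x, B=B, seed=seed)
    med, q1, q3 = summarize_tto(x)
    return WeibullFit(
        n=int(x.size), shape=beta, scale=lam, loglik=ll,
        shape_ci=(lo, hi), failure_type=classify_failure((lo, hi)),
        median_days=med, iqr_days=(q1, q3),
        pct_within_365=float(100.0 * np.mean(x <= 365)),
        n_degenerate_resamples=n_deg,
    )


# ---------------------------------------------------------------------------
# descriptive curves
# ---------------------------------------------------------------------------


def km_cumulative(days: Sequence[int], window_days: int | None = None
                  ) -> tuple[list[tuple[float, float]], float]:
    """Cumulative onset curve and the fraction of reports within 365 days.

    With no censoring the Kaplan-Meier event curve reduces to the empirical
    cumulative proportion of reports by day t, expressed in percent of all
    reports.  ``window_days`` truncates the step list (commonly 730 days for
    display) without renormalizing, so the truncated curve coincides with
    the full curve on its domain.
    """
    x = np.asarray(days, dtype=float)
    if x.size == 0:
        raise ValueError("empty TTO list")
    n = x.size
    ts, counts = np.unique(x, return_counts=True)
    cum = 100.0 * np.cumsum(counts) / n
    within_365 = float(100.0 * np.mean(x <= 365))
    steps = [
        (float(t), float(c)) for t, c in zip(ts, cum)
        if window_days is None or t <= window_days
    ]
    return steps, within_365


def histogram_boxplot_data(days: Sequence[int], bin_width: int = 5,
                           window: int = 730) -> dict:
    """Binned counts plus a five-number summary within the display window.

    Bins are half-open ``[k*w, (k+1)*w)`` and the window itself is half-open
    (``days < window``), so the bin counts always total the in-window count;
    values beyond the window are excluded from both the histogram and the
    summary (a warning is logged when nothing remains).
    """
    x = np.asarray(days, dtype=float)
    if x.size == 0:
        raise ValueError("empty TTO list")
    inw = x[x < window]
    if inw.size == 0:
        logger.warning("all %d TTO values exceed the %d-day window", x.size, window)
        return {"bin_width": bin_width, "window": window, "bins": [],
                "summary": None, "n_in_window": 0}
    edges = np.arange(0, window + bin_width, bin_width)
    counts, _ = np.histogram(inw, bins=edges)
    med, q1, q3 = summarize_tto(inw)
    bins = [
        (float(edges[i]), float(edges[i + 1]), int(c))
        for i, c in enumerate(counts) if c > 0
    ]
    return {
        "bin_width": bin_width,
        "window": window,
        "bins": bins,
        "summary": {
            "min": float(inw.min()), "q1": q1, "median": med,
            "q3": q3, "max": float(inw.max()),
        },
        "n_in_window": int(inw.size),
    }
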