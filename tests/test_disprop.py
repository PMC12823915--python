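"""Disproportionality metrics: hand checks, oracles and invariants."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.disprop import (
    ContingencyTable,
    SignalCriteria,
    bcpnn_ic,
    build_contingency,
    chi_square_pearson,
    chi_square_yates,
    classify_signal,
    compute_metrics,
    fisher_exact_two_sided,
    ic_strength,
    prr_ci,
    ror_ci,
    screen,
)
from pvsignal.icsr_io import EventTarget, build_plid
from pvsignal.synthetic import default_synonyms


def tab(a, b, c, d):
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def fisher_oracle(t: ContingencyTable) -> Fraction:
    """Exhaustive hypergeometric enumeration with exact rational arithmetic."""
    n1p, np1, npp = t.n1p, t.np1, t.npp
    np2 = npp - np1
    w_obs = math.comb(np1, t.n11) * math.comb(np2, n1p - t.n11)
    num = 0
    for k in range(max(0, n1p + np1 - npp), min(n1p, np1) + 1):
        w = math.comb(np1, k) * math.comb(np2, n1p - k)
        if w <= w_obs:
            num += w
    return Fraction(num, math.comb(npp, n1p))


def ic_mc_oracle(t: ContingencyTable, ndraw=10**5, seed=0):
    """Monte-Carlo posterior of the IC under the model's independent-Beta
    posteriors (the joint cell uses the adaptive gamma prior)."""
    rng = np.random.default_rng(seed)
    n11, n1p, np1, npp = t.n11, t.n1p, t.np1, t.npp
    g = (npp + 2) * (npp + 2) / ((n1p + 1) * (np1 + 1))
    ic = (np.log2(rng.beta(n11 + 1, npp - n11 + g - 1, ndraw))
          - np.log2(rng.beta(n1p + 1, npp - n1p + 1, ndraw))
          - np.log2(rng.beta(np1 + 1, npp - np1 + 1, ndraw)))
    return ic.mean(), np.percentile(ic, 2.5), np.percentile(ic, 97.5)


def random_tables(n, seed, max_margin=30):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        n1p = int(rng.integers(1, max_margin + 1))
        np1 = int(rng.integers(1, max_margin + 1))
        npp = int(rng.integers(max(n1p, np1), 2 * max_margin + 1))
        n11 = int(rng.integers(max(0, n1p + np1 - npp), min(n1p, np1) + 1))
        cells = (n11, n1p - n11, np1 - n11, npp - n1p - np1 + n11)
        if min(cells) >= 0:
            out.append(tab(*cells))
    return out


# ---------------------------------------------------------------------------
# hand checks
# ---------------------------------------------------------------------------


def test_ror_hand_check():
    r, lo, hi = ror_ci(tab(10, 90, 100, 9900))
    assert r == pytest.approx(11.0)
    assert lo == pytest.approx(5.56, abs=0.01)
    assert hi == pytest.approx(21.77, abs=0.01)


def test_prr_hand_check():
    p, lo, hi = prr_ci(tab(10, 90, 100, 9900))
    assert p == pytest.approx(10.0)
    assert lo < p < hi


def test_null_table_is_flat():
    t = tab(5, 45, 50, 450)
    assert ror_ci(t)[0] == pytest.approx(1.0)
    assert prr_ci(t)[0] == pytest.approx(1.0)
    assert chi_square_yates(t) == 0.0
    assert abs(bcpnn_ic(t)[0]) < 0.2  # shrinkage keeps it near zero


def test_row_swap_inverts_ror():
    t = tab(10, 90, 100, 9900)
    s = tab(100, 9900, 10, 90)
    assert ror_ci(s)[0] == pytest.approx(1 / ror_ci(t)[0])


def test_zero_cell_flags_undefined():
    assert ror_ci(tab(0, 5, 5, 5)) is None
    assert prr_ci(tab(5, 5, 0, 5)) is None
    assert chi_square_yates(tab(0, 0, 5, 5)) is None


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


def test_fisher_maximal_probability_table():
    assert fisher_exact_two_sided(tab(1, 1, 1, 1)) == 1.0


def test_fisher_full_enumeration_example():
    assert fisher_exact_two_sided(tab(5, 0, 0, 5)) == pytest.approx(
        2 / math.comb(10, 5), rel=1e-12)


def test_fisher_agrees_with_enumeration_oracle():
    for t in random_tables(80, seed=3):
        p = fisher_exact_two_sided(t)
        assert p == pytest.approx(float(fisher_oracle(t)), abs=1e-12)


def test_fisher_large_table_log_path_close_to_exact():
    # beyond the integer-enumeration limit the log-space path takes over
    t = tab(30, 600, 300, 19000)
    exact = float(fisher_oracle(t))
    assert fisher_exact_two_sided(t) == pytest.approx(exact, rel=1e-9)


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
def test_fisher_p_in_unit_interval(a, b, c, d):
    p = fisher_exact_two_sided(tab(a, b, c, d))
    assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------


def test_chi2_against_textbook_formula():
    t = tab(10, 90, 100, 9900)
    # independent evaluation: N(|ad-bc| - N/2)^2 / (row and column products)
    a, b, c, d = 10, 90, 100, 9900
    N = a + b + c + d
    expect = N * (abs(a * d - b * c) - N / 2) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d))
    assert chi_square_yates(t) == pytest.approx(expect, rel=1e-12)


def test_chi2_invariant_under_row_and_column_swap():
    t = tab(7, 13, 29, 81)
    s = tab(81, 29, 13, 7)
    assert chi_square_yates(t) == pytest.approx(chi_square_yates(s))
    assert chi_square_pearson(t) == pytest.approx(chi_square_pearson(s))


def test_chi2_clamps_small_deviations_to_zero():
    assert chi_square_yates(tab(5, 45, 50, 450)) == 0.0


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------


def test_ic_matches_monte_carlo_posterior_spot_checks():
    for i, t in enumerate([tab(10, 90, 100, 9900), tab(5, 45, 50, 450),
                           tab(30, 500, 300, 9000)]):
        ic, lo, hi = bcpnn_ic(t)
        m_ic, m_lo, m_hi = ic_mc_oracle(t, seed=i)
        assert ic == pytest.approx(m_ic, abs=0.05)
        assert lo == pytest.approx(m_lo, abs=0.1)
        assert hi == pytest.approx(m_hi, abs=0.1)


def test_ic_negative_when_count_below_expectation():
    ic, lo, hi = bcpnn_ic(tab(0, 1000, 1000, 100000))
    assert ic < 0


def test_ic_bounds_bracket_point():
    ic, lo, hi = bcpnn_ic(tab(12, 400, 300, 20000))
    assert lo < ic < hi


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("ic_lo,expected", [
    (-0.1, "none"), (0.0, "none"), (0.5, "weak"), (1.4999, "weak"),
    (1.5, "medium"), (2.9999, "medium"), (3.0, "strong"), (5.0, "strong"),
])
def test_ic_strength_bands(ic_lo, expected):
    assert ic_strength(ic_lo) == expected


def test_met_ror_requires_both_conditions():
    from pvsignal.disprop import MetricResult
    r = MetricResult(drug="x", n11=5, n12=5, n21=5, n22=5,
                     ror_lo=1.2, fisher_p=0.06)
    classify_signal(r, SignalCriteria())
    assert not r.met_ror


def test_prr_threshold_strict_at_two_vs_one():
    from pvsignal.disprop import MetricResult
    r = MetricResult(drug="x", n11=5, n12=5, n21=5, n22=5,
                     prr_lo=1.5, chi2=10.0)
    classify_signal(r, SignalCriteria())
    assert not r.met_prr  # main criterion: PRR025 > 2
    classify_signal(r, SignalCriteria(prr_lower_gt=1.0))
    assert r.met_prr  # conventional criterion: PRR025 > 1


def test_low_count_exclusion_blanks_everything():
    res = compute_metrics("x", tab(2, 100, 50, 5000), SignalCriteria())
    assert res.excluded_low_count
    assert res.ror is None and res.ic is None
    assert not (res.met_ror or res.met_prr or res.met_ic)
    assert res.ic_strength == "none"


def test_criteria_monotone_in_n11():
    # growing the co-report count with the rest fixed never turns a signal off
    met, ps = [], []
    for n11 in range(3, 40):
        r = compute_metrics("x", tab(n11, 100, 50, 5000), SignalCriteria())
        met.append(r.met_ror)
        ps.append(r.fisher_p)
    first_true = met.index(True)
    assert all(met[first_true:])
    assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(ps[first_true:], ps[first_true + 1:]))


# ---------------------------------------------------------------------------
# table building and screening
# ---------------------------------------------------------------------------


def _mini_plid():
    from pvsignal.icsr_io import CaseEvent, DrugExposure, PlidCase

    def case(cid, drugs, events):
        return PlidCase(
            case_id=cid,
            drugs=tuple(DrugExposure(d, d, "suspected", i + 1, ())
                        for i, d in enumerate(drugs)),
            events=tuple(CaseEvent(None, e, None) for e in events),
            max_drug_seq=len(drugs),
        )
    return case


def test_one_case_per_cell():
    case = _mini_plid()
    plid = [case("1", ["mirabegron"], ["atrial fibrillation"]),
            case("2", ["mirabegron"], []),
            case("3", ["other"], ["atrial fibrillation"]),
            case("4", ["other"], [])]
    t = build_contingency(plid, {"mirabegron"},
                          EventTarget.of(None, ["atrial fibrillation"]))
    assert t.cells() == (1, 1, 1, 1)


def test_case_counted_once_despite_duplicate_listings():
    from pvsignal.icsr_io import CaseEvent, DrugExposure, PlidCase
    c = PlidCase(case_id="1",
                 drugs=(DrugExposure("mirabegron", "mirabegron", "suspected", 1, ()),
                        DrugExposure("mirabegron", "mirabegron", "concomitant", 2, ())),
                 events=(CaseEvent(None, "atrial fibrillation", None),),
                 max_drug_seq=2)
    t = build_contingency([c], {"mirabegron"},
                          EventTarget.of(None, ["atrial fibrillation"]))
    assert t.cells() == (1, 0, 0, 0)


def test_contingency_matches_ground_truth_oracle(jader_draw, af_target):
    cfg, raw, truth = jader_draw
    plid, _ = build_plid(raw, synonyms=default_synonyms())
    by_id = {c.case_id: c for c in plid}
    order = [by_id[cid] for cid in truth.case_ids]
    for drug in ("solifenacin", "vibegron"):
        t = build_contingency(order, {drug}, af_target)
        exp = truth.exposure[drug]
        ev = truth.events["Atrial fibrillation"]
        brute = (int((exp & ev).sum()), int((exp & ~ev).sum()),
                 int((~exp & ev).sum()), int((~exp & ~ev).sum()))
        assert t.cells() == brute


def test_screen_cells_partition_the_plid(jader_draw, af_target):
    _, raw, _ = jader_draw
    plid, _ = build_plid(raw, synonyms=default_synonyms())
    for r in screen(plid, ["solifenacin", "mirabegron", "vibegron"], af_target):
        assert r.n11 + r.n12 + r.n21 + r.n22 == len(plid)


def test_rare_event_ror_prr_equivalence():
    rng = np.random.default_rng(8)
    for _ in range(200):
        n11 = int(rng.integers(5, 50))
        n12 = int(rng.integers(500, 3000))
        n21 = int(rng.integers(50, 500))
        n22 = int(rng.integers(40000, 120000))
        t = tab(n11, n12, n21, n22)
        if t.n11 / t.n1p >= 0.05 or t.n21 / t.n2p >= 0.05:
            continue
        ror, prr = ror_ci(t)[0], prr_ci(t)[0]
        assert abs(ror - prr) / prr < 0.05


def test_prr_ci_brackets_point_on_random_tables():
    for t in random_tables(300, seed=9, max_margin=25):
        if t.n11 == 0 or t.n21 == 0:
            continue
        r = prr_ci(t)
        if r is None:
            continue
        p, lo, hi = r
        assert lo <= p <= hi


def test_haldane_option_rescues_zero_cells_but_stays_off_by_default():
    t = tab(0, 10, 10, 100)
    assert ror_ci(t) is None
    r, lo, hi = ror_ci(t, haldane=True)
    assert r == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))
    assert lo < r < hi
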