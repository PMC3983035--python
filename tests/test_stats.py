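"""Fisher/BH against independent oracles; expression filter; direction calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import hypergeom

from splicemap.events import EventCounts
from splicemap.stats import test_all_events as run_splicing_tests
from splicemap.stats import (
    bh_adjust,
    fisher_exact_two_sided,
    rpkm,
    rpkm_and_expression_filter,
    significant_summary,
)


# ---------------------------------------------------------------------------
# Oracles


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration of same-margin tables."""
    row1, col1, n = a + b, a + c, a + b + c + d
    support = range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    probs = {k: hypergeom.pmf(k, n, col1, row1) for k in support}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def bh_oracle(pvals):
    """Textbook step-up: q_(i) = min_{j>=i} m p_(j) / j, original order."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = math.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(1.0, running)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Fisher


def test_fisher_extreme_table_closed_form():
    # all-or-nothing 10/10 table: two tables at minimal probability
    assert fisher_exact_two_sided((10, 0, 0, 10)) == pytest.approx(
        2 / 184756, rel=1e-9
    )


def test_fisher_balanced_table_is_one():
    assert fisher_exact_two_sided((5, 5, 5, 5)) == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(17)
    for _ in range(300):
        a, b, c, d = rng.integers(0, 40, size=4)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        p = fisher_exact_two_sided((a, b, c, d))
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7)


def test_fisher_specific_table_against_oracle():
    assert fisher_exact_two_sided((12, 3, 4, 11)) == pytest.approx(
        fisher_oracle(12, 3, 4, 11), rel=1e-9
    )


def test_fisher_row_column_swap_invariance():
    p = fisher_exact_two_sided((12, 3, 4, 11))
    assert fisher_exact_two_sided((4, 11, 12, 3)) == pytest.approx(p)
    assert fisher_exact_two_sided((3, 12, 11, 4)) == pytest.approx(p)


def test_fisher_proportional_table_is_one():
    assert fisher_exact_two_sided((6, 9, 2, 3)) == pytest.approx(1.0)


def test_fisher_rejects_untestable():
    for table in [(0, 0, 3, 4), (3, 0, 4, 0), (0, 3, 0, 4), (1, 2, -1, 3)]:
        with pytest.raises(ValueError):
            fisher_exact_two_sided(table)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_single_p_identity():
    assert bh_adjust([0.01]) == pytest.approx([0.01])


def test_bh_hand_computed_step_up():
    # min over j>=i of (4 p_j / j): all collapse to 0.04
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    hst.lists(
        hst.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
        min_size=1,
        max_size=200,
    )
)
def test_bh_matches_oracle_and_is_monotone(pvals):
    q = bh_adjust(pvals)
    assert q == pytest.approx(bh_oracle(pvals), rel=1e-12, abs=1e-12)
    assert np.all(q >= np.asarray(pvals) - 1e-15)
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_rejection_set_equals_classical_step_up():
    rng = np.random.default_rng(23)
    for _ in range(50):
        p = rng.random(rng.integers(1, 120))
        alpha = 0.05
        q = bh_adjust(p)
        # classical: reject the k largest-ranked with p_(i) <= i alpha / m
        m = p.size
        srt = np.sort(p)
        ks = np.nonzero(srt <= (np.arange(1, m + 1) * alpha / m))[0]
        k = ks[-1] + 1 if ks.size else 0
        classical = set(np.argsort(p, kind="stable")[:k])
        assert set(np.nonzero(q < alpha + 1e-15)[0]) | set(
            np.nonzero(q <= alpha)[0]
        ) >= classical
        assert set(np.nonzero(q <= alpha)[0]) == classical


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_adjust([])
    with pytest.raises(ValueError):
        bh_adjust([0.0, 0.5])
    with pytest.raises(ValueError):
        bh_adjust([1.5])


# ---------------------------------------------------------------------------
# test_all_events


def _ec(event_id, sample, inc, exc, n_inc=2, n_exc=1):
    return EventCounts(event_id, sample, inc, exc, n_inc, n_exc, "SE", f"gene_{event_id}")


def test_single_extreme_event_is_significant_with_direction():
    res = run_splicing_tests([_ec("e1", "control", 10, 0)], [_ec("e1", "treated", 0, 10)])
    (r,) = res
    assert r.significant and r.q == pytest.approx(r.p)
    assert r.delta_psi < 0 and r.direction == "activated"
    assert r.psi_control == 1.0 and r.psi_treated == 0.0


def test_untestable_events_excluded_before_bh():
    ctrl = [_ec("e1", "control", 10, 0), _ec("dead", "control", 0, 0)]
    trt = [_ec("e1", "treated", 0, 10), _ec("dead", "treated", 0, 0)]
    res = run_splicing_tests(ctrl, trt)
    assert [r.event_id for r in res] == ["e1"]


def test_fold_change_is_psi_ratio():
    res = run_splicing_tests(
        [_ec("e1", "control", 10, 10)], [_ec("e1", "treated", 30, 10)]
    )
    (r,) = res
    # psi_c = 5/(5+10) = 1/3; psi_t = 15/25 = 0.6
    assert r.fold_change == pytest.approx(0.6 / (1 / 3))


def test_power_and_fdr_on_null_plus_signal_counts():
    """Small-scale detection check: planted dPSI=0.4 found, nulls controlled."""
    rng = np.random.default_rng(31)
    n_reads = 200
    sig_total = 0
    hits = 0
    false = 0
    n_signal, n_null, reps = 10, 50, 10
    for _ in range(reps):
        ctrl, trt = [], []
        for i in range(n_signal + n_null):
            psi_c = 0.3
            psi_t = 0.7 if i < n_signal else psi_c
            for sample, psi, out in (("control", psi_c, ctrl), ("treated", psi_t, trt)):
                w = 2 * psi / (2 * psi + (1 - psi))
                inc = int(rng.binomial(n_reads, w))
                out.append(_ec(f"e{i}", sample, inc, n_reads - inc))
        res = run_splicing_tests(ctrl, trt)
        for r in res:
            if r.significant:
                sig_total += 1
                idx = int(r.event_id[1:])
                if idx < n_signal:
                    hits += 1
                else:
                    false += 1
    assert hits / (n_signal * reps) >= 0.9
    assert false <= 0.10 * max(sig_total, 1)


def test_significant_summary_counts_genes_once():
    ctrl = [_ec("e1", "control", 10, 0), _ec("e2", "control", 10, 0)]
    trt = [_ec("e1", "treated", 0, 10), _ec("e2", "treated", 0, 10)]
    res = run_splicing_tests(ctrl, trt)
    n_events, n_genes = significant_summary(res)
    assert n_events == 2 and n_genes == 2


# ---------------------------------------------------------------------------
# RPKM filter


def test_rpkm_formula():
    assert rpkm(100, 10**6, 1000) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        rpkm(1, 0, 100)
    with pytest.raises(ValueError):
        rpkm(1, 100, 0)


def test_expression_filter_thresholds():
    lengths = {"lo": 1000, "edge": 1000, "pass": 1000}
    totals = (10**6, 10**6)
    counts = {
        "lo": (0, 0),  # rpkm (0.4, 0.3) after scaling below
        "edge": (1000, 480),  # fold ~2.08 > 2, rpkm >= 0.5
        "pass": (1000, 2100),  # fold 2.1
    }
    # construct exact RPKMs 0.4/0.3 via counts 0.4 and 0.3 per million*kb
    counts["lo"] = (400, 300)
    got = rpkm_and_expression_filter(
        {g: c for g, c in counts.items()},
        lengths,
        totals,
        min_rpkm=500,  # makes 'lo' fail on abundance (rpkm 400/300)
        min_fold=2,
    )
    assert "lo" not in got and set(got) <= {"edge", "pass"}
    got2 = rpkm_and_expression_filter(counts, lengths, totals, 0.5, 2)
    assert set(got2) == {"edge", "pass"}
    # exactly 2-fold is NOT "over 2-fold"
    got3 = rpkm_and_expression_filter(
        {"x": (1000, 500)}, {"x": 1000}, totals, 0.5, 2
    )
    assert got3 == []
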