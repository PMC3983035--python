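"""Differential-splicing tests: Fisher 2x2 per event, BH across events.

Each event contributes a 2x2 contingency table of inclusion/exclusion read
counts in the control and treated (knockdown) libraries — one library per
condition, no replicates. Events with an all-zero row or column are
untestable and are excluded *before* the Benjamini-Hochberg step (they do
not inflate m). The direction call interprets the treated sample as a
regulator knockdown: an exon whose inclusion falls on knockdown
(delta PSI < 0) is *regulator-activated*, one whose inclusion rises is
*regulator-repressed*.

The module also hosts the RPKM-based expression filter used to separate
abundance changes from splicing changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .events import EventCounts, compute_psi

__all__ = [
    "fisher_exact_two_sided",
    "bh_adjust",
    "SplicingTestResult",
    "test_all_events",
    "significant_summary",
    "results_frame",
    "rpkm",
    "rpkm_and_expression_filter",
]


def _untestable(a: int, b: int, c: int, d: int) -> bool:
    return (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)


def fisher_exact_two_sided(table: Sequence[Sequence[int]] | tuple[int, int, int, int]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table ``[[a, b], [c, d]]``.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed one.
    Tables with an all-zero row or column are rejected.
    """
    flat = np.asarray(table, dtype=np.int64).ravel()
    if flat.size != 4:
        raise ValueError("expected a 2x2 table")
    a, b, c, d = (int(x) for x in flat)
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts")
    if _untestable(a, b, c, d):
        raise ValueError("table with an all-zero row or column is untestable")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class SplicingTestResult:
    """Per-event differential-splicing call."""

    event_id: str
    event_type: str
    gene_id: str
    a: int  # inclusion, control
    b: int  # exclusion, control
    c: int  # inclusion, treated
    d: int  # exclusion, treated
    psi_control: float
    psi_treated: float
    delta_psi: float
    fold_change: float
    p: float
    q: float
    significant: bool
    direction: Optional[str]  # "activated" / "repressed" when significant


def test_all_events(
    counts_control: Sequence[EventCounts],
    counts_treated: Sequence[EventCounts],
    alpha: float = 0.05,
) -> list[SplicingTestResult]:
    """Fisher + BH over all testable events; results in control-count order.

    Events present in only one sample get zero counts in the other; events
    whose table has an all-zero row or column are dropped before adjustment.
    """
    ctrl = {c.event_id: c for c in counts_control}
    trt = {c.event_id: c for c in counts_treated}
    if len(ctrl) != len(counts_control) or len(trt) != len(counts_treated):
        raise ValueError("duplicate event ids within a sample")
    order = list(ctrl)
    order += [e for e in trt if e not in ctrl]

    tested: list[tuple[EventCounts, int, int, int, int]] = []
    for event_id in order:
        base = ctrl.get(event_id) or trt[event_id]
        cc, ct = ctrl.get(event_id), trt.get(event_id)
        a = cc.inclusion_reads if cc else 0
        b = cc.exclusion_reads if cc else 0
        c = ct.inclusion_reads if ct else 0
        d = ct.exclusion_reads if ct else 0
        if _untestable(a, b, c, d):
            continue
        tested.append((base, a, b, c, d))
    if not tested:
        return []

    pvals = np.array(
        [fisher_exact_two_sided((a, b, c, d)) for _, a, b, c, d in tested]
    )
    qvals = bh_adjust(pvals)

    results = []
    for (base, a, b, c, d), p, q in zip(tested, pvals, qvals):
        psi_c = compute_psi(a, b, base.n_inclusion, base.n_exclusion)
        psi_t = compute_psi(c, d, base.n_inclusion, base.n_exclusion)
        delta = psi_t - psi_c
        fold = psi_t / psi_c if psi_c > 0 else math.inf
        significant = bool(q < alpha)
        direction = None
        if significant:
            direction = "activated" if delta < 0 else "repressed"
        results.append(
            SplicingTestResult(
                event_id=base.event_id,
                event_type=base.event_type,
                gene_id=base.gene_id,
                a=a,
                b=b,
                c=c,
                d=d,
                psi_control=psi_c,
                psi_treated=psi_t,
                delta_psi=delta,
                fold_change=fold,
                p=float(p),
                q=float(q),
                significant=significant,
                direction=direction,
            )
        )
    return results


def significant_summary(results: Sequence[SplicingTestResult]) -> tuple[int, int]:
    """(significant events, genes with >= 1 significant event)."""
    sig = [r for r in results if r.significant]
    return len(sig), len({r.gene_id for r in sig})


def results_frame(results: Sequence[SplicingTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def rpkm(count: int, total: int, length_nt: int) -> float:
    """Reads per kilobase of gene model per million mapped reads."""
    if total <= 0:
        raise ValueError("zero total mapped reads")
    if length_nt <= 0:
        raise ValueError("zero gene length")
    return 1e9 * count / (total * length_nt)


def rpkm_and_expression_filter(
    gene_counts: Mapping[str, tuple[int, int]],
    gene_lengths: Mapping[str, int],
    totals: tuple[int, int],
    min_rpkm: float = 0.5,
    min_fold: float = 2.0,
) -> list[str]:
    """Genes with an expression change beyond ``min_fold`` at ``min_rpkm``.

    A gene passes when the larger of its two RPKMs is at least ``min_rpkm``
    and the between-condition fold change (larger/smaller) strictly exceeds
    ``min_fold``. A zero in one condition with expression in the other counts
    as an infinite fold change.
    """
    total_c, total_t = totals
    passing = []
    for gene, (count_c, count_t) in gene_counts.items():
        r_c = rpkm(count_c, total_c, gene_lengths[gene])
        r_t = rpkm(count_t, total_t, gene_lengths[gene])
        hi, lo = max(r_c, r_t), min(r_c, r_t)
        if hi < min_rpkm:
            continue
        fold = math.inf if lo == 0 else hi / lo
        if fold > min_fold:
            passing.append(gene)
    return passing
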