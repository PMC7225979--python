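"""Kaplan-Meier estimation and log-rank (Mantel-Cox) comparison.

Both statistics are computed from the standard risk-table formulas.

Kaplan-Meier product-limit estimator: at each distinct event time t_i with
n_i patients at risk and d_i events, S(t) = prod_{t_i <= t} (1 - d_i/n_i).
Censored times reduce the risk set without producing a step; at tied times
events precede censorings (a patient censored at t_i is still at risk at
t_i).

Log-rank test: at each distinct pooled event time, the observed events in
group A are compared with their expectation under the null that both
groups share a hazard, E = d_j * n_Aj / n_j, with hypergeometric variance
V_j = d_j (n_Aj/n_j)(1 - n_Aj/n_j)(n_j - d_j)/(n_j - 1). The statistic
(O - E)^2 / V is chi-square with 1 df; the p-value is two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import SurvivalRecord
from .recurrence import MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "km_estimate",
    "median_survival",
    "LogrankResult",
    "logrank_test",
    "GeneSurvivalComparison",
    "compare_by_gene",
]


def _times_events(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    return times, events


def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival curve.

    Returns one row per distinct event time with columns ``time``,
    ``n_at_risk``, ``n_events``, ``n_censored`` (censorings at that exact
    time) and ``survival`` (S evaluated at the time, after the step).
    S(0) = 1 by construction; with no events the curve is identically 1
    and the frame is empty.
    """
    if not records:
        raise ValueError("no survival records")
    times, events = _times_events(records)
    event_times = np.unique(times[events])
    rows = []
    surv = 1.0
    for t in event_times:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        c = int(((times == t) & ~events).sum())
        surv *= 1.0 - d / n_at_risk
        rows.append({"time": float(t), "n_at_risk": n_at_risk,
                     "n_events": d, "n_censored": c, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                       "n_censored", "survival"])


def median_survival(records: Sequence[SurvivalRecord]) -> float:
    """Smallest event time with S(t) <= 0.5, or NaN if never reached."""
    curve = km_estimate(records)
    hit = curve[curve["survival"] <= 0.5]
    return float(hit["time"].iloc[0]) if len(hit) else float("nan")


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    n_a: int
    n_b: int
    observed_a: float
    expected_a: float


def logrank_test(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
) -> LogrankResult:
    """Two-sided log-rank (Mantel-Cox) test between two groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    t_a, e_a = _times_events(group_a)
    t_b, e_b = _times_events(group_b)
    all_times = np.concatenate([t_a, t_b])
    all_events = np.concatenate([e_a, e_b])
    if not all_events.any():
        raise ValueError("no events in either group")
    event_times = np.unique(all_times[all_events])
    observed = expected = variance = 0.0
    for t in event_times:
        n_aj = int((t_a >= t).sum())
        n_bj = int((t_b >= t).sum())
        n_j = n_aj + n_bj
        d_aj = int(((t_a == t) & e_a).sum())
        d_j = d_aj + int(((t_b == t) & e_b).sum())
        observed += d_aj
        expected += d_j * n_aj / n_j
        if n_j > 1:
            variance += (d_j * (n_aj / n_j) * (1.0 - n_aj / n_j)
                         * (n_j - d_j) / (n_j - 1))
    if variance == 0.0:
        chi = 0.0
        p = 1.0
    else:
        chi = (observed - expected) ** 2 / variance
        p = float(stats.chi2.sf(chi, df=1))
    return LogrankResult(chi_square=float(chi), p_value=p,
                         n_a=len(group_a), n_b=len(group_b),
                         observed_a=float(observed), expected_a=float(expected))


@dataclass
class GeneSurvivalComparison:
    """Mutated vs wild-type comparison for one gene and endpoint."""

    gene: str
    endpoint: str
    result: LogrankResult
    curves: dict[str, pd.DataFrame]      # "mutant" / "wildtype"
    medians: dict[str, float]
    n_excluded: int                      # patients without survival data


def compare_by_gene(
    matrix: MutationMatrix,
    records: Iterable[SurvivalRecord],
    gene: str,
    endpoint: str = "PFS",
) -> GeneSurvivalComparison:
    """Log-rank comparison of survival by mutation status of ``gene``.

    Groups are formed from the mutation matrix; records are restricted to
    patients present in both inputs (patients lacking survival data are
    counted and logged). Raises if the gene is absent or only one group is
    populated.
    """
    if gene not in matrix.genes:
        raise KeyError(f"gene {gene!r} not in mutation matrix")
    status = matrix.mutated[gene]
    recs = [r for r in records if r.endpoint == endpoint]
    with_data = {r.patient_id for r in recs}
    matrix_patients = set(matrix.patients)
    usable = [r for r in recs if r.patient_id in matrix_patients]
    n_excluded = len(matrix_patients - with_data)
    if n_excluded:
        logger.info("compare_by_gene(%s, %s): %d patients lack survival data",
                    gene, endpoint, n_excluded)
    mut = [r for r in usable if bool(status[r.patient_id])]
    wt = [r for r in usable if not bool(status[r.patient_id])]
    if not mut or not wt:
        raise ValueError(
            f"single group: {len(mut)} mutated vs {len(wt)} wild-type "
            f"records for {gene}/{endpoint}"
        )
    result = logrank_test(mut, wt)
    curves = {"mutant": km_estimate(mut), "wildtype": km_estimate(wt)}
    medians = {"mutant": median_survival(mut), "wildtype": median_survival(wt)}
    return GeneSurvivalComparison(gene=gene, endpoint=endpoint, result=result,
                                  curves=curves, medians=medians,
                                  n_excluded=n_excluded)
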