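"""Per-gene copy-number calling from tumor/normal coverage and
cross-patient recurrence enrichment.

The procedure works on per-gene mean read coverage of a matched
tumor/normal pair:

1. *Mean-shift normalization*: the sample with the lower mean coverage is
   shifted up by adding the difference of the two sample means to every
   gene, so both samples share a mean. The shift is additive by design —
   it assumes most genes are copy-neutral and preserves within-sample
   differences exactly.
2. *log2 ratios*: per gene, log2((tumor + eps) / (normal + eps)) with a
   floor of eps = 0.5 reads guarding against zero coverage.
3. *State calls*: gain if ratio >= +0.3, loss if ratio <= -0.3 (both
   inclusive, configurable), neutral otherwise. Genes with zero coverage
   in both samples are flagged 'nocall' and excluded from enrichment.
4. *Recurrence enrichment*: per gene and direction, a one-sided Fisher
   exact test of the patients carrying the state at the focal gene against
   the cohort-wide background rate of that state over all other
   (patient, gene) cells, Benjamini-Hochberg adjusted across genes within
   each direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CoveragePair

__all__ = [
    "CnvCallSet",
    "normalize_pair",
    "log2_ratio",
    "call_states",
    "call_cnv",
    "recurrence_enrichment",
    "LOG2_EPSILON",
    "GAIN_THRESHOLD",
    "LOSS_THRESHOLD",
]

LOG2_EPSILON = 0.5
GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3

STATES = ("gain", "neutral", "loss", "nocall")


@dataclass
class CnvCallSet:
    """Per-gene log2 ratios and copy-number states for one patient."""

    patient_id: str
    genes: list[str]
    log2_ratio: np.ndarray
    states: np.ndarray  # of STATES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.genes,
            "log2_ratio": self.log2_ratio,
            "state": self.states,
        })


def normalize_pair(pair: CoveragePair) -> CoveragePair:
    """Shift the lower-mean sample so both samples share a mean coverage.

    The difference of the two sample means is added to every gene of the
    lower-mean sample; the higher-mean sample is untouched. Raises on an
    all-zero coverage vector, for which no meaningful ratio profile exists.
    """
    if not pair.tumor_cov.any():
        raise ValueError(f"all-zero tumor coverage for {pair.patient_id}")
    if not pair.normal_cov.any():
        raise ValueError(f"all-zero normal coverage for {pair.patient_id}")
    m_t = float(pair.tumor_cov.mean())
    m_n = float(pair.normal_cov.mean())
    tumor, normal = pair.tumor_cov.copy(), pair.normal_cov.copy()
    if m_t < m_n:
        tumor = tumor + (m_n - m_t)
    elif m_n < m_t:
        normal = normal + (m_t - m_n)
    return CoveragePair(pair.patient_id, list(pair.genes), tumor, normal)


def log2_ratio(pair: CoveragePair, eps: float = LOG2_EPSILON) -> np.ndarray:
    """Per-gene log2((tumor + eps) / (normal + eps)) on a normalized pair."""
    return np.log2((pair.tumor_cov + eps) / (pair.normal_cov + eps))


def call_states(
    log2_ratios: np.ndarray,
    gain_thresh: float = GAIN_THRESHOLD,
    loss_thresh: float = LOSS_THRESHOLD,
) -> np.ndarray:
    """Gain iff ratio >= gain_thresh, loss iff ratio <= loss_thresh."""
    if not gain_thresh > 0 > loss_thresh:
        raise ValueError("thresholds must satisfy gain > 0 > loss")
    ratios = np.asarray(log2_ratios, dtype=float)
    states = np.full(ratios.shape, "neutral", dtype=object)
    states[ratios >= gain_thresh] = "gain"
    states[ratios <= loss_thresh] = "loss"
    return states


def call_cnv(
    pair: CoveragePair,
    gain_thresh: float = GAIN_THRESHOLD,
    loss_thresh: float = LOSS_THRESHOLD,
    eps: float = LOG2_EPSILON,
) -> CnvCallSet:
    """Full per-gene pipeline: normalize, log2 ratio, state call.

    Genes with zero coverage in both samples carry no copy-number signal
    and are flagged 'nocall' rather than called.
    """
    undefined = (pair.tumor_cov == 0) & (pair.normal_cov == 0)
    norm = normalize_pair(pair)
    ratios = log2_ratio(norm, eps=eps)
    states = call_states(ratios, gain_thresh, loss_thresh)
    states[undefined] = "nocall"
    return CnvCallSet(pair.patient_id, list(pair.genes), ratios, states)


def _direction_enrichment(state_matrix: np.ndarray, direction: str) -> np.ndarray:
    """One-sided Fisher p per gene for over-representation of a state.

    Table per focal gene g: [patients with the state at g, patients
    without] vs [background cells with the state, background cells
    without], the background being all (patient, gene) cells excluding
    gene g ('nocall' cells excluded throughout).
    """
    callable_ = state_matrix != "nocall"
    hits = (state_matrix == direction)
    n_genes = state_matrix.shape[1]
    hit_per_gene = hits.sum(axis=0)
    callable_per_gene = callable_.sum(axis=0)
    total_hits = int(hits.sum())
    total_cells = int(callable_.sum())
    pvals = np.ones(n_genes)
    for j in range(n_genes):
        a = int(hit_per_gene[j])
        b = int(callable_per_gene[j]) - a
        c = total_hits - a
        d = (total_cells - int(callable_per_gene[j])) - c
        if a == 0:
            continue  # p = 1 for the one-sided greater test
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        pvals[j] = float(p)
    return pvals


def recurrence_enrichment(
    callsets: Sequence[CnvCallSet],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-patient recurrence of gains/losses with Fisher + BH-FDR.

    Returns one row per gene with recurrence counts (n_gain, n_loss), raw
    one-sided Fisher p-values against the cohort-wide background rate
    (p_gain, p_loss), BH-adjusted q-values computed within each direction
    (q_gain, q_loss), and ``significant`` = min(q) < alpha.
    """
    if len(callsets) < 2:
        raise ValueError("recurrence enrichment needs >= 2 patients")
    genes = callsets[0].genes
    for cs in callsets[1:]:
        if cs.genes != genes:
            raise ValueError(
                f"inconsistent gene universe for patient {cs.patient_id}"
            )
    state_matrix = np.vstack([cs.states for cs in callsets])
    p_gain = _direction_enrichment(state_matrix, "gain")
    p_loss = _direction_enrichment(state_matrix, "loss")
    q_gain = multipletests(p_gain, method="fdr_bh")[1]
    q_loss = multipletests(p_loss, method="fdr_bh")[1]
    frame = pd.DataFrame({
        "gene": genes,
        "n_gain": (state_matrix == "gain").sum(axis=0).astype(int),
        "n_loss": (state_matrix == "loss").sum(axis=0).astype(int),
        "n_patients": len(callsets),
        "p_gain": p_gain,
        "p_loss": p_loss,
        "q_gain": q_gain,
        "q_loss": q_loss,
    })
    frame["significant"] = (frame[["q_gain", "q_loss"]].min(axis=1) < alpha)
    return frame
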