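"""Somatic variant filter cascades.

Three rule sets are implemented:

* :func:`filter_wgs` — the tumor/normal whole-genome cascade: functional
  impact at least MODERATE, >= 5 variant reads with support on both strands,
  no significant strand bias, absence from the matched normal, and exclusion
  of known (database-annotated) variants.
* :func:`filter_targeted` — the deep amplicon-panel cascade: non-synonymous
  and novel variants only, frameshifts in homopolymer runs removed, strand
  bias below a phred-scaled cutoff of 100, VAF >= 10%.
* :func:`select_panel` — the panel-selection rule combining genome-wide and
  exome screens: any gene mutated in >= 1 whole-genome case, any gene mutated
  in >= 2 exome cases, plus explicitly forced candidates.

Strand bias is scored as -10*log10 of the two-sided Fisher exact p-value of
the 2x2 table [variant fwd/rev ; reference fwd/rev]; a perfectly balanced
table scores 0, and larger scores mean stronger imbalance. The same score
serves both cascades so "no significant strand bias" has a single meaning.

Every removed call is annotated with *all* the rules it failed, so the
cascades double as an audit trail.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .model import IMPACT_RANK, SAMPLE_TYPES, VariantCall

__all__ = [
    "FilterConfig",
    "FilterResult",
    "strand_bias_score",
    "filter_wgs",
    "filter_targeted",
    "filter_quality",
    "choose_one_sample_per_patient",
    "select_panel",
]


@dataclass
class FilterConfig:
    """Thresholds for the filter cascades.

    Defaults reproduce the published cascades: impact at least MODERATE,
    < 5 variant reads removed, at least two forward and two reverse variant
    reads, strand bias below 100 (phred), VAF minimum 10% (inclusive),
    caller quality above 500 (exclusive), frameshifts inside homopolymer
    runs of >= 4 identical bases removed, known variants excluded.
    """

    min_impact: str = "MODERATE"
    min_var_reads: int = 5
    min_fwd: int = 2
    min_rev: int = 2
    strand_bias_max: float = 100.0
    min_vaf: float = 0.10
    min_quality: float = 500.0
    homopolymer_min_len: int = 4
    exclude_known: bool = True

    def __post_init__(self) -> None:
        if self.min_impact not in IMPACT_RANK:
            raise ValueError(f"unknown impact {self.min_impact!r}")
        for name in ("min_var_reads", "min_fwd", "min_rev", "strand_bias_max",
                     "min_quality", "homopolymer_min_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError(f"min_vaf must be in [0, 1], got {self.min_vaf}")


@dataclass
class FilterResult:
    """Retained calls plus the removed ones with the rules each failed."""

    retained: list[VariantCall]
    removed: list[tuple[VariantCall, tuple[str, ...]]]

    def reasons(self) -> Counter:
        """Count how often each rule fired (a call can fail several)."""
        c: Counter = Counter()
        for _, why in self.removed:
            c.update(why)
        return c

    def audit_frame(self) -> pd.DataFrame:
        """Removal audit as a table (one row per removed call)."""
        rows = [
            {
                "patient_id": call.patient_id,
                "sample_id": call.sample_id,
                "gene": call.gene,
                "chrom": call.chrom,
                "pos": call.pos,
                "ref": call.ref,
                "alt": call.alt,
                "vaf": call.vaf,
                "failed_rules": ",".join(why),
            }
            for call, why in self.removed
        ]
        return pd.DataFrame(
            rows,
            columns=["patient_id", "sample_id", "gene", "chrom", "pos",
                     "ref", "alt", "vaf", "failed_rules"],
        )


def strand_bias_score(var_fwd: int, var_rev: int, ref_fwd: int, ref_rev: int) -> float:
    """Phred-scaled strand-bias score.

    -10*log10 of the two-sided Fisher exact p-value of
    [[var_fwd, var_rev], [ref_fwd, ref_rev]]. 0 iff p = 1 (no imbalance).
    """
    counts = (var_fwd, var_rev, ref_fwd, ref_rev)
    if any(c < 0 for c in counts):
        raise ValueError("read counts must be >= 0")
    if sum(counts) == 0:
        raise ValueError("all-zero read count table")
    _, p = stats.fisher_exact([[var_fwd, var_rev], [ref_fwd, ref_rev]],
                              alternative="two-sided")
    p = min(float(p), 1.0)
    return max(0.0, -10.0 * math.log10(p))


def _call_strand_bias(call: VariantCall) -> float:
    return strand_bias_score(call.var_fwd, call.var_rev, call.ref_fwd, call.ref_rev)


def filter_wgs(
    tumor_calls: Iterable[VariantCall],
    normal_calls: Iterable[VariantCall],
    config: FilterConfig | None = None,
) -> FilterResult:
    """Tumor/normal somatic filter cascade for whole-genome calls.

    A tumor call is retained iff it passes *all* of: impact >= min_impact;
    total variant reads >= min_var_reads; at least min_fwd forward and
    min_rev reverse variant reads; strand-bias score < strand_bias_max;
    no call at the same (chrom, pos, ref, alt) in the normal; and (if
    ``exclude_known``) not flagged as a known variant.
    """
    config = config or FilterConfig()
    normal_sites = {c.site_key for c in normal_calls}
    min_rank = IMPACT_RANK[config.min_impact]

    retained: list[VariantCall] = []
    removed: list[tuple[VariantCall, tuple[str, ...]]] = []
    for call in tumor_calls:
        why: list[str] = []
        if IMPACT_RANK[call.impact] < min_rank:
            why.append("impact")
        if call.var_reads < config.min_var_reads:
            why.append("var_reads")
        if call.var_fwd < config.min_fwd or call.var_rev < config.min_rev:
            why.append("direction")
        if call.depth > 0 and _call_strand_bias(call) >= config.strand_bias_max:
            why.append("strand_bias")
        if call.site_key in normal_sites:
            why.append("in_normal")
        if config.exclude_known and call.known_variant:
            why.append("known")
        if why:
            removed.append((call, tuple(why)))
        else:
            retained.append(call)
    return FilterResult(retained, removed)


def filter_targeted(
    calls: Iterable[VariantCall],
    config: FilterConfig | None = None,
) -> FilterResult:
    """Deep amplicon-panel filter cascade.

    A call is retained iff it is non-synonymous, novel (not a known
    variant), not a frameshift inside a homopolymer run of
    >= homopolymer_min_len bases, has strand-bias score < strand_bias_max,
    and VAF >= min_vaf (inclusive).
    """
    config = config or FilterConfig()
    retained: list[VariantCall] = []
    removed: list[tuple[VariantCall, tuple[str, ...]]] = []
    for call in calls:
        why: list[str] = []
        if call.consequence == "synonymous":
            why.append("synonymous")
        if config.exclude_known and call.known_variant:
            why.append("known")
        if (call.consequence == "frameshift"
                and call.homopolymer_len >= config.homopolymer_min_len):
            why.append("homopolymer_frameshift")
        if call.depth > 0 and _call_strand_bias(call) >= config.strand_bias_max:
            why.append("strand_bias")
        if call.vaf < config.min_vaf:
            why.append("vaf")
        if why:
            removed.append((call, tuple(why)))
        else:
            retained.append(call)
    return FilterResult(retained, removed)


def filter_quality(
    calls: Iterable[VariantCall],
    min_quality: float = 500.0,
) -> list[VariantCall]:
    """Keep calls with caller quality strictly above ``min_quality``.

    Applied to exome calls before panel selection ("high quality score
    > 500").
    """
    return [c for c in calls if c.quality > min_quality]


_SAMPLE_PRIORITY = {"sorted": 0, "suspension": 1, "ffpe": 2}


def choose_one_sample_per_patient(
    calls: Sequence[VariantCall],
) -> list[VariantCall]:
    """When a patient has several QC-passing samples, keep calls from one.

    Priority by expected tumor-cell purity: sorted > suspension > FFPE;
    ties broken lexicographically on sample id for determinism.
    """
    best: dict[str, tuple[int, str]] = {}
    for c in calls:
        key = (_SAMPLE_PRIORITY[c.sample_type], c.sample_id)
        if c.patient_id not in best or key < best[c.patient_id]:
            best[c.patient_id] = key
    return [c for c in calls if (best[c.patient_id][1] == c.sample_id)]


def select_panel(
    wgs_gene_sets: Mapping[str, set[str]] | Sequence[set[str]],
    wes_gene_sets: Mapping[str, set[str]] | Sequence[set[str]],
    forced: Iterable[str] = (),
) -> list[str]:
    """Select the targeted-sequencing gene panel.

    Panel = genes mutated in at least one whole-genome case, union genes
    mutated in at least two exome cases, union the forced candidates.
    Returned deduplicated in lexicographic order. Gene sets are expected to
    be post-filter (and, for exomes, post quality filter).
    """
    if isinstance(wgs_gene_sets, Mapping):
        wgs_gene_sets = list(wgs_gene_sets.values())
    if isinstance(wes_gene_sets, Mapping):
        wes_gene_sets = list(wes_gene_sets.values())
    panel: set[str] = set()
    for genes in wgs_gene_sets:
        panel.update(genes)
    wes_counts: Counter = Counter()
    for genes in wes_gene_sets:
        wes_counts.update(set(genes))
    panel.update(g for g, n in wes_counts.items() if n >= 2)
    panel.update(forced)
    return sorted(panel)
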