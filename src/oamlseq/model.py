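"""Core domain records shared across the pipeline stages.

The records deliberately mirror what a tumor/normal sequencing workflow
hands downstream once alignment, variant calling and annotation are done:
annotated variant calls with read-direction support, per-gene mean-coverage
vectors for matched tumor/normal pairs, gene loci, and time-to-event
records. Parsing of on-disk formats lives in :mod:`oamlseq.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SAMPLE_TYPES = ("ffpe", "suspension", "sorted")
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
#: Severity order used for "at least MODERATE"-style thresholds.
IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}
CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice", "synonymous", "other")
ENDPOINTS = ("PFS", "OS")

#: Tolerated discrepancy between the stored VAF and the VAF implied by the
#: read counts (callers round/estimate independently of the counts).
VAF_COUNT_TOLERANCE = 0.01


@dataclass
class VariantCall:
    """One called variant in one sample.

    Positions are 1-based (VCF convention). ``vaf`` is the variant allele
    frequency as a fraction; when read counts are present it must agree with
    the count-implied frequency to within :data:`VAF_COUNT_TOLERANCE`.
    ``homopolymer_len`` is the length of the longest identical-base run
    containing the site (0 if unknown/none), used to flag error-prone
    frameshift calls.
    """

    patient_id: str
    sample_id: str
    sample_type: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    impact: str
    consequence: str
    var_fwd: int
    var_rev: int
    ref_fwd: int
    ref_rev: int
    vaf: float
    quality: float = 0.0
    known_variant: bool = False
    homopolymer_len: int = 0

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.impact not in IMPACTS:
            raise ValueError(f"unknown impact {self.impact!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for name in ("var_fwd", "var_rev", "ref_fwd", "ref_rev", "homopolymer_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.quality < 0:
            raise ValueError("quality must be >= 0")
        depth = self.depth
        if depth > 0:
            implied = (self.var_fwd + self.var_rev) / depth
            if abs(self.vaf - implied) > VAF_COUNT_TOLERANCE:
                raise ValueError(
                    f"vaf {self.vaf:.4f} inconsistent with counts "
                    f"({implied:.4f}) at {self.chrom}:{self.pos}"
                )

    @property
    def var_reads(self) -> int:
        return self.var_fwd + self.var_rev

    @property
    def depth(self) -> int:
        return self.var_fwd + self.var_rev + self.ref_fwd + self.ref_rev

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) — the key used for tumor/normal matching
        and paired-sample overlap."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneModel:
    """Gene locus in 0-based half-open coordinates (BED convention)."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")


@dataclass
class CoveragePair:
    """Matched tumor/normal per-gene mean read coverage for one patient."""

    patient_id: str
    genes: list[str]
    tumor_cov: np.ndarray
    normal_cov: np.ndarray

    def __post_init__(self) -> None:
        self.tumor_cov = np.asarray(self.tumor_cov, dtype=float)
        self.normal_cov = np.asarray(self.normal_cov, dtype=float)
        if not (len(self.genes) == self.tumor_cov.size == self.normal_cov.size):
            raise ValueError("genes, tumor_cov and normal_cov must be equally long")
        if self.tumor_cov.size == 0:
            raise ValueError("empty coverage pair")
        if (self.tumor_cov < 0).any() or (self.normal_cov < 0).any():
            raise ValueError("coverage must be >= 0")

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in coverage universe") from None


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-event record for one patient and one endpoint.

    ``time`` is in months; ``event`` is True when progression/death was
    observed and False for censoring. ``group`` is a free label (e.g.
    mutation status) used when comparing strata.
    """

    patient_id: str
    time: float
    event: bool
    endpoint: str = "PFS"
    group: str = ""

    def __post_init__(self) -> None:
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ValueError(f"time must be a positive finite number, got {self.time}")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}")
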