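"""Patient x gene mutation matrix and cohort recurrence summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import VariantCall

__all__ = [
    "MutationMatrix",
    "build_matrix",
    "gene_frequency",
    "classify_clonality",
    "paired_concordance",
    "mean_mutation_burden",
    "round_half_up_percent",
]


@dataclass
class MutationMatrix:
    """Patient x gene mutation-presence matrix (oncoprint semantics).

    A (patient, gene) cell is *mutated* when the patient carries at least
    one retained call in that gene, regardless of multiplicity; ``max_vaf``
    holds the largest VAF among those calls (NaN where unmutated) and
    ``n_mutations`` the call count.
    """

    patients: list[str]
    genes: list[str]
    mutated: pd.DataFrame      # bool, index=patients, columns=genes
    max_vaf: pd.DataFrame      # float, NaN where unmutated
    n_mutations: pd.DataFrame  # int

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_mutated_cases(self) -> int:
        """Number of patients with >= 1 mutation in any panel gene."""
        return int(self.mutated.any(axis=1).sum())

    def mutated_percent(self) -> int:
        """Whole-number percent of patients with >= 1 mutation."""
        return round_half_up_percent(self.n_mutated_cases, self.n_patients)

    def to_wide_frame(self) -> pd.DataFrame:
        """Patients x genes table with max VAF per mutated cell, '.' else."""
        out = self.max_vaf.copy().astype(object)
        out = out.where(self.mutated, other=".")
        return out

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (patient, gene, max_vaf, n_mutations), mutated cells only."""
        rows = []
        for p in self.patients:
            for g in self.genes:
                if bool(self.mutated.at[p, g]):
                    rows.append({
                        "patient_id": p,
                        "gene": g,
                        "max_vaf": float(self.max_vaf.at[p, g]),
                        "n_mutations": int(self.n_mutations.at[p, g]),
                    })
        return pd.DataFrame(rows, columns=["patient_id", "gene", "max_vaf",
                                           "n_mutations"])


def round_half_up_percent(count: int, total: int) -> int:
    """Integer percent with ties rounded up, matching whole-percent
    reporting (9/82 -> 11, 41/82 -> 50)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


def build_matrix(
    calls: Iterable[VariantCall],
    patients: Sequence[str],
    panel: Sequence[str],
) -> MutationMatrix:
    """Aggregate retained calls into a MutationMatrix.

    Patients without calls are kept as all-unmutated rows. A call whose
    gene is not in the panel signals an upstream mis-mapping and raises.
    """
    patients = list(patients)
    panel = list(panel)
    pat_set = set(patients)
    n_mut = pd.DataFrame(0, index=patients, columns=panel, dtype=int)
    max_vaf = pd.DataFrame(np.nan, index=patients, columns=panel, dtype=float)
    for call in calls:
        if call.gene not in n_mut.columns:
            raise ValueError(f"call in gene {call.gene!r} not in panel")
        if call.patient_id not in pat_set:
            raise ValueError(f"call for unknown patient {call.patient_id!r}")
        n_mut.at[call.patient_id, call.gene] += 1
        prev = max_vaf.at[call.patient_id, call.gene]
        if np.isnan(prev) or call.vaf > prev:
            max_vaf.at[call.patient_id, call.gene] = call.vaf
    mutated = n_mut >= 1
    return MutationMatrix(patients, panel, mutated, max_vaf, n_mut)


def gene_frequency(matrix: MutationMatrix) -> pd.DataFrame:
    """Per-gene mutated-case counts, fractions and whole-number percents."""
    if matrix.n_patients == 0:
        raise ValueError("empty matrix")
    counts = matrix.mutated.sum(axis=0).astype(int)
    frame = pd.DataFrame({
        "gene": matrix.genes,
        "n_mutated": [int(counts[g]) for g in matrix.genes],
    })
    frame["fraction"] = frame["n_mutated"] / matrix.n_patients
    frame["percent"] = [
        round_half_up_percent(n, matrix.n_patients) for n in frame["n_mutated"]
    ]
    return frame


def classify_clonality(vaf: float, threshold: float = 0.20) -> str:
    """'clonal' for VAF >= threshold (default 20%), else 'subclonal'."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    return "clonal" if vaf >= threshold else "subclonal"


def paired_concordance(
    calls_a: Iterable[VariantCall],
    calls_b: Iterable[VariantCall],
) -> float:
    """Overlap between two call sets from the same patient, as a percent.

    Jaccard index on (chrom, pos, ref, alt) site keys, scaled to [0, 100].
    Two empty sets are fully concordant (100%).
    """
    a = {c.site_key for c in calls_a}
    b = {c.site_key for c in calls_b}
    union = a | b
    if not union:
        return 100.0
    return 100.0 * len(a & b) / len(union)


def mean_mutation_burden(matrix: MutationMatrix) -> float:
    """Mean number of retained mutations per patient."""
    if matrix.n_patients == 0:
        raise ValueError("empty matrix")
    return float(matrix.n_mutations.values.sum()) / matrix.n_patients
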