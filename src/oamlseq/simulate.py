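"""Synthetic sequencing-cohort generator.

Emulates the statistical structure of a targeted-panel lymphoma cohort so
every downstream stage (filtering, recurrence, CNV calling, enrichment,
survival) is testable without any external data:

* 82 patients screened over a 38-gene panel, with per-gene mutation
  probabilities set to the published per-gene mutation frequencies and a
  subset of panel genes that are never mutated;
* true somatic VAFs drawn uniformly from [10%, 72%], covering the clonal /
  subclonal mixture (tumor purity is modeled implicitly through this range);
* read support consistent with each VAF, with forward/reverse variant reads
  split ~ Binomial(1/2);
* sequencing artifacts injected at configurable per-patient rates and
  labeled in a truth ledger: strand-biased calls, frameshifts inside
  homopolymer runs, known-SNP germline contamination, and sub-threshold
  (VAF < 10%) calls;
* six tumor/normal whole-genome coverage pairs at unequal mean depths with
  negative-binomial per-gene noise and planted copy-number gains/losses;
* progression-free and overall survival with a mutation-dependent hazard
  (overall survival neutral by default).

Every planted event is recorded in ``SyntheticCohort.truth`` so tests can
measure recovery against ground truth. A single seed fully determines the
cohort; each generation stage draws from its own deterministically derived
substream, so adding a stage does not perturb earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import CoveragePair, GeneModel, SurvivalRecord, VariantCall
from .recurrence import MutationMatrix, build_matrix

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "plant_cnv",
    "generate_survival",
    "DEFAULT_PANEL",
    "DEFAULT_MUT_PROBS",
]

# 38-gene targeted panel: recurrently mutated genes from genome/exome
# screens of ocular adnexal MALT lymphoma plus two forced candidates
# (CXCR4, ACTN4).
DEFAULT_PANEL: tuple[str, ...] = (
    "TBL1XR1", "CREBBP", "JAK3", "COL12A1", "COL1A2", "DOCK8",
    "TNFAIP3", "NOTCH1", "NOTCH2", "KMT2D", "KMT2C", "MYD88", "BCL10",
    "TNIP1", "NFKBIA", "TNFRSF14", "TET2", "LRP1B", "CARD11", "CD79B",
    "PIM1", "PRDM1", "SOCS1", "STAT3", "STAT6", "B2M", "EP300", "ARID1A",
    "SPEN", "FAS", "GNA13", "CCND3", "BTG1", "IRF8", "FBXW7", "SF3B1",
    "CXCR4", "ACTN4",
)

# Per-gene mutation probabilities. The six most frequent genes carry the
# published cohort frequencies (14/13/11/7/6/6 %); nine panel genes are
# never mutated; the rest sit at 3%, giving an expected burden of ~1.31
# mutations per patient.
_NEVER_MUTATED = ("CXCR4", "B2M", "FAS", "GNA13", "CCND3", "BTG1", "IRF8",
                  "FBXW7", "SF3B1")
DEFAULT_MUT_PROBS: dict[str, float] = {
    **{g: 0.03 for g in DEFAULT_PANEL},
    "TBL1XR1": 0.14, "CREBBP": 0.13, "JAK3": 0.11,
    "COL12A1": 0.07, "COL1A2": 0.06, "DOCK8": 0.06,
    **{g: 0.0 for g in _NEVER_MUTATED},
}

_DEFAULT_ARTIFACT_RATES: dict[str, float] = {
    "strand_bias": 0.05,
    "homopolymer_fs": 0.05,
    "known_snp": 0.05,
    "subthreshold_vaf": 0.05,
}

# Default planted copy-number lesions for the six whole-genome pairs:
# single-copy loss of TNFAIP3 in three patients, one-copy gains of HES4 in
# four and CEBPB in four, echoing the recurrent 6q23.3 loss and 1p36/20q13
# gains seen in this lymphoma.
_DEFAULT_CNV_PLANTS: tuple[tuple[tuple[str, ...], float, tuple[int, ...]], ...] = (
    (("TNFAIP3",), -1.0, (0, 1, 2)),
    (("HES4",), 1.0, (0, 1, 2, 3)),
    (("CEBPB",), 1.0, (2, 3, 4, 5)),
)

_CONSEQUENCE_CHOICES = ("missense", "nonsense", "frameshift", "splice", "other")
_CONSEQUENCE_PROBS = (0.70, 0.10, 0.10, 0.05, 0.05)
_HIGH_IMPACT = {"nonsense", "frameshift", "splice"}
_BASES = ("A", "C", "G", "T")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``cnv_plants`` entries are (gene tuple, log2 fold, tuple of
    whole-genome pair indices). ``coverage_means`` are the (tumor, normal)
    mean depths for the coverage pairs; ``call_depth_mean`` is the mean
    sequencing depth of the targeted panel calls. ``survival_params`` keys:
    ``median_pfs_wt`` (months), ``hazard_ratio_mut``, ``censor_rate``, and
    optionally ``median_os_wt`` and ``hazard_ratio_os`` (default 1:
    mutation status does not affect overall survival).
    """

    n_patients: int = 82
    panel_genes: tuple[str, ...] = DEFAULT_PANEL
    per_gene_mut_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUT_PROBS))
    vaf_range: tuple[float, float] = (0.10, 0.72)
    clonal_threshold: float = 0.20
    artifact_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ARTIFACT_RATES))
    n_wgs_pairs: int = 6
    coverage_means: tuple[float, float] = (21.0, 30.0)
    coverage_dispersion: float = 0.05
    n_background_genes: int = 462
    cnv_plants: Sequence[tuple[tuple[str, ...], float, tuple[int, ...]]] = \
        _DEFAULT_CNV_PLANTS
    survival_gene: str = "JAK3"
    survival_params: Mapping[str, float] = field(default_factory=lambda: {
        "median_pfs_wt": 60.0, "hazard_ratio_mut": 4.0, "censor_rate": 0.3})
    call_depth_mean: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.panel_genes:
            raise ValueError("empty gene panel")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        low, high = self.vaf_range
        if not (0.0 <= low < high <= 1.0):
            raise ValueError(f"invalid vaf_range {self.vaf_range}")
        for g, p in self.per_gene_mut_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mutation probability for {g} outside [0, 1]")
        for k, p in self.artifact_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"artifact rate {k} outside [0, 1]")
        if min(self.coverage_means) <= 0:
            raise ValueError("coverage means must be > 0")
        if self.coverage_dispersion < 0:
            raise ValueError("coverage_dispersion must be >= 0")
        hr = self.survival_params.get("hazard_ratio_mut", 1.0)
        if hr <= 0:
            raise ValueError("hazard_ratio_mut must be > 0")
        if self.call_depth_mean < 50:
            raise ValueError("call_depth_mean must be >= 50")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted-event truth ledger.

    ``truth`` keys: ``true_calls`` (list of dicts describing each true
    somatic call), ``artifacts`` (each with an ``artifact`` label),
    ``cnv`` (planted lesions), ``survival`` (generating parameters).
    """

    config: CohortConfig
    calls: list[VariantCall]
    coverage_pairs: list[CoveragePair]
    gene_models: list[GeneModel]
    pathways: dict[str, set[str]]
    survival: list[SurvivalRecord]
    truth: dict

    @property
    def patients(self) -> list[str]:
        return [_patient_id(i) for i in range(self.config.n_patients)]

    def true_calls(self) -> list[VariantCall]:
        """The non-artifact calls (by truth-ledger label)."""
        artifact_keys = {(a["patient_id"], a["chrom"], a["pos"])
                         for a in self.truth["artifacts"]}
        return [c for c in self.calls
                if (c.patient_id, c.chrom, c.pos) not in artifact_keys]

    def mutation_matrix(self) -> MutationMatrix:
        """Ground-truth mutation matrix built from the true calls."""
        return build_matrix(self.true_calls(), self.patients,
                            list(self.config.panel_genes))


def _patient_id(i: int) -> str:
    return f"P{i + 1:03d}"


def _gene_universe(config: CohortConfig) -> list[str]:
    """Panel genes, the planted CNV genes, then background filler genes."""
    universe = list(config.panel_genes)
    for genes, _, _ in config.cnv_plants:
        for g in genes:
            if g not in universe:
                universe.append(g)
    n_named = len(universe)
    universe += [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    assert len(set(universe)) == n_named + config.n_background_genes
    return universe


def _gene_models(universe: Sequence[str]) -> list[GeneModel]:
    # Deterministic synthetic loci: 22 autosomes round-robin, 100 kb genes
    # spaced 1 Mb apart.
    models = []
    for i, gene in enumerate(universe):
        chrom = f"chr{(i % 22) + 1}"
        start = 1_000_000 * (i // 22 + 1)
        models.append(GeneModel(gene=gene, chrom=chrom, start=start,
                                end=start + 100_000, strand="+"))
    return models


def _counts_for_vaf(vaf: float, depth: int, rng: np.random.Generator,
                    ) -> tuple[int, int, int, int]:
    """Read counts whose implied VAF matches ``vaf`` to within 0.5/depth.

    The variant-read total is round(vaf * depth) so the stored VAF stays
    exactly as drawn; randomness enters through the strand split only.
    """
    var_total = int(round(vaf * depth))
    ref_total = depth - var_total
    var_fwd = int(rng.binomial(var_total, 0.5)) if var_total else 0
    ref_fwd = int(rng.binomial(ref_total, 0.5)) if ref_total else 0
    return var_fwd, var_total - var_fwd, ref_fwd, ref_total - ref_fwd


def _draw_site(gene_model: GeneModel, rng: np.random.Generator,
               ) -> tuple[str, int, str, str]:
    pos = int(rng.integers(gene_model.start + 1, gene_model.end + 1))
    ref, alt = rng.choice(len(_BASES), size=2, replace=False)
    return gene_model.chrom, pos, _BASES[ref], _BASES[alt]


def _sample_type(i: int, n: int) -> str:
    # Fixed 63:10:11 split of FFPE / suspension / sorted material for the
    # default 82-patient cohort, scaled proportionally otherwise.
    ffpe_n = round(n * 63 / 84) if n != 82 else 63
    susp_n = round(n * 10 / 84) if n != 82 else 10
    if i < ffpe_n:
        return "ffpe"
    if i < ffpe_n + susp_n:
        return "suspension"
    return "sorted"


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort from a config.

    Deterministic: the same (config, seed) yields a byte-identical cohort.
    """
    config = config or CohortConfig()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(6)
    rng_calls, rng_art, rng_cov, rng_path = (
        np.random.default_rng(child) for child in children[:4])
    surv_seed = int(children[4].generate_state(1)[0] % (2 ** 31))

    universe = _gene_universe(config)
    models = _gene_models(universe)
    model_by_gene = {m.gene: m for m in models}

    low, high = config.vaf_range
    calls: list[VariantCall] = []
    truth_calls: list[dict] = []
    truth_artifacts: list[dict] = []

    for i in range(config.n_patients):
        pid = _patient_id(i)
        stype = _sample_type(i, config.n_patients)
        sid = f"{pid}-S1"
        for gene in config.panel_genes:
            p = config.per_gene_mut_prob.get(gene, 0.0)
            if p == 0.0 or rng_calls.random() >= p:
                continue
            vaf = float(rng_calls.uniform(low, high))
            depth = max(50, int(rng_calls.poisson(config.call_depth_mean)))
            vf, vr, rf, rr = _counts_for_vaf(vaf, depth, rng_calls)
            chrom, pos, ref, alt = _draw_site(model_by_gene[gene], rng_calls)
            csq = _CONSEQUENCE_CHOICES[
                rng_calls.choice(len(_CONSEQUENCE_CHOICES),
                                 p=_CONSEQUENCE_PROBS)]
            call = VariantCall(
                patient_id=pid, sample_id=sid, sample_type=stype, gene=gene,
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                impact="HIGH" if csq in _HIGH_IMPACT else "MODERATE",
                consequence=csq, var_fwd=vf, var_rev=vr, ref_fwd=rf,
                ref_rev=rr, vaf=vaf,
                quality=float(rng_calls.uniform(600.0, 2000.0)),
                known_variant=False, homopolymer_len=0)
            calls.append(call)
            truth_calls.append({"patient_id": pid, "gene": gene,
                                "chrom": chrom, "pos": pos, "vaf": vaf,
                                "clonal": vaf >= config.clonal_threshold})
        # Artifact injection (each type independently per patient).
        for kind, rate in sorted(config.artifact_rates.items()):
            if rate == 0.0 or rng_art.random() >= rate:
                continue
            gene = config.panel_genes[
                int(rng_art.integers(len(config.panel_genes)))]
            chrom, pos, ref, alt = _draw_site(model_by_gene[gene], rng_art)
            depth = max(50, int(rng_art.poisson(config.call_depth_mean)))
            csq, impact, known, hp_len = "missense", "MODERATE", False, 0
            if kind == "strand_bias":
                vaf = float(rng_art.uniform(0.15, 0.50))
                var_total = int(round(vaf * depth))
                ref_total = depth - var_total
                ref_fwd = int(rng_art.binomial(ref_total, 0.5))
                vf, vr, rf, rr = var_total, 0, ref_fwd, ref_total - ref_fwd
            elif kind == "homopolymer_fs":
                vaf = float(rng_art.uniform(low, high))
                vf, vr, rf, rr = _counts_for_vaf(vaf, depth, rng_art)
                csq, impact = "frameshift", "HIGH"
                hp_len = int(rng_art.integers(4, 10))
            elif kind == "known_snp":
                vaf = float(np.clip(rng_art.normal(0.5, 0.04), 0.40, 0.60))
                vf, vr, rf, rr = _counts_for_vaf(vaf, depth, rng_art)
                known = True
            elif kind == "subthreshold_vaf":
                vaf = float(rng_art.uniform(0.02, 0.095))
                vf, vr, rf, rr = _counts_for_vaf(vaf, depth, rng_art)
            else:
                raise ValueError(f"unknown artifact kind {kind!r}")
            call = VariantCall(
                patient_id=pid, sample_id=sid, sample_type=stype, gene=gene,
                chrom=chrom, pos=pos, ref=ref, alt=alt, impact=impact,
                consequence=csq, var_fwd=vf, var_rev=vr, ref_fwd=rf,
                ref_rev=rr, vaf=vaf,
                quality=float(rng_art.uniform(600.0, 2000.0)),
                known_variant=known, homopolymer_len=hp_len)
            calls.append(call)
            truth_artifacts.append({"patient_id": pid, "gene": gene,
                                    "chrom": chrom, "pos": pos,
                                    "artifact": kind})

    coverage_pairs, truth_cnv = _generate_coverage(config, universe, rng_cov)
    pathways = _generate_pathways(universe, rng_path)

    truth: dict = {"true_calls": truth_calls, "artifacts": truth_artifacts,
                   "cnv": truth_cnv}

    cohort = SyntheticCohort(config=config, calls=calls,
                             coverage_pairs=coverage_pairs,
                             gene_models=models, pathways=pathways,
                             survival=[], truth=truth)
    if config.survival_gene in config.panel_genes:
        cohort.survival = generate_survival(
            cohort.mutation_matrix(), config.survival_gene,
            dict(config.survival_params), seed=surv_seed)
        truth["survival"] = {"gene": config.survival_gene,
                             **dict(config.survival_params),
                             "seed": surv_seed}
    return cohort


#: Synthetic gene length and read length used to size coverage noise.
GENE_LENGTH = 100_000
READ_LENGTH = 300


def _mean_coverage_draw(rng: np.random.Generator, mean: np.ndarray,
                        dispersion: float, n_eff: float) -> np.ndarray:
    """Per-gene *mean* coverage with negative-binomial per-position noise.

    Per sequenced position the coverage is NB with var = m + dispersion*m^2;
    the reported per-gene value is the mean over ~n_eff independent
    positions (gene length / read length), approximated by a Gamma with
    matching mean and variance. Averaging is what makes gene-level
    log-ratios far quieter than a single NB draw at the same depth.
    """
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    var = (mean[pos] + dispersion * mean[pos] ** 2) / max(n_eff, 1.0)
    shape = mean[pos] ** 2 / var
    out[pos] = rng.gamma(shape, mean[pos] / shape)
    return out


def _generate_coverage(config: CohortConfig, universe: Sequence[str],
                       rng: np.random.Generator,
                       ) -> tuple[list[CoveragePair], list[dict]]:
    tumor_mean, normal_mean = config.coverage_means
    pairs: list[CoveragePair] = []
    truth: list[dict] = []
    for i in range(config.n_wgs_pairs):
        pid = _patient_id(i)
        expected_t = np.full(len(universe), tumor_mean)
        base = CoveragePair(pid, list(universe), expected_t,
                            np.full(len(universe), normal_mean))
        for genes, fold, patient_idx in config.cnv_plants:
            if i in patient_idx:
                base = plant_cnv(base, genes, fold)
                truth.append({"patient_id": pid, "genes": list(genes),
                              "log2_fold": fold})
        n_eff = GENE_LENGTH / READ_LENGTH
        pairs.append(CoveragePair(
            pid, list(universe),
            _mean_coverage_draw(rng, base.tumor_cov,
                                config.coverage_dispersion, n_eff),
            _mean_coverage_draw(rng, base.normal_cov,
                                config.coverage_dispersion, n_eff)))
    return pairs, truth


# Curated pathways over the named panel genes; random filler pathways are
# drawn over the whole universe at generation time.
_CURATED_PATHWAYS: dict[str, tuple[str, ...]] = {
    "JAK_STAT_SIGNALING": ("JAK3", "STAT3", "STAT6", "SOCS1", "PIM1"),
    "NF_KB_SIGNALING": ("TNFAIP3", "MYD88", "BCL10", "CARD11", "NFKBIA",
                        "TNIP1", "TNFRSF14", "CD79B", "ACTN4"),
    "NOTCH_SIGNALING": ("NOTCH1", "NOTCH2", "SPEN", "FBXW7", "HES4"),
    "CHROMATIN_MODIFICATION": ("CREBBP", "EP300", "KMT2D", "KMT2C", "TET2",
                               "ARID1A"),
    "CELL_ADHESION_ECM": ("COL12A1", "COL1A2", "DOCK8", "CXCR4"),
}


def _generate_pathways(universe: Sequence[str], rng: np.random.Generator,
                       n_random: int = 10) -> dict[str, set[str]]:
    uni = set(universe)
    pathways = {name: set(genes) & uni
                for name, genes in _CURATED_PATHWAYS.items()}
    pathways = {k: v for k, v in pathways.items() if v}
    for i in range(n_random):
        size = int(rng.integers(10, 31))
        members = rng.choice(len(universe), size=size, replace=False)
        pathways[f"RANDOM_SET_{i + 1:02d}"] = {universe[j] for j in members}
    return pathways


def plant_cnv(pair: CoveragePair, genes: Iterable[str], log2_fold: float,
              ) -> CoveragePair:
    """Multiply the tumor coverage of ``genes`` by 2**log2_fold.

    Intended for noiseless expected-coverage vectors before noise is
    drawn. Raises KeyError naming the first gene absent from the pair's
    universe.
    """
    tumor = pair.tumor_cov.copy()
    for gene in genes:
        tumor[pair.gene_index(gene)] *= 2.0 ** log2_fold
    return CoveragePair(pair.patient_id, list(pair.genes), tumor,
                        pair.normal_cov.copy())


def generate_survival(
    matrix: MutationMatrix,
    gene: str,
    params: Mapping[str, float],
    seed: int,
) -> list[SurvivalRecord]:
    """Exponential PFS/OS times with mutation-dependent hazard.

    Event times are exponential with rate ln2 / median; mutated patients'
    PFS hazard is multiplied by ``hazard_ratio_mut`` (OS by
    ``hazard_ratio_os``, default 1). Censoring is an independent
    exponential chosen so that each record is censored with probability
    ``censor_rate``; at censor_rate 1 every record is censored, at 0 none.
    """
    if gene not in matrix.genes:
        raise KeyError(f"gene {gene!r} not in mutation matrix")
    hr_pfs = float(params.get("hazard_ratio_mut", 1.0))
    hr_os = float(params.get("hazard_ratio_os", 1.0))
    if hr_pfs <= 0 or hr_os <= 0:
        raise ValueError("hazard ratios must be > 0")
    median_pfs = float(params.get("median_pfs_wt", 60.0))
    median_os = float(params.get("median_os_wt", 2 * median_pfs))
    censor_rate = float(params.get("censor_rate", 0.0))
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    records: list[SurvivalRecord] = []
    for pid in matrix.patients:
        mutated = bool(matrix.mutated.at[pid, gene])
        group = "mutant" if mutated else "wildtype"
        for endpoint, median, hr in (("PFS", median_pfs, hr_pfs),
                                     ("OS", median_os, hr_os)):
            lam = np.log(2.0) / median * (hr if mutated else 1.0)
            t_event = float(rng.exponential(1.0 / lam))
            if censor_rate >= 1.0:
                time, event = t_event, False
            elif censor_rate <= 0.0:
                time, event = t_event, True
            else:
                c = lam * censor_rate / (1.0 - censor_rate)
                t_cens = float(rng.exponential(1.0 / c))
                time, event = min(t_event, t_cens), t_event <= t_cens
            records.append(SurvivalRecord(patient_id=pid, time=time,
                                          event=event, endpoint=endpoint,
                                          group=group))
    return records
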