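# oamlseq

Somatic lesion landscape analysis for ocular adnexal MALT lymphoma (OAML)
cohorts — and, more generally, for any targeted-panel / tumor–normal
sequencing study with the same shape: per-sample variant call tables,
per-gene tumor/normal coverage, pathway membership and time-to-event
follow-up.

OAML is a rare extranodal marginal zone B-cell lymphoma. Its mutation
landscape is typically assembled in two steps: unbiased whole-genome (WGS)
and whole-exome (WES) screens of a few index cases nominate candidate
genes, and a targeted deep-sequencing panel then measures recurrence of
those genes across a large archival cohort (mostly FFPE material, hence
low tumor purity and abundant sequencing artifacts). `oamlseq` implements
that downstream analysis as a tested, reusable library plus CLI:

- **Variant filter cascades** — the tumor/normal WGS cascade (impact ≥
  MODERATE, ≥ 5 variant reads, ≥ 2 forward and ≥ 2 reverse reads, no
  significant strand bias, absent from the matched normal, no known
  SNPs) and the targeted-panel cascade (non-synonymous, novel, no
  frameshifts in homopolymer runs of ≥ 4 bases, strand bias < 100,
  VAF ≥ 10%). Strand bias is scored as −10·log₁₀ of the two-sided Fisher
  exact p of the 2×2 table [variant fwd/rev ; reference fwd/rev].
- **Recurrence summaries** — the patient × gene mutation matrix
  (oncoprint semantics), per-gene frequencies with whole-percent
  rounding, clonal/subclonal classification at VAF ≥ 20%, and
  paired-sample concordance (Jaccard on variant site keys).
- **Copy-number calling** — per-gene tumor/normal mean coverages are put
  on a common mean by an additive shift of the lower-coverage sample,
  log₂(T/N) ratios are computed with an ε = 0.5-read floor, states are
  called at ±0.3, and cross-patient recurrence of gains/losses is tested
  per gene with one-sided Fisher exact tests against the cohort-wide
  background rate, Benjamini–Hochberg corrected (q < 0.05).
- **Pathway enrichment** — one-sided Fisher over-representation of
  mutated genes per pathway with BH correction.
- **Survival** — Kaplan–Meier product-limit curves
  S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) and the log-rank (Mantel–Cox) test,
  (O − E)²/V ~ χ²₁, comparing PFS/OS between mutated and unmutated
  patients.
- **A synthetic-cohort generator** — 82 patients over a 38-gene panel,
  true VAFs in [10%, 72%], labeled strand-bias / homopolymer /
  known-SNP / sub-threshold artifacts, six tumor/normal coverage pairs
  with planted gains and losses, and exponential PFS/OS with a
  mutation-dependent hazard. Every planted event is recorded in a truth
  ledger, so recovery is measurable end to end.

## Worked example

Run the full pipeline on a simulated cohort (results land in `demo/`):

```sh
$ oamlseq -v run-all --outdir demo --seed 7
[oamlseq.pipeline.input] simulated cohort: 82 patients, 125 calls, 6 coverage pairs
[oamlseq.pipeline.filter] targeted cascade: 125 in, 101 retained, 24 removed
[oamlseq.pipeline.recurrence] matrix 82 x 38, 60/82 patients mutated (73%)
[oamlseq.pipeline.cnv] 6 pairs, 502 genes, 3 significant
[oamlseq.pipeline.enrich] 15 pathways, 25 affected genes
[oamlseq.pipeline.survival] JAK3 PFS: chi2=2.727 p=0.09868 (n=8 vs 74)
wrote 11 result files to demo
```

The filter stage removed the 24 injected artifacts and kept the 101 true
somatic calls; the CNV stage recovered exactly the three planted lesions
(TNFAIP3 lost in 3/6 patients, HES4 and CEBPB gained in 4/6, all with
q < 0.05); the survival stage compares the 8 JAK3-mutant patients of this
replicate against the 74 wild-type patients. The same stages are available
as library calls:

```python
import oamlseq as o
from oamlseq.cnv import call_cnv, recurrence_enrichment

cohort = o.generate_cohort(o.CohortConfig(seed=7))
res = recurrence_enrichment([call_cnv(p) for p in cohort.coverage_pairs])
print(res[res.significant][["gene", "n_gain", "n_loss", "q_gain", "q_loss"]])
#    gene  n_gain  n_loss       q_gain   q_loss
# TNFAIP3       0       3 1.000000e+00 0.000002
#    HES4       4       0 7.684139e-08 1.000000
#   CEBPB       4       0 7.684139e-08 1.000000

cmp = o.compare_by_gene(cohort.mutation_matrix(), cohort.survival,
                        "JAK3", "PFS")
print(cmp.result.p_value, cmp.medians)
# 0.0987 {'mutant': 8.0, 'wildtype': 42.2}
```

The generated mutant group has a median PFS of 8 months against 42 months
for wild-type — the direction the mutation-dependent hazard plants — while
at n = 8 vs 74 the log-rank test is underpowered, as expected for a rare
mutation.

Subcommands `simulate`, `filter`, `recurrence`, `cnv`, `enrich` and
`survival` expose each stage separately; every threshold is a flag
defaulting to the cascade values above.

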