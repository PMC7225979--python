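# Methods

This note documents the statistical procedures `oamlseq` implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-cohort generator does and does not emulate, and the numerical
conventions used throughout.

## Variant filtering

Two cascades operate on annotated variant calls; both are pure
conjunctions of per-record predicates, so they are idempotent and
order-invariant, and tightening any threshold can only shrink the output.

**Tumor/normal (WGS) cascade.** A tumor call is retained iff its
functional impact is at least MODERATE, it has ≥ 5 variant reads with at
least 2 on each strand, its strand-bias score is below the cutoff, no
call with the same (chrom, pos, ref, alt) key exists in the matched
normal, and it is not flagged as a known (database) variant. Matching on
the exact site key is deliberate: the normal sample is a germline
control, so any co-occurring allele disqualifies the site.

**Targeted-panel cascade.** A call is retained iff it is non-synonymous,
novel, not a frameshift inside a homopolymer run of ≥ 4 identical bases,
has strand bias < 100 and VAF ≥ 10%. Boundary conventions follow the
phrasing of each rule: "minimum/at least" thresholds are inclusive
(VAF = 0.10 passes), "< 5 reads" style thresholds exclusive. The
homopolymer length cutoff of 4 is a configurable default; indel errors in
ion semiconductor data rise steeply from runs of about that length.

**Strand bias.** Vendor pipelines report proprietary strand-bias scores;
here a single, reproducible definition serves both cascades: the
phred-scaled two-sided Fisher exact p-value of the 2×2 table
[var_fwd, var_rev; ref_fwd, ref_rev], i.e. −10·log₁₀ p, with score 0 for
a perfectly balanced table. The cutoff 100 (p = 10⁻¹⁰) is intentionally
permissive for true heterozygous calls at panel depth: a binomial(1/2)
split essentially never reaches it, while calls with all variant support
on one strand at depth ≳ 100 always do.

**Panel selection.** Candidate genes qualify with ≥ 1 mutated
whole-genome case or ≥ 2 mutated exome cases (exome calls are first
required to exceed caller quality 500, exclusive); forced candidates are
added afterwards and the panel is sorted lexicographically for
determinism. When a patient contributed several QC-passing samples, one
is kept with priority sorted > suspension > FFPE, i.e. by expected tumor
purity.

## Recurrence summaries

The mutation matrix uses oncoprint semantics: a (patient, gene) cell is
mutated if at least one retained call maps there, regardless of
multiplicity; the cell stores the maximum VAF and the call count.
Per-gene percents are rounded half-up to whole numbers, matching how such
cohorts are reported (9/82 → 11%). Clonality is a VAF dichotomy at 20%
(inclusive for clonal), a pragmatic proxy that folds tumor purity into
the cutoff rather than modeling it. Paired-sample concordance is the
Jaccard index of variant site keys expressed as a percent; it is
symmetric, penalizes private calls on either side, and is defined as 100%
for two empty sets (two samples in which nothing was found agree).

## Copy-number calling

Per-gene mean coverages of a tumor/normal pair are made comparable by an
**additive mean shift**: the difference of the two sample means is added
to every gene of the lower-mean sample. The shift is additive rather than
multiplicative by design — it assumes most genes are copy-neutral,
preserves within-sample differences exactly, and leaves the higher-mean
sample untouched. The cost is a known bias: a planted log₂ fold f at
equal means is recovered slightly compressed (the shift enters both
numerator and denominator), which is why tests allow 0.05 slack on
noiseless planted folds.

Ratios are log₂((T + ε)/(N + ε)) with ε = 0.5 reads, which keeps
zero-coverage genes finite (T = 0, N = 100 → −7.65) without otherwise
moving ratios at realistic depth. Genes with zero coverage in **both**
samples carry no signal and are flagged `nocall` instead of being
called. States are gain at ratio ≥ +0.3 and loss at ≤ −0.3 (inclusive);
±0.3 (≈1.23-fold) is a common log-ratio convention that still detects a
one-copy event at two-thirds tumor purity (expected ratio −0.58).

**Recurrence enrichment.** For each gene and direction the 2×2 table is
[patients with the state at the focal gene, patients without] vs [cells
with the state, cells without] over all other (patient, gene) cells; the
test is one-sided (greater) Fisher, BH-corrected across genes within each
direction, significant at q < 0.05. This background-cell construction,
the sidedness and the per-direction correction are explicit package
choices — the underlying procedure is usually described only as "Fisher
with FDR correction" — and all three are parameters of the run, not
hidden constants. Raw recurrence counts (gene lost in k of n patients)
are always reported alongside the q-values.

## Pathway enrichment

One-sided (greater) Fisher exact test per pathway on [affected ∩ pathway,
affected ∖ pathway; unaffected ∩ pathway, unaffected ∖ pathway] over a
fixed gene universe, BH-corrected across pathways (correction can be
switched off). Enrichment, not depletion, is the question being asked,
hence the sidedness. Affected genes outside the universe are dropped with
a warning rather than silently absorbed. The pathway table is an input
(GMT-like file); no pathway database is bundled.

## Survival

Kaplan–Meier and the log-rank test are computed from the standard
risk-table formulas (see README for the notation). Ties follow the
standard conventions: all events at a tied time form one risk-table row,
and events precede censorings at the same time (a patient censored at t
is still at risk at t). The variance term uses the hypergeometric form
with the (n_j − d_j)/(n_j − 1) correction, skipping times with a single
patient at risk. The test suite checks the implementation against
lifelines on tied, censored datasets and against a closed-form empirical
curve in the censoring-free case. Times are treated as opaque positive
numbers; no progression definition is imposed.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults frozen to the study conditions of the cohort it models:

- **Cohort**: 82 patients over a 38-gene panel; sample material split
  63 FFPE / 10 suspension / 11 sorted.
- **Mutations**: per patient and gene, an independent Bernoulli draw.
  The six most frequent genes carry probabilities 0.14, 0.13, 0.11,
  0.07, 0.06, 0.06; nine panel genes are never mutated; the remaining
  nineteen sit at 0.03, for an expected burden of ≈1.31 mutations per
  patient. Under independent Bernoulli draws these frequencies imply
  ~70% of patients carry ≥ 1 mutation; an observed cohort can pair a
  lower mutated fraction with the same mean burden only through
  patient-level overdispersion (a few hypermutated cases), which this
  generator intentionally does not model.
- **VAFs**: true somatic VAFs are uniform on [0.10, 0.72]; the range
  stands in for tumor purity and zygosity jointly rather than modeling
  either explicitly. Read counts are derived as round(VAF · depth) with
  depth ~ Poisson(500) (floored at 50), so the count-implied VAF matches
  the drawn one to ≤ 0.5/depth; forward/reverse splits are
  Binomial(1/2).
- **Artifacts** (per patient, per type, default rate 0.05 each), all
  labeled in the truth ledger: fully strand-biased calls (all variant
  reads forward), frameshifts inside homopolymer runs of 4–9 bases,
  known-SNP-flagged calls at VAF ≈ 0.5, and calls with VAF in
  [0.02, 0.095].
- **Coverage pairs**: six tumor/normal pairs at mean depths 21 (tumor)
  and 30 (normal) — unequal on purpose, to exercise the mean-shift
  normalization. The reported value per gene is a *mean* coverage: per
  sequenced position the noise is negative-binomial with
  var = m + φ·m² (φ = 0.05 by default), and the gene-level mean over
  ~gene length / read length ≈ 333 effective positions is drawn from a
  moment-matched Gamma. Modeling the mean rather than a single
  negative-binomial draw is what makes gene-level log-ratios usable at
  depth 20; it ignores mappability/GC structure, so real coverage
  profiles are noisier than these.
- **Planted lesions**: tumor expectations are multiplied by 2^fold
  before noise; defaults plant a one-copy loss of TNFAIP3 in pairs 1–3
  and one-copy gains of HES4 (pairs 1–4) and CEBPB (pairs 3–6).
- **Survival**: exponential PFS with wild-type median 60 months and a
  mutant hazard ratio of 4 on the survival gene (JAK3 by default); OS
  has hazard ratio 1, so mutation status affects PFS only. The printed
  source cohort reports direction and significance but no hazard ratio
  or median; 60 months and HR 4 were fixed once as values detectable at
  the cohort's group sizes. Censoring is an independent exponential with
  rate λ·r/(1−r), giving each record censoring probability r exactly
  (r = 0.3 by default); r = 1 censors everything, r = 0 nothing.
- **Determinism**: one seed, with per-stage substreams derived via
  `SeedSequence.spawn`, so identical configs are byte-identical and
  adding a stage does not perturb earlier ones.

What passing tests on this generator show: the cascades remove the
injected artifact classes and keep clonal truth, the CNV pipeline
recovers planted |log₂ fold| ≥ 0.5 events essentially perfectly at depth
20, and the survival machinery has the advertised size and power. What
they do not show: robustness to FFPE deamination spectra, coverage
waviness, panel design bias, or non-exponential hazards — none of which
the generator models.

## Numerical conventions

- Variant positions are 1-based (VCF convention); gene models are
  0-based half-open (BED convention).
- Stored VAFs must agree with count-implied VAFs to within 0.01;
  readers recompute VAF from counts when it is absent.
- p-values are clamped to [0, 1] before phred scaling; BH uses the
  statsmodels step-up implementation, verified exactly against the
  literal definition in tests.
- All result tables are written atomically (temp file + rename), TSV
  with "." for missing; floats use round-trip-exact formatting.
- Percent rounding is half-up, not banker's.

## Problem sizes

The test and reproduction runs use the defaults above: 82-patient
cohorts, a ~500-gene coverage universe over 6 pairs (200 background genes
in the 20-seed recovery sweep), 100–200 replicates for power and
uniformity checks, and ≥ 10⁴ calls for distributional bounds. These sizes
give binomial standard errors comfortably inside the asserted margins.

## Known limitations

- The Fisher background-cell contingency for CNV recurrence treats
  (patient, gene) cells as exchangeable; correlated events (whole-arm
  lesions) would inflate significance. Per-gene calling without
  segmentation is a faithful design choice, not an oversight.
- The mutation model has no patient-level overdispersion and no
  site-level hotspots; per-gene frequencies, not co-occurrence
  structure, are the emulated quantity.
- The additive coverage normalization is kept exactly as specified even
  though multiplicative scaling is more conventional; its small
  compression of planted folds is quantified in the tests.
- Survival analysis is two-group log-rank only; no Cox regression or
  covariate adjustment.
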