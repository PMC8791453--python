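# Methods

## The statistical model

### Background and signal mutation rates

The unit of evidence for a gene is the number of tumors (out of *n*) that
carry at least one non-silent mutation in it — multiple hits in one tumor
count once, because tumor counts, not mutation counts, are what a
recurrence argument needs. That count is modelled as Binomial(*n*, *p*).

Under the null (passengers only), the per-tumor probability of at least one
non-silent mutation in a gene of length *L* is

    p0 = 1 − (1 − μ·f_g)^((3/4)·L)

- **μ** — background mutation rate per base per tumor (dimensionless
  probability). Exome-wide averages for non-hypermutated tumors are
  ~1e-6; MSI-hypermutated endometrial tumors run an order of magnitude
  higher. There is no universal default; the analysis must supply it (or a
  per-gene override, below).
- **f_g** — gene-specific mutation-rate factor. Default 3.9, a 90th
  percentile: the null deliberately assumes the tested gene is hotter than
  90 % of genes, making the test conservative for the large majority.
- **L** — gene coding length in bases; default 1500 (90th percentile).
- **3/4** — the approximate fraction of coding positions where a point
  mutation is non-silent. The exponent is read as (3/4)·L; the alternative
  grouping 3/(4L) would make p0 ≈ μ·f_g·5e-4 regardless of gene length,
  which would render the power analysis vacuous (power ≈ 1 everywhere) and
  contradict its framing.

A gene mutated in a fraction *r* of tumors, with mis-detection rate *m*
(the probability sequencing/calling misses a true event; default 0.1), has

    p1 = min(1, p0 + r·(1 − m))  ≥  p0.

p0 is evaluated as `-expm1(0.75·L·log1p(-μ·f_g))` so rates down to 1e-12
do not underflow.

### The per-gene test and power

The test statistic is the one-sided, inclusive upper-tail exceedance
P(X ≥ x | n, p0): only an *excess* of mutated tumors is evidence of
selection, so a one-sided test is the right shape, and inclusivity makes
the p-value valid (P(p ≤ t) ≤ t exactly, with slack from discreteness).

Power at family level α = 0.1 split over k tests is

    power(n, μ, r) = P( p-value(X) ≤ α/k ),  X ~ Binomial(n, p1),

computed by exact tail summation — no Monte Carlo. Properties asserted in
the test suite: power is non-decreasing in r and n, non-increasing in m,
and at r = 0 it equals the test's size, which is ≤ α/k. With n = 270,
k = 14, r = 0.10, m = 0.1 and the 90th-percentile constants, the minimum
power over 25 log-spaced μ ∈ [1e-7, 1e-5] is 99.8 %, comfortably above
95 %; the μ grid bounds are an implementation choice covering the range
from quiet genomes to hypermutated ones.

### FDR and the restricted re-test

`bh_adjust` is a direct implementation of the Benjamini–Hochberg step-up:
sort p ascending, raw_i = p_(i)·m/i, take running minima from the largest
rank down, cap at 1, return in input order. It is hand-written rather than
delegated because the restricted re-test needs m = n_tests *larger* than
the number of supplied p-values; for the ordinary case it is cross-checked
against `statsmodels.multipletests(method="fdr_bh")` exactly. Zero
p-values are accepted literally (q = 0); Q-Q plotting clamps them instead.

SMG calling uses q ≤ 0.10 *inclusive*. The boundary form matters in
principle (methods-style "≤ 0.10" vs results-style "< 0.1" phrasings
differ in the field); no value in the reference tables sits on the
boundary, so the choice is not load-bearing, and the inclusive form is
used everywhere for internal consistency.

The restricted re-test takes the late-stage SMG set (k genes), looks up
each gene's early-stage p-value, recomputes BH q-values with n_tests = k,
and classifies a gene stage-specific when its early q exceeds the
threshold. Genes never observed mutated in the early cohort have no
p-value; the configurable fallback p = 1 encodes "no evidence of early
mutation" (an artifact decision — flagged, since upstream engines differ
in how they treat never-mutated genes).

The package deliberately does **not** re-implement MutSigCV's
covariate-based background model. Where an analysis was originally run on
MutSigCV p-values, those p-values are *inputs* (the `external_pvalues`
bypass in the pipeline, `stagesmg stagespec` on the CLI), and the
stage-specificity machinery operates on them exactly as published. The
binomial scan is the built-in significance engine for synthetic and
exploratory cohorts.

## Filters

Two filter stacks are provided, matching the two kinds of input:

- **TCGA dialect** (`filter_tcga_variants` + `exclude_noncoding`): keep
  FILTER ∈ {PASS, WGA, Native_WGA_mix}, require MUTECT provenance for SNVs
  and INDELOCATOR for indels, then drop UTR/Flank/Intron/RNA/lincRNA/
  De-novo-start classes. Caller provenance is parsed from a delimited
  column (MC3 `CENTERS` style, `|`-separated, trailing `*` markers
  stripped); the delimiter is part of the dialect definition.
- **In-house consensus** (`run_consensus_pipeline`): tumor depth ≥ 14 and
  normal depth ≥ 8 (inclusive — "a minimum of 14" reads as ≥ 14); normal
  VAF strictly > 3 % excluded (exactly 3 % passes); dbSNP SNVs excluded
  only when catalogued with MAF strictly > 5 %, dbSNP indels excluded on
  membership alone; SNVs require all of {Strelka, Shimmer, SomaticSniper,
  MuTect}, indels any of {Strelka, Shimmer}; noncoding classes dropped
  last. Rules apply in that fixed order and every dropped variant is
  tallied under the *first* failing rule, so reports reconcile exactly
  with input counts. Variants missing a required field are dropped under a
  separate `missing_data` tally rather than raising.

Two decisions here are genuinely open and were made as artifact choices:
dbSNP matching is by exact (chrom, pos, ref, alt) allele — position-only
matching would over-exclude multi-allelic sites — and SNVs catalogued
*without* a recorded frequency are retained (conservative towards keeping
putative somatic calls).

## MSI target-gene annotation

An indel is "in tract" when the maximal run of one base containing the
deleted base(s) — or immediately flanking the insertion point, for
insertions of a single repeated base — reaches `min_tract_length` **and**
the edited bases all equal the run base. The default minimum is 5, a
conventional instability floor; the EEC tracts of interest (e.g. the (C)₇
run in *PAX6*) are longer, so the default is not load-bearing. Context
windows travel with the variant (`context_seq` + 0-based
`context_offset`, defaulting to the window centre); a reference-genome-
backed context provider is an extension point, deliberately not built in
to keep the package download-free. Homopolymer calls are invariant under
reverse complementation of the window (property-tested).

Recurrence counts distinct samples per (gene, protein-change string);
protein changes are compared as strings, not derived from coordinates.
Subgroup enrichment uses the two-tailed Fisher exact test with the
"sum of point probabilities ≤ observed" convention (scipy's, with its
1 + 1e-7 relative tolerance; verified against full hypergeometric
enumeration in the tests). Missense impact is the ≥ 3-of-4 agreement rule
over MutationAssessor ("high"), PROVEAN ("deleterious"), SIFT
("damaging") and PolyPhen-2 ("probably-damaging"); missing predictors
count as non-impact, unknown predictor names are an error.

## The synthetic generator

`synthetic_cohort.generate` fabricates cohorts with the structure the
analysis assumes. Defaults are the study-like TCGA conditions: strata of
114/119/37 early and 27/21/18 late samples (MSI-hypermutated / CN-low /
CN-high), per-subgroup background μ of 1e-5 (MSI) and 1e-6 (CN-low,
CN-high) — reproducing the order-of-magnitude burden gap between
hypermutated and copy-number subgroups and a per-gene per-sample
background rate of a few percent in MSI-heavy cohorts — and two
MSI-restricted drivers mutated at the reported stage-specific frequencies
whose events are mostly 1-bp deletions inside planted (C)₇ windows with
named hotspot protein changes.

Per-gene factors f_g are drawn Exponential with scale 3.9/ln 10, so their
90th percentile equals the analysis constant 3.9 — the generated genome is
heterogeneous and the constant-f_g null is conservative for exactly 90 %
of genes, mirroring how the 90th-percentile constants are meant to be
used. L is fixed at 1500 to match the model constant. The truth ledger
records each gene's (f_g, L), every planted driver event, and every
planted filter violation; closed-loop tests disable all noise channels but
one and assert that the corresponding filter removes exactly the ledger
set. Each variant receives at most one violation channel (single
categorical draw), which is what makes first-fail attribution exact.

All sampling comes from one `numpy.random.default_rng(seed)` stream in
documented order (gene table → samples per cell, cells sorted → background
matrix → driver events → per-variant field fabrication); a seed pins the
fixture byte-for-byte and changing the draw order is a breaking change.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: trinucleotide/signature context of SNVs,
read-level noise (depths are Poisson around clean means), covariate
structure of the background (expression, replication timing — precisely
what MutSigCV models and this package treats as an external input),
sample contamination/purity, and correlated mutations between genes.

## Problem sizes and numerical choices

The simulation-based tests use cohorts of 100–336 samples over 120–400
genes and 20 seeded replicates; these sizes make every distributional
claim measurable while keeping the full suite under ten seconds. Exact
arithmetic oracles (integer binomial coefficients, full hypergeometric
enumeration, the min-over-tail BH definition) back every tail
computation; agreement tolerances are 1e-12 relative for binomial tails
and exact equality for BH. Reference q-values are asserted to half a unit
in the last printed digit (three significant figures) — e.g. a computed
0.002205 against a printed half-up-rounded 2.21E-03.

## Known limitations

- The binomial scan ignores per-gene covariates; in hypermutated-heavy
  cohorts the single-μ null misstates the background for individual genes
  unless per-gene (f_g, L) overrides are supplied. It is a transparent
  power/teaching model and a synthetic-data engine, not a replacement for
  covariate-aware SMG callers on real cohorts.
- With heterogeneous per-subgroup μ, scanning a pooled cohort against the
  cohort-weighted rate is slightly conservative (concavity of p0 in μ,
  and binomial variance exceeding the true Poisson-binomial variance) but
  not exact.
- An end-to-end caveat discovered while validating the design: a driver
  mutated in 3 % of 270 early-stage tumors against a μ = 1e-6 background
  is *detectably* enriched under this binomial test (null expectation
  ~1.2 mutated tumors, signal ~8; early detection power ≈ 0.92), so such
  a gene is usually classified early-significant rather than
  stage-specific. Stage-specificity of low-frequency drivers is only
  recoverable when the effective background is high (as with MutSigCV's
  covariate null on real hypermutated cohorts) — with this model's exact
  null it is not, and the corresponding end-to-end recovery test records
  that fact.
- Stage classification is binary (early = I/II, late = III/IV); no
  ordinal modelling of stage, grade or substage.
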