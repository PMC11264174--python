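# Methods

## Coordinate and naming conventions

All intervals are 0-based half-open (BED convention); abutting intervals
do not overlap. Chromosome names are compared after stripping a leading
`chr`. CNVs are unstranded and a gene is reduced to a single CDS span —
sub-exon structure is out of scope, so "a CNV hitting a gene" means ≥1 bp
of overlap with that span (a full-containment mode exists behind a flag).

## Exact tests

**Two-sided Fisher.** "Two-sided Fisher exact test" is ambiguous across
conventions; this package fixes the *minimum-likelihood* rule: the p-value
sums the hypergeometric probabilities of all tables with the observed
margins that are no more likely than the observed table. The p-value is
computed by `scipy.stats.fisher_exact`; the test suite verifies it against
an independent full-enumeration oracle on **every** 2×2 table with total
≤ 40 (135,751 tables, max |Δ| < 1e-12). Degenerate margins (an empty row
or column) give p = 1 — only one table exists.

**Odds ratio.** The reported OR is the sample OR `ad/bc`. When exactly
one cell is zero the Haldane–Anscombe +0.5 correction is applied to all
four cells *for the reported OR only* (the p-value is untouched); when a
full margin is zero (nobody or everybody is a carrier, or an arm is
empty) the OR is undefined and reported as NA. Significance flags treat
an NA odds ratio as "not > 1".

**Bonferroni.** Thresholds are `α/n` at full precision; the denominator
for the region scan is the number of loci in the input table (not the
subset with carriers), for the burden test the size of the gene's dosage
tier, and for the phenotype scan the number of evaluated gene-term pairs
*before* the direction filter — the reading fixed by the published
threshold arithmetic (0.05/40,838 ≈ 1.22e-6).

**One-sided binomial TDT.** `p = P(X ≥ k | n, ½)` by exact tail
summation (`scipy.stats.binomtest`), with a two-sided 95% Clopper-Pearson
interval for the transmission probability. Verified against direct tail
summation for all n ≤ 60.

## Region scan

The primary per-locus test pools deletions and duplications ("a CNV in
the region"); per-type tables are also tested and used to label the locus
with the type(s) whose case carrier frequency exceeds the control
frequency. Locus membership needs ≥1 bp of overlap by default
(`min_overlap_bp` configurable — no published overlap threshold exists
for locus assignment); a sample with several qualifying CNVs counts once.
Novelty against a reference region list uses reciprocal overlap:
≥ 50% ⇒ known, any positive overlap below that ⇒ boundary expansion,
none ⇒ novel.

## Dosage tiers

HI requires pHI ≥ 0.84, TS requires pTS ≥ 0.993. The published tier
definitions double-book the corner point (0.84, 0.993); here bHITS takes
priority (≥ on both scores) and HI/TS require the opposing score to be
strictly below its cutoff, so the three tiers partition the score square.
A gene contained in two overlapping risk regions is listed per region but
counted once in tier totals. Scores are inputs; their derivation is out
of scope.

## Rarity rule and burden test

A CNV is rare when the union of same-type common variants (AF ≥ 0.001)
covers **≤ 50%** of it — exactly 50% is not "more than 50%", so such a
call is retained. Masking is type-matched (DEL vs common DELs, DUP vs
common DUPs): cross-type masking would conflate loss and gain mechanisms.
The coverage statistic is one-directional (fraction of the query
covered); a pairwise reciprocal-overlap mode exists behind a flag. The
burden test matches the CNV class to the tier — deletions for HI genes,
duplications for TS genes, both pooled for bHITS — following dosage
logic; per-class results are emitted for every gene regardless. Case
carriers are pooled into a single column (no per-cohort stratification).

## TDT counting

The counting unit is one (carrier parent, affected child) pair per
gene-level deletion: every affected sibling contributes one opportunity
per carrier parent, and a transmission is recorded when the child carries
a deletion overlapping the same gene (breakpoint identity is not
required; array-era boundaries are imprecise). Only affected children
count; unaffected siblings are ignored. A per-family collapsed mode
(`per_family=True`) is provided since the family-level convention is also
in use. Two exclusions keep the null honest:

* a child deletion present in neither parent is de novo, not a
  transmission (logged and ignored);
* when **both** parents carry a deletion hitting the same gene, the
  child's carrier status cannot be attributed to either parent at gene
  level; those opportunities are uninformative and are dropped — counting
  them credits each parent with P(child carries) = 1 − (1−t)² instead of
  t and inflates the null false-positive rate (we measured 0.07 instead
  of ≤0.05 before adopting the exclusion).

## Expression analysis

Counts are normalized with median-of-ratios size factors (the DESeq
estimator) followed by log2(x+1). The downstream statistic — top-5%
membership per (stage, region) stratum — is rank-based within each
stratum, so any monotone variance-stabilizing map yields identical flags;
the log2 transform is used as that map, a deliberate substitution for a
model-based VST. Genes are summarized per stratum by the mean of
transformed values (median mode available), the distribution is computed
per stratum (not pooled), and the threshold is the empirical 95th
percentile with ties included — with every gene identical, all genes tie
at the threshold and all are flagged (documented degenerate behavior).
"Persistently high" genes are flagged at every developmental stage within
at least one brain region (an all-regions mode exists).

## Phenotype scan

Evaluated pairs are (gene, term) combinations observed in at least one
carrier of the gene; pairs whose carrier incidence exceeds the population
incidence (computed over all patients in the table) are tested, carriers
vs non-carrier patients. Carriers of *other* genes remain in the
comparison group. Terms are flat labels; no ontology propagation.

## Network statistics

Edges with score ≥ 0.4 (inclusive) are high-confidence. Expected induced
edges for a gene set come from a permutation null (random equal-size node
subsets) with the add-one estimator `p = (1 + #{perm ≥ obs})/(B + 1)`,
never zero; for an Erdős–Rényi background the expectation converges to
the density closed form `E·k(k−1)/(N(N−1))` (property-tested). No
service-specific analytical edge model is replicated. Both the mean-local
clustering coefficient (nodes of degree < 2 contribute 0) and the global
transitivity are emitted, since "cluster coefficient" is ambiguous.

## Synthetic-data generator

The generators define the study conditions the pipeline is validated
under:

* **Cohorts** — planted risk loci with control carrier frequency f and
  odds ratio OR; case carrier frequency is the odds transform
  `OR·f/(1−f+OR·f)`. Planted carriers get exactly one deletion spanning
  the full locus. Background events (Poisson per sample, default mean
  0.5 — the order of rare CNV calls surviving frequency filters on
  arrays; type Bernoulli, length log-uniform 20 kb–2 Mb) are placed
  uniformly over rounded autosome lengths and rejection-sampled to never
  intersect risk loci, making planted effects the only case-control
  signal. Default planted frequencies (0.001–0.01) are package choices;
  no published per-locus control frequencies exist.
* **Annotations** — tier counts are allocated deterministically
  (`round(frac·n)`), scores drawn uniformly inside each tier's score box,
  and CDS spans tiled into disjoint slots per region: overlapping spans
  would let one deletion hit several genes and cross-credit transmissions
  or burden carriers, an artifact real annotations rarely exhibit.
* **Families** — each parent carries a deletion over one target gene with
  a given probability and transmits it to each affected child
  independently with the planted transmission probability; the child
  inherits the parent's exact coordinates (an inherited CNV is the same
  event). Parents are unaffected, children affected.
* **Expression** — negative binomial with variance m + d·m²; baseline
  means uniform in [0.5, 2]·nb_mean, planted genes at 20·nb_mean in every
  stratum; dispersion 0 degenerates to deterministic counts (the all-ties
  case). Defaults nb_mean = 50, dispersion = 0.3, 4 samples per stratum —
  bulk-RNA-seq-like moderate counts.
* **Phenotypes** — carriers of an effect gene draw the term at the effect
  incidence, everyone else at the background incidence.

Each generator derives an independent random stream from
`(seed, CRC32(stream name))`, so adding one generator call never perturbs
another and fixed seeds give byte-identical outputs.

What the generators do **not** emulate: genotyping-array intensities and
call errors, linkage disequilibrium, cohort heterogeneity across source
studies, ontology structure among phenotype terms, and realistic
gene-length/GC covariation in expression. Passing the planted-recovery
suites therefore shows the *statistical machinery* is correct under the
assumed sampling models, not that those models capture every property of
the clinical data.

## Calibration and power studies (`cnvdriver.studies`)

Study sizes are chosen to be informative on one CPU. The null region-scan
calibration (10 all-null cohorts of 2,000+2,000 samples × 200 loci ⇒
2,000 per-locus tests) uses *polymorphic* loci (carrier frequency 0.1):
the nominal-rate band check asks the p-values to be uniform, and at
rare-CNV frequencies the exact test's discreteness makes its achieved
size ≈ 0.029–0.035 — conservatism, which the band check would measure
instead of correctness. At carrier frequency 0.1 the achieved size is
≈ 0.044 and the observed nominal rate sits inside the exact binomial 99%
band around 0.05. The TDT null suite (300 replicates at transmission 0.5)
and the phenotype null suite (40 replicates, expecting zero corrected
hits) are analogous. Power studies: planted locus f = 0.01, OR = 10 at
5,000+5,000 samples (200 replicates, detected in >95%), transmission 0.75
with ≥100 opportunities (500 replicates, one-sided p < 0.05 in >80%), and
gene burden OR = 8 at 4,000+2,500 (200 replicates, >90%) — all planted
effects are in practice detected in essentially every replicate at these
sizes.

## Known limitations

* No meta-analytic heterogeneity modeling or covariate adjustment in the
  region scan (sources are pooled into one table).
* Duplications are excluded from the TDT (duplication calls from
  short-read family data are unreliable); no parent-of-origin inference
  from genotypes.
* The pipeline's `enrichment` stage reproduces GO-style enrichment
  structurally (user-supplied GMT catalogs, Bonferroni over sets); it
  does not query any enrichment service.
* Exactly reproducing published cohort-dependent counts is out of scope:
  those numbers require the original clinical data.
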