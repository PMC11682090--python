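# Methods

`moiscan` implements a candidate-causal-variant discovery analysis for a
rare, presumed-monogenic disorder studied by whole-genome sequencing of a
small case series against tiered control cohorts — the setting of bovine
spastic syndrome (SS), an adult-onset neuromuscular disorder in Holstein
cattle.  This note records the model, the parameters that matter, the
design choices that were genuinely open, and what the bundled synthetic
cohorts do and do not demonstrate.

## The filtering model

Let `G[v, s] ∈ {hom-ref, het, hom-alt, missing}` be the zygosity of sample
`s` at biallelic variant `v` (multiallelic sites are split beforehand; a
genotype carrying any other alternate allele, or a half-missing genotype,
is *missing* for that record).  The cohort manifest partitions samples
into cases, a tier-1 control cohort (the primary comparison set) and a
tier-2 control cohort (a larger global set, subdivided into populations).

Three mode-of-inheritance (MOI) scenarios are screened, each as a
four-stage funnel:

| stage | recessive shared | recessive per-case | dominant per-case |
|---|---|---|---|
| all | hom-alt in every case | hom-alt in the case | het or hom-alt in the case |
| private (tier 1) | tier-1 hom-alt ≤ 0, het unbounded | same | tier-1 alt alleles ≤ 0 |
| protein-changing | ≥ 1 annotation term in the configured set | same | same |
| post tier 2 | tier-2 hom-alt ≤ 0, het unbounded | same | tier-2 alt alleles ≤ 0 |

All thresholds are configurable (`FilterConfig`); the table shows the
defaults.  Two asymmetries are deliberate:

* **Recessive privacy allows heterozygous control carriers.**  A recessive
  causal allele is expected to segregate in carrier state in the wider
  population; requiring strict allele absence would discard exactly the
  variants the model predicts.  Only homozygous-alternate controls defeat
  recessive privacy by default (threshold 0).
* **Dominant privacy is strict.**  Under a fully penetrant dominant model
  no unaffected control may carry the allele, so the default threshold is
  zero alternate alleles in both tiers.

Missing genotypes never count as control carriers (conservative toward
keeping candidates), while a missing *case* genotype excludes the variant
for that case's filters (conservative toward not asserting a genotype that
was not observed).  Only PASS-labelled records enter the analysis by
default; records with an empty FILTER column can be opted in.

The default protein-changing term set is: missense, stop gained/lost,
start lost, frameshift, conservative/disruptive in-frame insertion and
deletion, splice acceptor/donor, protein-altering.  It covers the variant
types that change an encoded protein under standard sequence-ontology
annotation (including the in-frame deletion class seen among real SS
candidates) and is configurable because annotation pipelines differ in
their term inventories.

Funnel reports record the four per-case counts and the final-stage gene
symbols; counts are non-increasing by construction and the report builder
hard-fails if they are not.  All variant ordering and tie-breaking is by
(chromosome rank, position, ref, alt), with chromosome rank taken from the
provided chromosome table (VCF header contigs by default) — outputs are
deterministic for identical inputs.

## Runs of homozygosity and F_ROH

ROH are detected per sample with a consecutive-runs scan (no sliding
window): markers are walked left to right; a run starts at the earliest
unconsumed homozygous marker and extends to the furthest marker such that
the run contains at most `max_opposite` heterozygous calls, at most
`max_missing` missing calls, and no adjacent-marker gap above `max_gap`;
the run is then trimmed back to its last homozygous marker, and detection
continues after it.  Equivalently: among all valid homozygous-endpoint
intervals, greedily keep the one with the smallest start (largest end on
ties) and discard overlapping intervals.  This frozen formulation admits
an exact independent oracle (interval enumeration plus greedy selection),
which the test suite exercises on random tracks.  Runs are finally
filtered to `min_snp` markers and `min_length` bp.  One algorithm with an
exact oracle was preferred over also shipping a sliding-window variant.

Defaults: `min_snp=20`, `min_length=50 kb`, `max_gap=1 Mb`,
`max_opposite=1`, `max_missing=1` — near the documented defaults of the
widely used consecutive-runs implementation in livestock genetics; all
configurable.  Marker tracks come from the same VCF as the filtering
analysis, optionally strided to bound runtime.

Shared homozygous regions are the interval intersection of every case's
ROH union, filtered to `min_shared_length` (default 10 kb, "kb-sized");
the result is invariant under case order.  The genomic inbreeding
coefficient is `F_ROH = Σ autosomal ROH length / Σ autosome length`, a
[0, 1] fraction, with the autosome set supplied as a chromosome-length
table (a table for the cattle ARS-UCD1.2 assembly is bundled).  The
denominator is always the full autosome length — "SNP-covered length"
denominators were rejected for determinism and comparability.  Cohort
mean and standard deviation use the n−1 (sample) denominator.

Intervals are 0-based half-open internally and in BED exports; VCF
positions are 1-based and the conversion lives in one function.

## Population frequency tables

For a target variant, per-population genotype counts (hom-alt / het /
hom-ref / missing) feed the allele frequency
`AF = (2·n_hom-alt + n_het) / (2·(n_hom-alt + n_het + n_hom-ref))`.
Missing genotypes are excluded from the denominator and never imputed
(array and WGS subcohorts have different missingness).  Percent display
uses two significant figures, the convention that reproduces every
internally consistent published row this package was checked against; the
exact fraction is always emitted alongside.  A population with no
genotyped sample yields a flagged undefined row rather than a number.

## Candidate classification

The classifier is a deliberately small, frozen rule cascade ("ACMG-lite")
over the evidence this pipeline can actually see; the full 28-criterion
clinical framework is under-determined here:

* **R1** — if no tool predicts the variant deleterious ("at least one
  deleterious" defines the consensus) or the gene is not flagged as a
  neuromuscular-disease candidate: *not a candidate*.
* **R2** — homozygous under a recessive model, deleterious, candidate
  gene: *likely pathogenic*.
* **R3** — otherwise (carrier state: dominant model or heterozygous),
  deleterious, candidate gene, no segregation data: *uncertain
  significance*.

The gene-level candidacy flag is user-supplied with a free-text evidence
note (function, associated disorders, expression) rather than computed
from external databases, avoiding database-version dependence.  Residue
conservation, computed from an aligned FASTA as the fraction of non-gap
sequences matching the reference residue at the affected column, is
descriptive: at or above 0.9 (configurable) it is noted in the rationale
but never changes the class.  Inconsistent bundles (hom-ref or missing
case zygosity) are hard errors.  The cascade is total and monotone:
every valid bundle maps to exactly one class, and adding a deleterious
prediction can never downgrade it.

## The synthetic cohort generator

The generator emulates the *design* of the study cohort, not its
population genetics: n cases, a tier-1 cohort, labelled tier-2
populations, background polymorphism, planted MOI-consistent variants
with designated control carriers, and planted per-sample ROH blocks, all
written as an annotated multi-sample VCF plus a machine-readable truth
table.  Modelling choices:

* Background genotypes are drawn under Hardy–Weinberg equilibrium with a
  per-variant allele frequency uniform on [0.01, 0.5] — the minimal
  neutral choice.  There is no linkage disequilibrium, no coalescent
  ancestry, no sequencing-error or coverage model, and no sex chromosomes
  (the analysis concerns autosomes).
* Evenly spaced marker variants (default grid) provide the homozygosity
  track; outside planted blocks they are heterozygous at a configurable
  rate (default 0.5) so runs terminate quickly, and inside a sample's
  planted block *every* variant of that sample is homozygous — an ROH is
  homozygous at every site by definition, and without this the background
  draw would shred planted runs.
* **Zero false candidates are guaranteed by construction, not by
  probability:** any non-planted variant with no homozygous-alternate
  tier-1 control has one forced in, which simultaneously defeats
  recessive privacy (hom-alt threshold 0) and dominant privacy
  (alt-allele threshold 0) for every case.  This slightly inflates rare
  background allele frequencies and is a test-harness constraint, not a
  biological feature.
* Planted genotypes are stamped exactly and never randomized; control
  carriers are the first k samples of their population, so different
  seeds change the background but never the planted truth.  Outputs are
  byte-identical for a given seed.

Passing tests on these cohorts therefore demonstrates the *logic* of the
filters, interval arithmetic and classification — recovery of everything
that satisfies a filter's definition and nothing else — but says nothing
about real-data properties driven by LD, relatedness, call-set error or
annotation quality.

### The bundled preset

`paper_like_preset()` mirrors the published study structurally: 7 cases,
1031 tier-1 controls, four tier-2 populations with heterozygous carrier
counts 71/6/4/0 for the recessive candidate, one recessive case-private
planting, seven dominant case-private plantings across six cases (one
case digenic, two genes), one dominant tier-2 decoy that survives tier 1
but is removed by a single global-cohort carrier, five shared homozygous
blocks totalling exactly 2.2 Mb, and per-case private blocks sized so the
case F_ROH values are {0.10, 0.11, 0.13, 0.15, 0.17, 0.19, 0.20} — mean
0.15, sample SD 0.039 — on a two-chromosome 100 Mb pseudo-genome with 100
markers/Mb.  Tier-2 population sizes are scaled down (673 total) because
the preset's purpose is funnel structure, not tier-2 allele-frequency
estimation; tier-1 is kept at full size.  Detected shared-ROH totals land
within a few percent of 2.2 Mb: block edges are resolved only to the
10-kb marker spacing, and runs may extend a marker or two past a block
before hitting their heterozygosity budget.

## Problem sizes and numerical notes

* The preset cohort is 12,009 variants × 1,711 samples and runs end to
  end (simulate, parse, three funnels, ROH, F_ROH) in well under a
  minute; the full test suite, including 100-cohort and 100-track oracle
  sweeps and a 20-seed recovery study, completes in tens of seconds.
* Oracle sweeps use cohorts up to 500 variants × 30 samples and marker
  tracks up to 1,000 markers, with randomized thresholds.
* Genotype classes are stored as int8 matrices; filters are vectorized
  numpy reductions; candidate sets are materialized lists of records so
  stage nesting can be asserted directly.
* Percent rounding: two significant figures via decimal rounding on the
  percent scale (`0.0060622 → 0.61%`, `0.0273973 → 2.7%`); zero prints
  `0%`; an undefined frequency prints `NA`.
* HGVS strings from annotations are carried verbatim and never validated
  or recomputed — upstream annotation output is occasionally internally
  inconsistent, and filter logic only consumes effect terms.

## Known limitations

* The real study's per-case variant totals, its exact 2.2 Mb/5-region
  shared-homozygosity map and its F_ROH of 0.15 ± 0.04 arise from real
  genomes and unstated detection parameters; they are reproduced here
  *structurally* (by construction of the preset), not from data.
* Consecutive-runs only; no sliding-window ROH, no homozygosity-mapping
  association statistics.
* No statistical association testing, imputation, structural-variant
  screening or in-house deleteriousness prediction; external predictions
  are consumed as evidence, never computed.
* The classifier encodes the three decisions the evidence model supports;
  it is not a general clinical-guideline implementation.
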