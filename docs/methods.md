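# Methods

## Scope and model

`panelclass` implements a gene-level molecular classification of gastric
cancer from targeted panel sequencing. The unit of analysis is a tumor's
alteration profile over a capture panel (435 genes, 69 of them "actionable",
i.e. paired with an FDA-approved targeted therapy): somatic small-variant
calls, gene-level copy-number fold changes, viral read fractions for EBV and
HPV-16/18, and an indel count over a catalog of microsatellite loci.
Upstream steps (alignment, variant calling, annotation) are out of scope;
the package consumes their gene-level outputs.

## Biomarker calling

**Tumor mutation burden (TMB).** The rate of peptide-changing SNVs per
megabase of captured region: SNVs with putative impact *high* or *moderate*
and allele fraction ≥ 10% are counted and divided by the ROI size in Mb.
Indels and silent/low-impact variants are excluded. The ROI size of the
panel is a required configuration value (default 1.7 Mb) because it cannot
be derived from gene symbols alone; TMB scales inversely with it, so
cohort-internal comparisons are unaffected by its choice while absolute
counts/Mb are not.

**Microsatellite instability.** A tumor is MSI-H when its indel count over
the repeat-locus catalog reaches a threshold (default 20 indels, inclusive).
The catalog itself is not re-derived (it requires a reference genome); the
count arrives as an input summary. The threshold default was chosen so a
bimodal cohort (MSS indel counts ~Poisson(3), MSI-H counts 20+) separates
cleanly; it is a configuration value, not a measured constant.

**Viral status.** Positivity is called per virus from the percentage of
reads mapping to the viral genome, against empirical cutoffs of 0.0005%
(EBV), 0.02% (HPV-16) and 0.01% (HPV-18). Comparisons are inclusive (≥) —
the convention adopted here for all "empirical cutoff" boundaries — and
configurable.

**Copy number.** Gene-level gains are fold change > 2.5, losses < 0.75
(strict inequalities, as stated for the calling pipeline these thresholds
come from); everything else is neutral. The SCNA locus count is the number
of distinct genes with a gain or loss.

## Subtyping decision tree

Tumors are assigned one of the four TCGA-style subtypes sequentially:
EBV-positive → **EBV**; else MSI-H → **MSI**; else ≥ 4 SCNA loci → **CIN**;
else **GS**. The precedence order and the 4-locus cutoff follow the source
classification scheme. `derive_scna_cutoff` offers a data-driven
re-derivation of the locus cutoff: candidate cutoffs k = 1..10 are scored by
the product of two two-tailed Fisher p-values — SCNA-high (≥ k) vs TP53
mutation, and SCNA-low (< k) vs diffuse Lauren histology — on EBV-negative
MSS tumors, and the minimizing k wins with ties broken toward smaller k.
This scan is one defensible operationalization of a cutoff choice that was
originally presented graphically; the cutoff can always be set directly.

**Hypermutation.** The cutoff is the minimum TMB among MSI-H tumors, and a
tumor is hypermutated when its TMB is ≥ that cutoff. The comparison is
inclusive although the narrative phrase is "more than": the defining MSI-H
tumor is itself hypermutated and every MSI-H tumor must be in the
hypermutated set, which strict inequality would violate. Cohorts without an
MSI-H tumor cannot derive a cutoff and must supply one explicitly.

## Co-alteration clustering

For non-hypermutated donors i, j the count c_ij is the number of genes (from
a chosen gene set — the 69 actionable genes by default, or all 435) altered
in both tumors, where "altered" means any small variant or an SCNA
gain/loss. The diagonal c_ii is the tumor's own altered-gene count and is
normalized like any other entry. Each entry is replaced by 1/(c_ij + 1), a
strictly decreasing map of counts into (0, 1] with 1 meaning no shared
alteration. The matrix is used verbatim: rows of the normalized matrix are
the feature vectors, clustered agglomeratively with Euclidean distance and
Ward linkage. (Clustering a condensed distance form of the matrix is a
plausible alternative reading; rows-as-features is the implemented choice.)
Trees are cut by merge order (`cut_tree`), so exactly k clusters result even
under tied merge costs, and cluster indices are renumbered by first
appearance in row order for determinism; scipy's nearest-neighbor-chain
Ward implementation makes the merge sequence itself deterministic.

**Choosing k.** Three internal validation measures are computed per
candidate k: connectivity (sum of 1/j penalties for each observation whose
j-th nearest neighbor, j ≤ 10, lies in another cluster; lower is better),
average silhouette width, and the Dunn index (minimum between-cluster
distance over maximum cluster diameter, defined as +∞ when all clusters are
point masses). Average silhouette is the primary criterion (ties toward
smaller k); the full table is returned for inspection. k can be pinned
(k = 6 reproduces the published six-cluster structure).

**Labeling.** Each cluster is named by the gene with the smallest two-tailed
Fisher p-value (cluster vs rest) among genes altered in ≥ 50% of the
cluster's tumors; clusters with no such gene are "unassigned", matching the
background cluster of tumors with minor or no actionable alterations.
Exact ties break lexicographically (the CDKN2A/CDKN2B co-deletion cluster
therefore labels as CDKN2A).

## Statistics

Alteration frequencies are percentages of tumors with ≥ 1 alteration per
(gene, class), rounded half away from zero to one decimal; mutation and
SCNA (AMP/DEL) tables are separate. Group associations use two-tailed
Fisher's exact test for categorical features (multi-level features
dichotomized one level at a time) and the Mann–Whitney U test for continuous
ones, each group against all remaining donors; hypermutated-vs-rest
contrasts can restrict the reference set to non-hypermutated donors. The
Mann–Whitney p is exact when min(n) ≤ 8 and the pooled sample has no ties,
otherwise the normal approximation with tie correction — the switch point is
a package choice. Raw p-values carry the significance flag at P < 0.05 with
no multiple-testing correction, mirroring the practice of the cohort
analyses this package emulates; Benjamini–Hochberg adjusted values are
emitted alongside for more conservative reuse.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions the package targets:

* **n = 207** tumors; subtype mixture exactly 9/207 EBV, 17/207 MSI,
  119/207 CIN, 62/207 GS, realized by largest-remainder allocation so the
  default cohort reproduces the counts 9/17/119/62;
* **TMB arms:** MSI-H uniform on [18.5, 66.9] counts/Mb, MSS uniform on
  [3.1, 27.7] (printed ranges; only medians and ranges are published, so
  uniform is the default and a triangular option matching the printed
  medians, 31.5 and 11.2, is provided). One MSI-H tumor is anchored at the
  arm floor so the derived hypermutation cutoff equals the floor.
* **Hypermutated tumors: 32** — all MSI tumors plus enough non-MSI tumors
  drawn at random, with TMB above the MSI-H floor;
* **Planted clusters** among the 175 non-hypermutated tumors: ERBB2
  amplification (25), CDKN2A/B co-deletion (10), KRAS (10), BRCA2 (9) and
  ATM (12) mutation, each label firing with probability 0.9 inside its
  cluster and 0.05 elsewhere; the remaining 109 tumors form the background
  cluster;
* **Background gene frequencies** seeded from the published 207-tumor
  frequency table (TP53 mutation 0.531, ARID1A 0.159, …, ERBB2 AMP 0.121,
  CCNE1 AMP 0.068, …), with qualitative subtype coupling (TP53 enriched in
  CIN, CDH1 in GS) via per-(gene, subtype) multipliers — synthetic defaults,
  not estimates;
* **Biomarker planting:** intended-EBV tumors draw EBV read fractions above
  the 0.0005% cutoff (log-uniform up to 0.05%), others below it;
  intended-MSI tumors draw indel counts ≥ the MSI threshold, others are
  clipped below it; intended-CIN tumors receive ≥ 4 distinct SCNA loci and
  all other tumors are capped at 3.

Two structural choices matter for recovery semantics:

1. **TMB is realized through actual variant lists.** A tumor with target
   burden t gets ⌈t·roi⌉ qualifying SNVs if it belongs to a hypermutated
   arm and ⌊t·roi⌋ otherwise. Under this quantization every
   hypermutated-arm tumor's realized TMB stays at or above the MSI-H arm
   floor and every other tumor's stays below it, so the derived cutoff
   recovers the planted hypermutated set exactly. Filler and noise variants
   for non-hypermutated tumors are drawn from non-actionable genes only, so
   they do not dilute the planted actionable-gene structure.
2. **Recurrent non-label actionable alterations live in the hypermutated
   arm.** Treating the published actionable-gene frequencies (PIK3CA 8.7%,
   RNF43 5.8%, …) as independent background probabilities would create
   co-alteration blocks structurally identical to planted clusters — every
   cluster here is a "shared single gene" block — and no clustering
   algorithm could then separate planted from incidental structure. The
   generator therefore concentrates these alterations in the hypermutated
   tumors (rate scaled by n/n_hyper so the cohort-level frequency is
   preserved), which also reflects the known enrichment of recurrent
   oncogenic mutations in hypermutated MSI/EBV gastric tumors. Consequently
   the non-hypermutated actionable landscape is exactly the six-cluster
   structure plus background label firings.

The **ground truth** table records, per tumor: the intended subtype, the
hypermutation flag, the intended cluster assignment, and the *realized*
cluster — the first planted label (in cluster order, ERBB2 first) whose
gene the tumor actually carries, or "none". Clustering recovery is measured
against the realized membership: the published clusters are defined by the
alterations themselves (cluster 1 *is* the ERBB2-altered tumors), so a
background tumor that drew an ERBB2 alteration genuinely belongs to that
cluster, and an intended member whose label never fired genuinely does not.

### What the generator does not emulate

Real panel data have correlated multi-gene alteration patterns, mutational
signatures, subclonal allele-fraction structure, purity/ploidy effects on
fold changes, and locus-level (not gene-level) copy-number segments. Gene
frequencies here are independent Bernoulli draws (plus filler inflation
from TMB realization: every non-actionable gene's frequency carries a small
positive offset of roughly mean-SNVs/366 ≈ 5–7 percentage points).
Passing recovery tests therefore demonstrates that the pipeline's logic is
correct under the stated statistical structure, not that it is robust to
every artifact of real sequencing data.

## Problem sizes and numerics

Tests and the acceptance script run the full default cohort (n = 207;
clustering over 175×175 matrices), 1,000-cohort cutoff-derivation sweeps,
and exhaustive exact-test enumerations (all 2×2 tables with grand total
≤ 30; Mann–Whitney rank-split enumeration at n ≤ 8) — sizes chosen so the
whole suite completes in well under a minute while still exercising every
code path at realistic scale. Fisher p-values are compared to enumeration at
relative tolerance 1e-7; round-trip I/O preserves numeric fields to 6
significant digits. Degenerate inputs fail loudly: no MSI-H tumor (cutoff
derivation), all-identical rows (silhouette), empty gene sets, k outside
[1, N], non-positive fold changes or ROI sizes.

## Known limitations

* The ROI size (TMB denominator) and the MSI threshold are configuration
  values, not published constants; absolute TMB values depend on them.
* The SCNA cutoff scan is one reading of a graphically presented
  derivation; other objective functions could pick different cutoffs on
  borderline cohorts.
* Cluster labels come from marginal enrichment; a cluster defined by a
  combination of genes with no single dominant member labels "unassigned".
* The similarity transform 1/(c+1) compresses large counts (c = 10 vs
  c = 20 differ by < 0.05), so the method is most sensitive to the 0-vs-1
  shared-alteration distinction; this is inherited from the published
  method, implemented verbatim.
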