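# Methods

`coresnp` re-creates, as a tested pipeline, the construction of core SNP
marker sets for crop variety identification and DUS testing (distinctness,
uniformity, stability): mine genome-wide SNPs for trait association, keep a
small candidate set, and reduce it to nested panels whose genotype vectors
uniquely identify every variety while still resolving the UPOV test-guideline
traits through genotype clustering. This note records the models, the
defaults and why, and the places where a design choice was genuinely open.

## Data model

Genotypes are biallelic diploid calls stored as an `int8` matrix
(varieties x markers) with codes 0 = hom-ref, 1 = het, 2 = hom-alt,
-1 = missing; coordinates are 1-based inclusive everywhere (VCF convention).
Traits are typed QL (qualitative), QN (quantitative) or PQ
(pseudo-qualitative); graded traits carry their declared integer grade set
and QN traits are measurements.

## Synthetic panel generator

Real panels of this kind are commercial variety collections: a handful of
diverged market-type subpopulations, mostly F1 hybrids, genotyped by
reduced-representation sequencing with appreciable missingness. The
generator emulates exactly that:

- **Subpopulation divergence.** Cluster allele frequencies are drawn from
  the Balding–Nichols model, Beta(p(1-F)/F, (1-p)(1-F)/F) around an
  ancestral frequency p with MAF floor 0.05. Default F_ST = 0.2, a moderate
  divergence typical of distinct market types; K = 7 clusters.
- **Variety types.** Inbred lines are gamete-doubled (one allele drawn per
  locus, fully homozygous — their heterozygosity is exactly 0). F1
  varieties take one allele from each of two simulated inbred parents and
  are heterozygous exactly where the parents differ. Default
  `f1_fraction = 0.8`, reflecting the predominance of F1 hybrids among
  commercial cabbage varieties. Parents cross within a cluster by default;
  between-cluster crossing is a flag, since how real F1 parents relate
  across clusters is not knowable from panel data.
- **Traits.** 19 traits typed 2 QL / 11 QN / 6 PQ. QN values are
  `effect_size x noise_sd` per alt allele summed over `causal_per_trait = 5`
  causal markers, plus Gaussian noise (`noise_sd = 1`). QL/PQ traits
  threshold the same kind of causal score into their integer grade levels
  ((1, 9) for QL, (1, 2, 5) for PQ) at score quantiles, so graded traits
  stay linked to genotype but take only printed grade values.
- **Missingness** is uniform at rate 0.1 by default (GBS-like);
  assay-grade panels are simulated at 0.005 (high-call-rate chip
  genotyping). Missingness is applied after trait generation, so phenotypes
  are not secretly informed by masked calls.
- **Determinism.** One `numpy` Generator seeded from the spec; identical
  specs give bitwise-identical panels.

What the generator does *not* emulate: linkage/recombination maps (markers
are exchangeable given their cluster frequencies), allele-frequency spectra
shaped by ascertainment, marker-biased missingness (available behind a
flag), genotyping error, and trait architectures beyond additive effects.
Passing recovery tests therefore show the pipeline's statistics behave
correctly under the model's assumptions, not that real panels satisfy them.

A separate helper simulates gene-model intervals (CDS synonymous /
non-synonymous blocks, introns, 1 kb flanks; roughly a third of the genome
genic) so the annotation-aware stages can be exercised end to end.

## Marker metrics and filters

MAF and call rate are computed over called genotypes only (a het
contributes one copy of each allele). PIC uses the biallelic closed form
`1 - (p^2 + q^2) - 2 p^2 q^2`, verified in tests against a from-scratch
enumeration of parent-offspring matings; it peaks at 0.375 at MAF 0.5.
Filters are strict inequalities (`maf > 0.05`, `missing < 0.30` for
association, `< 0.10` for structure), matching the usual screening wording;
filtering is idempotent.

## Association funnel

Each trait is regressed on additively coded genotype (0/1/2) by ordinary
least squares with an F-test, varieties dropped pairwise on missing
genotype or phenotype; markers monomorphic after dropping are flagged with
p = 1. Graded traits enter as their integer grade codes (they are ordered
by construction); a one-way ANOVA mode exists for unordered PQ traits. No
multiple-testing correction is applied — downstream stages consume rank
order only, and the selection threshold is a rank (top 200 per trait), not
a significance level. Ties break deterministically by larger MAF, then
position. Pooled top-K lists are deduplicated to one entry per (chrom, pos)
keeping the best trait, then candidates are picked greedily by genic-class
priority (CDS > other genic > intergenic group) and association strength
subject to a minimum physical spacing, halving the spacing (logged) when
the target is otherwise unreachable. The exact rule the original screen
used to mix "annotation" and "distribution" is not written anywhere; this
priority-plus-spacing greedy is one declared, reproducible reading.

## Core-set selection

A marker *separates* a variety pair when both calls are present and differ;
het vs hom counts as different (chip scatter calls resolve them), missing
never separates — conservative for identification claims. Unique
identification of all varieties is a set cover over the C(n,2) pairs,
solved by the classic greedy (pick the marker covering the most uncovered
pairs; ties to higher PIC, then panel order). Greedy replaces the manual
"randomly select, then purposefully include/exclude" search for
reproducibility; a seeded randomized-restart mode emulates that search when
wanted. Pairs no marker can separate (duplicate varieties) are reported in
the certificate, never dropped silently.

Nested panels grow from the smallest set by a weighted score of (a)
pair-coverage redundancy, (b) entropy gain of per-trait marker
representation and (c) per-cluster allele-frequency contrast, guaranteeing
the subset chain (the published panels are nested the same way). Sets
capped below the greedy minimum are returned with unresolved pairs flagged.
`verify_identification` reports distinct-profile counts as connected
components of the collision graph, which equals the number of unique
restricted genotype vectors when data are complete.

## Diversity analyses

The default distance is allele sharing: per co-called locus 0 / 0.5 / 1 for
identical / one-shared-allele / opposite homozygotes, averaged over
compared loci. The original study fed IUPAC genotype FASTA to a tree
program without stating its distance model, so a strict-mismatch metric is
provided for sensitivity analysis and no published branch-length sum is
treated as a reproducible target. UPGMA (average linkage, node height =
distance/2, lexicographic tie-break) and Saitou–Nei neighbor joining are
implemented in-package so that tie-breaking, branch-length statistics and
the negative-branch convention (clamp to zero, shift the remainder to the
sister edge, preserving the joined pair's distance) are explicit; tests
cross-check them against `scipy`'s average linkage and `scikit-bio`'s NJ,
and NJ provably reproduces additive metrics exactly. Bootstrap support
resamples markers with replacement (seeded) and scores bipartition
frequency.

The population-structure stage is deliberately *not* a variational
admixture model: it is K-medoids on the genotype distance matrix (best of
10 seeded restarts), with Q-like soft proportions as normalized inverse
medoid distances and hard labels by argmax — the same "highest ancestry
proportion" assignment rule. Internally the algorithm runs in id-sorted
canonical order, so permuting input rows permutes labels only. Clusters are
relabeled by decreasing size; an optional outgroup flag gives the most
divergent cluster the sentinel label 99 (mirroring the convention of
labelling an outlying market type separately). PCA variance fractions come
from `sklearn` on the mean-imputed centered dosage matrix (mean imputation:
simplest defensible default). LD decay bins squared Pearson correlation of
dosages by physical distance within chromosomes; the decay distance is the
first bin below a threshold (default half the maximum bin mean).

## Cluster-trait evaluation (DMRT)

Per trait, one-way fixed-effects ANOVA across cluster labels (unbalanced
groups supported, zero-variance data give p = 1), gated at p < 0.05. Duncan's
new multiple range test compares the p ordered means spanning a gap with

    R_p = q(1 - (1 - alpha)^(p-1); p, df_error) * sqrt(MSE / n_h),

using Duncan's protection level, the studentized-range quantile q (from
`scipy.stats.studentized_range`, validated against printed tables in the
tests, and cached because its numeric inversion is expensive), and the
harmonic mean n_h of the span's group sizes (the clusters are unbalanced; a
package default would otherwise decide this silently). A non-significant
wider span protects all inner pairs, and letters come from the standard
insert-and-absorb display. For two groups the span-2 criterion reduces
exactly to the two-sample t-test, which the tests verify.

"Explained by g groups" is formalized from the narrative usage: a trait is
explained when the global p < alpha and the letter display has more than one
letter; g is the number of distinct letters; clusters carrying several
letters (the `a / ab / b` pattern) set an overlap flag and are listed as
unclear rather than resolved. Under this rule g >= 2 whenever a trait is
explained; the original "explained by one group" phrasing (a single
distinguished cluster-set) has no precise written rule and is left to the
grouping string.

## Pipeline and reproducibility

`run_pipeline` executes filter -> associate -> candidates -> core sets ->
trees/clusters -> DMRT -> reference database, writing every artifact and a
manifest of stage counts; one global seed fans out to per-stage seeds by
stable hashing of stage names, so the same config and seed reproduce the
manifest exactly. The reference database is a wide TSV of two-letter
genotypes (`NN` missing) with a round-trip reader, plus IUPAC-coded FASTA
(het = ambiguity code, missing = N).

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the package's
own study conditions: a GBS-scale funnel of 96 varieties x 3000 markers
with 19 traits (the real screen held ~58k markers; 3000 preserves >200
markers per trait for top-200 pooling), an assay-scale identification panel
of 94 varieties x 400 near-complete markers with nested sets 87/24/10,
100 small instances for exhaustive set-cover comparison, 50 random additive
metrics for NJ, 1000 null permutations for ANOVA calibration, 100 bootstrap
replicates in the funnel run, and 10 seeds x 3 traits x 2000 markers for
causal-recovery measurement.

## Known limitations

Markers are simulated without linkage, so LD-decay estimates on synthetic
panels reflect only sampling noise; the clustering surrogate does not
estimate admixture proportions, only medoid-relative similarity; candidate
selection quality degrades gracefully but visibly when very few markers are
available per trait; and exact minimal covers are only verified at
enumeration scale — at panel scale the greedy carries its ln-factor
guarantee, not optimality.
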