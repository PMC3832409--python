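# Methods

## RRL design model

The design calculator treats restriction-fragment lengths as i.i.d.
exponential with mean `d` (the Poisson-process approximation to random
cutting of a long genome), so a genome of size `G` yields `G/d` fragments of
which `(G/d)(e^{-a/d} - e^{-b/d})` fall in a size-selection window `[a, b]`.
Defaults: `d = 3100` bp (the mammalian BglII figure), `G = 2.4` Gbp,
window 100–700 bp, 2×100 bp paired-end reads. Window bounds are treated as
inclusive — a gel excision "between 100 and 700 bp" retains the endpoints —
and are configurable.

In-silico digestion matches the recognition pattern exactly and
case-insensitively; windows containing ambiguity characters (N) never
match, the conservative choice for draft assemblies. Cuts fall at
`occurrence_start + cut_offset` (offset 1 for BglII, A^GATCT). Terminal
scaffold fragments are included: the realized counts come from a scaffolded
draft in which every scaffold end truncates a fragment, and dropping them
would bias short-scaffold assemblies. Coordinates are 0-based half-open
everywhere, including serialized BED output.

Per-individual read depth is `Y / (2 L D)` for yield `Y`. The default
`Y = 1.0` Gbp corresponds to one 2×100 bp HiSeq lane split across ten
samples and reproduces both published depths (38× predicted, 53× realized)
after integer rounding; it is a configurable reconstruction, since lane
yield is rarely reported. Percent differences are taken relative to the
*estimated* value (`(est − act)/est`), the convention consistent with the
published genome-size, fragment-count, fragment-size and coverage cells;
the published depth cell uses the opposite denominator and is deliberately
not reproduced.

## Filter cascade

The cascade runs: single-SNP → central position → individuals/classes →
unique alignment → scaffold uniqueness → homopolymer. The first three use
only the stack records and are order-independent (tested by permutation);
they are applied sequentially for bookkeeping. Flank thresholds are strict
counts of bases 5′/3′ of the SNP (admissible 0-based positions 20..64 on a
100-nt read). The alignment screen accepts exactly one hit with identity
≥ 99% and zero gap opens, reading the identity field as reported rather
than recomputing it from mismatches (a blast-tabular dialect choice).
Scaffold uniqueness drops *all* SNPs on any scaffold carrying two or more
survivors, since either member of such a pair may be in physical linkage.

Two originally manual criteria are automated with configurable rules: the
homopolymer screen fails a record if either flank contains a
single-nucleotide run longer than 5 within 20 nt of the SNP, and "adequate
allelic representation" is subsumed by the all-three-genotype-classes rule.

## Locus statistics

Allele frequencies pool diploid (two alleles per call) and haploid (one)
contributions; observed heterozygosity and the Hardy–Weinberg test use
diploid calls only, and missing calls are excluded locus-wise
(complete-case per locus). The HWE test is the exact conditional test:
given the allele counts, the p-value sums the probabilities of all
heterozygote configurations no more probable than the observed one,
computed in log-gamma space (an exact-rational enumeration serves as the
test oracle). No multiple-testing correction is applied.

D′ uses EM over the four haplotype frequencies from unphased two-locus
genotypes, initialised at linkage equilibrium; only the double heterozygote
is phase-ambiguous. Convergence: max absolute change < 1e-9 or 1000
iterations. `D = p_AB − p_A p_B` is normalised by
`min(p_A(1−p_B), (1−p_A)p_B)` when positive, `min(p_A p_B, (1−p_A)(1−p_B))`
otherwise; monomorphic loci raise rather than returning 0.

X-linkage detection flags polymorphic loci at which every called male is
homozygous (or hemizygous) for one shared allele while at least one female
is heterozygous, attaching the Type-I-error probability
`(maf² + (1−maf)²)^{n_males}` — the Hardy–Weinberg chance that all males
are homozygous at an autosomal locus. Note the detection signature (shared
allele) is stricter than the event the probability bounds (each male
homozygous for either allele), so the quoted error probability is
conservative in the direction that matters.

Panel selection is by MAF rank around an unconditionally included reserved
set (e.g. four mtDNA + two Y markers), with ties broken by expected
heterozygosity then locus id; the original visual criterion of "clear
cluster divergence" on the genotyping instrument is not computable from
genotypes and is intentionally not modelled.

## Relatedness

The Lynch–Ritland estimator is combined across loci as a ratio of sums
(`Σ N_l / Σ D_l`), which reproduces the source estimator's
denominator-proportional locus weighting and removes the singularity of a
heterozygous reference individual at `p = 0.5`; the estimate is symmetrized
over the two reference choices. Allele frequencies for estimation are taken
from the full sample including the dyad (typical practice; a leave-two-out
frequency set can be supplied instead). Monomorphic loci and loci with a
missing call in either individual are dropped per dyad.

Confidence intervals are percentile bootstrap over loci (1000 replicates,
seeded); simulation shows ~95% coverage of r = 0.5 for parent–offspring
dyads at 87 loci. Candidate first-order dyads are screened at r > 0.40.
Autosomal exclusion requires an opposite-homozygote locus; X exclusion
applies the inheritance rules (son's X maternal; daughter carries the
paternal X; mother–daughter must share an allele; father–son unconstrained)
and, because a dyad is unordered, excludes only when *neither* ordering of
parent and offspring is compatible. Missing calls never exclude, and no
genotyping-error tolerance is modelled: a single erroneous opposite
homozygote will exclude a true dyad, which is the published procedure's
behaviour too.

## Synthetic data

The generators define the test conditions:

* **Genome**: recognition sites are planted at exponential spacings (mean
  3100 bp by default) on a uniform-ACGT background from which accidental
  pattern occurrences are scrubbed by regeneration. Planting sites as a
  Poisson process — rather than relying on the background composition —
  makes the fragment-length distribution exactly exponential, so the
  design-model calibration test is sharp. Default 1 Mbp; real draft
  assemblies differ in GC structure, repeats and gaps, none of which are
  modelled.
* **Pedigree panel**: founder genotypes under Hardy–Weinberg proportions at
  per-locus MAFs drawn uniformly (default [0.2, 0.5]; the relatedness
  recovery experiments use [0.28, 0.5], mean 0.39, matching the validated
  panel's mean MAF); offspring by Mendelian transmission; 87 autosomal,
  3 X, 4 mtDNA and 2 Y markers by default, mirroring the chip layout.
  X loci are hemizygous in males, mitochondrial haplotypes (one of the
  three recognized lineages) follow the maternal line, Y markers are
  present in males only. No linkage, population structure, allele dropout
  or genotyping error is simulated, so passing tests demonstrate
  correctness of the estimators under their own assumptions, not robustness
  to real-data artefacts.
* **Stack fixtures**: records are generated in labelled strata, each
  violating exactly one filter criterion (multi-SNP, off-window position,
  too few individuals or a missing genotype class, low-identity / gapped /
  multi-mapped / absent alignments, shared scaffolds in pairs, planted
  6-base homopolymer runs), with background consensus constrained to runs
  ≤ 3 so no stratum fails a second criterion. This gives exact
  planted-truth recovery checks; the published intermediate counts depend
  on the unavailable raw sequencing data and are not reproducible by
  construction.

All generators are deterministic given the configured seed.

## Problem sizes and numerical choices

Simulation-based checks use: 500 dyads for mean-r recovery, 10,000 for
exclusion soundness, 500 bootstrap-coverage trials of 1000 replicates each,
20 seeded 1-Mbp genomes for digest-model calibration, 2000 loci at n = 50
for HWE p-value uniformity, and 10⁶ Monte-Carlo replicates for the
Type-I-error cross-check — sizes chosen to keep each statistical assertion
inside 3 standard errors of its target while the whole suite runs in well
under a minute. Probability comparisons in the HWE test use a relative
tie tolerance of 1e-12 to keep the "no more probable" sum stable against
floating-point noise.

## Known limitations

* The filter cascade consumes alignment *hits*; it does not compute
  alignments, assemble stacks, or process reads.
* Relatedness assumes unlinked, biallelic autosomal loci with known
  (sample-estimated) allele frequencies; no likelihood-based parentage
  assignment or sibship reconstruction is provided.
* Exclusion logic has no error model: it is exact-match Mendelian logic.
* The X Type-I-error formula assumes Hardy–Weinberg proportions and
  independence across males.
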