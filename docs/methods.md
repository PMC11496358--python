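# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## The synthetic population model

The simulator exists to give every downstream stage inputs with the
statistical structure the analyses assume, not to be a coalescent or
read-level simulator.

**Genes and alleles.** Each gene is a `GeneRegion` (0-based half-open
exons; VCF positions are 1-based). Its ancestral exonic sequence is built
from uniformly drawn sense codons, so open reading frames are respected
and synonymous/non-synonymous status of simulated SNPs emerges from the
genetic code rather than being assigned. Segregating sites are placed
Poisson(per-bp density × length); each derived allele carries the
alternate base at each site independently with probability 0.35. The
default panel holds eight MHC-like genes (four with copy-number
variation, including one deletion-prone gene) and eight single-copy TLR
reference genes of 2,250 bp — eight because the copy-number estimator
averages reference RPK over eight genes.

**Regional structure.** Allele frequencies per region are
softmax-transformed log-abundances: a shared per-allele baseline
N(0, 1.5) plus, when `distance_decay=True`, a per-allele cline term
N(0, 6d) scaled linearly along the sampling transect, plus regional noise
N(0, 0.75d), where d = `differentiation` ∈ [0, 1). d = 0 makes every
region identical (F_ST = 0); F_ST grows monotonically with d (rank
correlation ≈ 0.99 over ten levels in the test suite), and the cline
yields genuine isolation by distance. An earlier Dirichlet random-walk
design was discarded because a random walk wanders rather than
diverges, capping the Mantel correlation well below the strong
isolation-by-distance regime the survey analyses target. With
`distance_decay=False` regional deviations are i.i.d. N(0, 3d): structure
without geography. The default d = 0.15 produces pairwise F_ST in the
0.03–0.15 range typical of structured wild populations; 0.3 is used where
a strong cline is the point of the experiment.

**Copy number.** Each CNV-prone gene draws an allelic copy number 0–6 per
individual from its configured distribution; reference genes are pinned
at 2. Individuals carry `copies` haplotypes drawn from their region's
allele frequencies. Diploid genotypes at SNP sites come from two of those
haplotypes (hemizygotes are homozygous for their single haplotype; zero
copies means no calls) — the view a diploid genotyper has of a duplicated
locus. Genotypes of >2-copy individuals therefore under-represent their
allele content, as in the real pipeline.

**Coverage.** `read_count ~ Poisson(depth × (copies/2) × L / read_length)`
per gene × individual; read length defaults to 150 bp (short-read
paired-end chemistry). This makes E[ACN] equal the true copy number and
reproduces the depth-dependence of CNV detectability: complete deletions
are visible even at 1×, hemizygotes need roughly ≥10×.

**Genotype calls.** Per-site per-individual depth is
Poisson(depth × copies/2). A site needs ≥ `min_reads_to_call` (default 2)
reads to be callable. A true heterozygote is called heterozygous iff both
alleles were read, so its miscall probability is exactly 2 × 0.5^depth. A
true homozygote flips to heterozygous only when errant reads (per-read
error, default 0.005) occur at least twice *and* reach 20% of reads; the
fraction floor is essential — without it hom→het errors scale like
depth × error and would make concordance *fall* with depth, the opposite
of the depth-reliability behaviour the whole design rests on. Sites where
no individual receives a called ALT allele are "not discovered" and drop
from the call set, which is why low-depth call sets contain fewer sites.
Site annotations are drawn so that ~5% of sites (configurable) fail one
of QUAL/MQ/MQRankSum/ReadPosRankSum, giving the filter cascade real work.

**Phasing artifacts.** `haplotype_sets()` injects an 'N' into both
haplotypes of a configurable fraction (default 5%) of gene × individual
pairs, emulating statistical-phasing failures; these sequences are
flagged unresolved and excluded before allele assignment, so per-gene N
varies the way it does in real phased surveys.

**Not emulated:** linkage disequilibrium, recombination, read-level
errors and mapping ambiguity between paralogs, indels, and
caller-specific genotype likelihoods. Passing tests therefore show the
*analysis stages* are correct and well-calibrated under their stated
assumptions, not that any particular caller behaves well on real MHC
reads.

## Filter semantics

All comparisons are strict: QUAL exactly 80, MQ exactly 40, mean depth
exactly at threshold and allelic-balance difference exactly 0.9 all pass.
The depth rule is t = min(target/3, 10) — "capped at 10" is the reading
under which the rule's worked example (15× target → threshold 5) extends
smoothly to higher targets. Allelic balance is computed per site as the
mean over heterozygous genotypes of |ref−alt|/(ref+alt); sites without
heterozygotes pass vacuously. An alternative band interpretation (mean
heterozygote ALT fraction within [0.05, 0.95]) is available via
`mode="band"`. Each stage is a pure site predicate, so the cascade is
order-stable and idempotent (property-tested).

## Concordance grid

The letter grid is row-major with rows = WGS state and columns =
enrichment state, both ordered (HOM_REF, HET, HOM_ALT, MISSING). This is
the unique row-major layout in which the four published ratio formulas
are simultaneously consistent: the diagonal is A, F, K, P; the
WGS-missing row is M, N, O; the enrichment-missing column is D, H, L. The
grid is overridable by passing an explicit 16-entry mapping. Both-missing
pairs (P) count toward concordance, as printed; `strict=True` excludes
them.

## Copy-number classification

Bins are closed-left/open-right at n ± 0.5 and clamp at 6, except that
the printed single-copy band [1.5, 2.5] is closed at both ends, so ACN
exactly 2.5 resolves to single-copy. Reference aggregation is the mean
RPK (a median option exists for robustness). Both the integer class and
the raw ACN are reported, since raw values are what a violin plot of
depth ratios shows.

## Diversity statistics

π is the mean over unordered sequence pairs of per-site differences —
algebraically the n/(n−1)-corrected form of 1−Σp² per site; h is Nei's
n/(n−1)(1−Σp²). Both are validated to 1e-12 against enumeration oracles.
SNP effect classification translates the codon containing the site (with
strand and codon-phase handling); sites in partial codons are
"indeterminate" and never counted as non-synonymous. F_ST uses the 1984
variance components with the ratio-of-sums ("mean weighted") estimator;
monomorphic sites contribute zero components and are excluded from the
sums. Sample sizes, allele frequencies and heterozygote fractions are
computed per region from called genotypes only, so missingness shrinks
n_i rather than biasing p_i.

The published 24-gene koala diversity table ships as package data
(`data/koala_mhc_diversity.tsv`) and is used as a worked aggregate input;
its allele and non-synonymous totals are asserted in the acceptance
suite. (Its SNP column is known to sum to one less than the survey's
stated SNP total; no test asserts the SNP sum.)

## Structure

Encodings are individuals × features (SNP dosage 0/1/2, allele counts, or
supertype counts); missing entries are mean-imputed. The distance is
Euclidean by default (allele-sharing available). PCoA double-centers
B = −½ J D² J, eigendecomposes, retains positive eigenvalues and fixes
signs so each axis's first non-zero loading is positive; on Euclidean
distances of a feature matrix it reproduces PCA scores to 1e-8
(tested, including against scikit-bio). The Mantel test is one-sided
(greater) with the add-one permutation p-value. Isolation by distance is
tested at the population level — region-mean dosage distances against
great-circle distances between region centroids — because pair distances
between individuals are dominated by within-region sampling noise, which
bounds the individual-level Mantel r far below the strong correlations a
regional cline produces.

## Supertypes

The Sandberg et al. (1998) 20×5 z-descriptor table is embedded as
versioned package data. Peptide-binding-region positions are user input;
the pipeline default is a fixed, evenly spaced position list over the
class I protein. BIC is fixed as n·ln(WSS/n) + k·ln(n) with k-means++
restarts (best WSS kept), and k is the modal argmin across replicate
runs; defaults mirror the procedure's published settings (n_pca = 30,
max_k = 30, 500 starts, 1000 replicates), while tests and the acceptance
script run reduced sizes (5–20 replicates, 10–20 starts, max_k ≤ 15) that
leave the selection behaviour unchanged at a fraction of the cost.

Two numerical realities are worth recording. First, k cannot exceed the
number of distinct z-profiles: alleles identical at every PBR position
collapse to one point, and k-means is capped accordingly (an exactly
coincident allele pool gives k = 1). Second, for a genuine Gaussian
cloud this BIC sits within a fraction of a penalty unit of preferring
k+1: the WSS gain from optimally bipartitioning a small cluster of
points is scale-invariant and comparable to ln(n)/n, so single-draw k
selection can overshoot by one even on well-separated data (and on
unstructured data the minimum lands at 2–3 rather than 1). Recovery
checks therefore score the modal selected k over several independent
allele pools — the same majority logic the replicate-BIC procedure
applies within one dataset — with cluster sizes (~25 alleles per
centroid in 15 dimensions) at which the criterion is solidly
identifiable. DAPC retains all k−1 discriminant functions; when
within-class scatter is exactly singular (clusters of identical points) a
deterministic sub-resolution jitter (1e-8 of the data scale) regularizes
the LDA without moving any boundary. The a-score is the observed mean
per-cluster reassignment rate minus its mean under random label
permutations; its ceiling for k balanced clusters is 1 − 1/k.

## Pipeline and reproducibility

Every random stage takes an explicit seed; rerunning a pipeline entry
point with the same config and seed reproduces byte-identical tabular
outputs, and the run manifest records the config hash, seed, package
version and per-stage row counts. The depth-comparison entry point runs
ten individuals over the 0.5–30× ladder (the paired-design size); the
survey entry point defaults to 7 regions × 30 individuals and scales
down cleanly. Outputs are tidy long-format TSV/JSON intended for direct
plotting.

## Known limitations

- The genotype-caller emulation is a two-parameter toy; absolute
  concordance values are not calibrated to any specific caller, only the
  depth-dependence shape is.
- Copy-number estimation assumes reads map uniquely to the correct
  paralog; mismapping between highly similar genes would bias ACN and is
  not modelled.
- Genotypes of individuals with more than two gene copies are reduced to
  a diploid view; allele-frequency estimates at duplicated genes inherit
  that censoring.
- The supertype k-selection criterion is intrinsically marginal at small
  allele counts (see above); headline k values on small pools should be
  read with the BIC trace, not alone.
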