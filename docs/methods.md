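# Methods

This note documents the models behind jamkit, the parameters that matter,
and the choices made where the design was genuinely open.  Nothing here
states a number the test suite or `scripts/acceptance.py` does not itself
compute.

## Cross and read simulator

The simulator reproduces the calibration design used throughout the test
suite: four haploid genomes from a neutral Wright–Fisher coalescent,
paired into a mother (chromosomes a, b) and a father (c, d), offspring
formed by recombinant gametes, and Illumina-like paired-end reads.

**Coalescent.**  The chromosome is cut into blocks and an independent
Kingman tree (n = 4) is drawn per block — an SMC-like approximation, not
a full ancestral recombination graph.  Block lengths are exponential with
rate (ρ/2)·E[L], where E[L] = 2(1 + ½ + ⅓) is the *expected* total tree
length.  Using the realized tree length instead would length-bias genome
coverage toward short trees and depress the segregating-site density by
roughly a third; with the expected length the marginal tree at any
position is an unbiased Kingman draw, and the realized density matches
the Watterson expectation θ·(1 + ½ + ⅓) (checked against msprime as an
independent oracle).  Linkage *between* nearby trees is weaker than in a
true ARG; nothing downstream consumes it.  Mutations fall as a Poisson
process on branches (rate θ/2 per site per unit branch length).  In the
default finite-sites mode mutations land on discrete positions with reuse
allowed — recurrent hits can create tri-allelic sites, which are recorded
and flagged (the pipeline only tracks bi-allelic SNPs).  An infinite-sites
mode forces every mutation onto a fresh position.  At the study-scale
density of ~7.6 SNPs/kb, recurrent hits touch under 1% of sites, so the
finite-sites singleton fraction is indistinguishable from the
infinite-sites analytic value (1 + ⅓)/(1 + ½ + ⅓) = 8/11 ≈ 72.7%; the
simulation reports ~72–73%.

**Cross.**  Each offspring receives one recombinant maternal and one
paternal gamete; crossover counts are Poisson with mean rate·length,
breakpoints uniform.  Default sex-specific rates are 1.28 (maternal) and
0.76 (paternal) cM/Mb.  Tests that need chromosome-scale *genetic*
lengths on desk-scale *physical* lengths raise the cM/Mb rates so a
150 kb chromosome carries tens of cM — the mapping stages only see
segregation patterns, which depend on crossovers per chromosome, not bp.

**Reads.**  Fragments are uniform over haplotypes and positions with
insert ~ N(300, 30²) bp and 100 bp mates (read 2 reverse-complemented).
Qualities are two-tier: an exponential low-quality (Q15) run at the 3'
end of each read with mean length `low_q_fraction`·read_len (default 5%),
Q35 elsewhere.  Substitution errors average `error_rate` (default 0.002)
and are concentrated on the low tier in proportion to the tier error
probabilities, so q20 masking removes most of them — mimicking real
end-of-read decay.  Scattering low-quality bases uniformly would destroy
most 23-base windows and is deliberately avoided.  Indels, structural
variation and platform-specific error profiles are out of scope.

## k-mer profiling

Bases below Phred 20 are masked to N, below 30 lowercased; a read
qualifies when it retains ≥ k consecutive unmasked bases.  Soft-masked
bases still count toward k-mers — the counted set is the q20+ k-mers —
and the lowercase annotation is retained only for display.  k must be odd
(≤ 31) so canonicalization (numeric min of the 2-bit code and its reverse
complement, A=0 C=1 G=2 T=3, most-significant first) never ties.  Hash
slicing keeps k-mers whose code ≡ s (mod S) for a prime S; slices
partition the table exactly.  The artifact filter requires ≥ 3 total
copies with ≥ 1 in every sequencing-run group (incomplete adapters differ
between runs); with a single run group the run rule is inert.

The frequency spectrum is fit on frequencies 3–70 by non-negative least
squares over four Poisson components with means locked at d, 3d/4, d/2,
d/4, with d optimized by a bounded search seeded from the spectrum mode.
The constraint that the fitted curve not exceed the observed counts is
applied afterwards as a uniform amplitude scale (class *fractions* are
scale-invariant, so depth and heterozygosity estimates are unaffected);
where the observed count is zero the model is held below one count, the
observable resolution.  Frequencies above the fit range are reported as
an unmodeled repeat tail.  Locus accounting: a homozygous locus
contributes one k-mer at d, a major–minor locus one each at 3d/4 and d/4,
a tied locus two at d/2; the SNP base fraction is the bi-allelic locus
share divided by k.

## SNPmers and node selection

All 3k one-substitution variants of every filtered k-mer are looked up in
canonical space.  Exactly one neighbor, whose only neighbor is the
original: a *partnered* SNPmer pair (substitution position, change class
— transition / complementary / non-complementary transversion — and
relative orientation recorded).  No neighbor: *unique*.  Anything else:
*ambiguous*.  A k-mer one substitution from its own reverse complement
would pair with itself; such self-pairs are classed ambiguous.  Node
selection keeps SNPmer pairs with the substitution at positions
{3, 12, 21} for k = 23 — the set must be closed under p ↦ k+1−p so the
choice is orientation-independent, and avoids the error-enriched window
ends — and unique k-mers in one hash slice modulo 11, the smallest
non-Mersenne prime above 23/3 (remainders modulo Mersenne primes mix
poorly for base-4 codes).

## Assembly

Consecutive node hits within a read create edges carrying orientation,
start-to-start distance and support; observing the same node pair at a
different distance or orientation poisons all edges at the involved node
ends.  An edge is robust at an end when its support is ≥ 2 plus the sum
of competing supports and ≥ 2× the runner-up; contigs are chains of
mutually robust edges (cycles and singletons reported, excluded).  Read
pairs whose two mates land best in different contigs (ties discarded;
span rule applied in the inclusive convention under which any hit
qualifies) become template links; links are grouped per contig pair with
majority orientation (exact tie drops the pair) and applied greedily in
decreasing support order when both facing ends are free — a deliberately
simple scaffolder sharing the contract of a full one (consistent order
and orientation chains), with `min_links` = 2.

`max_span` (pipeline default 4 kb) caps scaffold growth.  On clean
simulated data the greedy chainer happily scaffolds a whole test
chromosome into one marker, which breaks the genotyper's assumption that
no recombination occurs within a marker and starves the map of loci; real
data keeps scaffolds short through noise and repeats, the cap plays that
role here and matches the few-kb marker scale of a typical run.

Consensus emits node tag sequences in order; at SNPmer nodes the
better-supported allele wins (ties produce IUPAC codes).  Gaps between
nodes joined by an edge are patched from the edge's witness read (they
are always spanned, being consecutive hits in one read); inter-contig
scaffold gaps remain N-runs with the mean template-implied length,
floor 1.

## Genotyping

With parental chromosomes a,b / c,d, each SNP site has 2⁴ − 2 = 14
bi-allelic phases and each offspring one of four genotypes per marker.
Site likelihoods given a phase and genotype are binomial for homozygous
states, ε being the base-calling error rate (default 0.01, a typical Illumina
post-filter rate; parent-homozygous sites can estimate it from data).
For heterozygous states the trinomial with per-allele-read probability
(1 − 2ε/3)/2 is used.  The unnormalized form of that trinomial (without the
½ per allele read) is preserved verbatim in `site_likelihood` for
reference, but cannot drive inference: without the ½ the heterozygous
state outscores every homozygous state on any data (e.g. 30 reads of one
base: 0.82 vs 0.74), and the EM collapses to all-heterozygous phases —
the normalized form is the one under which the method works.

The incremental EM starts from the parents (pseudo-states (a,b), (c,d))
plus one random offspring fixed at (a,c), recomputes phase posteriors,
admits one random sample per iteration, then re-chooses every included
offspring's genotype to maximize the expected log likelihood; convergence
when the objective improves < 10⁻⁶ (cap 100 sweeps — plumbing, never hit
in practice).  Five restarts with seeds derived from the run seed; since
swapping a↔b or c↔d relabels solutions without changing the likelihood,
restart agreement is judged on the genotype vector canonicalized over the
four relabelings, and a marker is high-confidence when ≥ 3 of 5 restarts
agree.  Per-call confidence is the expected-log-likelihood gap between
the best and second-best genotype.

**Error model.**  p(e|s) = a₁·exp(−(s/c₁)^b₁) + a₂·exp(−(s/c₂)^b₂),
clipped to [0,1]; a reference parameter set (a₁=0.49, b₁=2.08, c₁=1.26,
a₂=5.47, b₂=0.17, c₂=0.16) ships as the default, and the alternative
parameterization a·exp(−s^b/c) is available as `form="rate"`.  Calibration bins truth-scored calls by confidence
(default 10,000 calls per bin; scaled-down runs use proportionally
smaller bins), fits by minimum χ² weighted with the Beta(nₑ+1, n_c−nₑ+1)
posterior sd, and reports per-bin 95% Beta intervals (one-sided for
all-correct or all-wrong bins, where a central interval would exclude a
perfectly consistent model) plus the reduced χ².  The cost surface is
multi-modal when the low- and high-confidence regimes separate sharply,
so the fit multi-starts from the reference defaults and data-driven
seeds.  Calibration uses the calls the model is meant for — those of
high-confidence markers; positive parameters make the curve monotone
non-increasing by construction.

## Linkage map

Markers qualify for map construction with ≥ 18 SNPs (12–17 for post-hoc
placement, both configurable).  Patterns are compared up to the four
parental relabelings everywhere: two markers genotyped independently land
in arbitrary gauges.  A unique pattern becomes a map bin when ≥ 3 markers
carry it or one carrier has ≥ 20 SNPs with mean phase posterior > 0.9;
patterns with < 80% of offspring called are dropped.  The linkage
p-value counts *two* calls per offspring (one per parent), n = 68 for 34
offspring; missing calls are dropped pairwise.  Single-linkage clustering
at p₁ forms groups; bins that are articulation points of the p₂-graph
(p₂ > p₁) within a p₁-component are removed.  The protocol does not pin
the (p₁, p₂) values; the defaults here are
(10⁻¹⁰, 10⁻⁶), (10⁻¹², 10⁻⁸), (10⁻¹⁴, 10⁻¹⁰) — stringent enough that
chance linkage at n = 68 (floor 2⁻⁶⁸) never merges groups, configurable.

Within a group, labels are harmonized along the minimum spanning tree of
the p-value graph (each bin relabeled to maximize agreement across the
traversed edge; the result is gauge-fixed by the root).  Ordering is
average-linkage hierarchical clustering on cosine distances between rows
of the recombination-fraction matrix, followed by the deterministic
subtree rotations toward the root-adjacent side and an in-order
traversal.  The three manual segment reversals of the original protocol
are not automated; an explicit reversal list can be applied by the
caller.  Anchoring assigns a marker to its argmin-p bin when p < 10⁻⁶.

Local recombination rate regresses cumulative Haldane distance on
cumulative physical position over ±10 bins, using the bin marker count as
the physical proxy (scaled by a configurable bp-per-marker).  Watterson's
Θ divides the segregating-site density by Σ 1/i; with the finite-sites
flag (default on) the density is first corrected for unseen recurrent
hits via the Poisson relation, density_true = −ln(1 − observed) — for
0.76% over four haplotypes this yields 0.0042 where the uncorrected value
rounds to 0.0041.  Segregation distortion is a two-sided exact binomial
test per parent, Bonferroni ×2.

## Comparative layer

RBH orthology takes mutual best-scoring hits above an e-value threshold
(default 10⁻⁵; the source text leaves it blank), ties broken
deterministically.  ALG enrichment tests each (map bin of 1,000 markers)
× ALG 2×2 table with one-sided Fisher's exact, Bonferroni over
bins × ALGs.  Paralog pairs are mapped markers sharing a best-hit
out-group gene (genes with > 5 best-hit markers excluded); same-group
pairs are "tandem".  Max-gap clustering chains inter-chromosomal pairs
transitively when both footprints stay within `max_gap` markers
(footprint distances in marker index, endpoints inclusive); a cluster
needs `mp` pairs seeded by *distinct* out-group genes.  Permutation nulls
shuffle gene identities over the mapped markers — preserving per-gene
marker counts and the marker universe — optionally excluding genes with
tandem duplicates; empirical p-values use the add-one convention.  The
paralogon graph (nodes: merged non-redundant footprints; edges: clusters)
is summarized by its average clustering coefficient against Erdős–Rényi
graphs with the same node count and edge probability.  Ks mixtures fit
plain (untruncated) Gaussians by EM on values in [0, 2.5], the standard
practice in Ks-based duplication dating; BIC = −2 lnL + k ln N with k = 3c − 1
selects the component count.  EM runs with 10 initializations and a tight
tolerance (10⁻⁶ per-observation) — the default loose tolerance of common
implementations visibly biases overlapping-component means.  Ks and Ka
values are inputs; their estimation from alignments is out of scope.

## Problem sizes in the test suite

The real study's inputs (billions of reads, a 2.7 Gbp genome) are not
reproducible at desk scale, so the suite runs the same machinery on
scaled-down synthetic designs chosen once: 30–150 kb chromosomes at the
calibration rates (θ = 0.012, ρ = 0.0085), parents at 20X, offspring at
5X, 34 offspring and 3 chromosomes for the end-to-end cross (with cM/Mb
raised to give tens of cM per chromosome), 20 replicates of 1 Mb for the
coalescent singleton check, and 50 random ≤3-SNP/≤5-offspring markers for
the EM-vs-exhaustive comparison.  Passing these shows the algorithms are
implemented correctly and recover known truth in the regime they model;
it does not exercise repeat-rich sequence, platform-specific artifacts,
indel polymorphism or memory-scale engineering, which real data would
add.

## Known limitations

- The SMC-like coalescent underestimates linkage disequilibrium between
  distant blocks; fine-scale LD analyses should not rely on it.
- The scaffolder is greedy and span-capped; it trades contiguity for
  marker validity and makes no attempt at repeat resolution or long-range
  gap sizing.
- Genotype confidence is calibrated per run; the stored reference error
  curve is a default, not a substitute for calibration.
- The k-mer table is an in-memory numpy structure, adequate for tens of
  megabases per run; counting a multi-gigabase genome needs the hash
  slicing workflow run slice by slice.
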