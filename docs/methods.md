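# Methods

This note documents the models, default parameters and numerical choices
behind `gbsphylo`, and what the synthetic-data tests do and do not show
about real GBS data.

## Tag-level discovery

**De novo route.** Reads are demultiplexed by longest-prefix barcode
match (the key must be prefix-free, which is validated), trimmed to a
fixed tag length (default 64 bp — the standard GBS tag size), and
collapsed into tags carrying per-sample read counts. Candidate SNPs are
unordered tag pairs at Hamming distance exactly 1, found by neighbourhood
hashing (L buckets, each keyed by the sequence with one position masked);
two equal-length tags collide in exactly one bucket iff they differ at
exactly one position, so the method provably equals the all-pairs scan,
and the test suite asserts that equality on random instances.

The network error filter drops a pair when the rarer tag's share of the
pair's reads, min(a,b)/(a+b), falls below the error-tolerance rate
(default 0.03) — such a tag is better explained as a recurrent sequencing
error of its partner — and, unless `allow_complex` is set, removes every
pair of any tag that participates in more than one surviving pair, so
only reciprocal 1-to-1 tag networks remain. The 0.03 default and the
reciprocal-only rule are this package's concrete, testable rendering of
network-based error curation; both are parameters.

**Reference route.** Tags are placed by ungapped search on both strands
with at most 3 mismatches (pigeonhole seed index: a tag within k
mismatches must match exactly in one of k+1 chunks). A tag is kept iff a
single placement achieves its minimal mismatch count; ties, including a
palindromic tag matching the same locus on both strands, count as
multimapping and discard the tag. Candidate sites come from the pileup of
placed tags: positions where tag bases and the reference base form
exactly two alleles; positions showing three or more alleles are
discarded and counted. Gapped alignment, indels and restriction-site
chemistry are out of scope.

Tags present in only one sample are retained at this stage; missingness
is a property of the SNP matrix and is filtered there.

## Genotype likelihoods

Calls are made per sample and site from the two allele depths (a, b),
d = a + b, under a symmetric-error binomial model:

    L(AA) = C(d,b) · e^b (1−e)^a
    L(AB) = C(d,b) · 0.5^d
    L(BB) = C(d,b) · e^a (1−e)^b

with per-read error rate e (default 0.01). The genotype is the argmax
(dosage-coded 0/1/2); GQ is the Phred-scaled gap between the best and
second-best likelihood, capped at 99, and calls below `min_depth`
(default 1) are missing. Exact ties are broken toward the heterozygote,
then toward genotype 0, with GQ 0 — deterministic and conservative. The
model ignores base qualities and assumes a single shared error rate;
that is the cost of calling from tag count vectors rather than per-base
pileups. Likelihoods are computed in log10 space with `gammaln` for the
binomial coefficient, so large depths cannot overflow, and the argmax is
exactly symmetric under allele relabelling (asserted in tests).

## Filter suite

Each rule is an independent, idempotent, non-mutating transformation;
`apply_filters` composes them in an explicit, logged order. Boundary
semantics are fixed and unit-tested:

| rule            | default  | semantics                                        |
|-----------------|----------|--------------------------------------------------|
| sample_missing  | 0.90     | drop sample iff missing fraction **>** threshold |
| site_missing    | 0.50     | keep site iff missing fraction **≤** threshold   |
| maf             | 0.02     | keep site iff MAF **≥** threshold                |
| het             | 0.01     | keep iff observed het **≥** min (and ≤ optional max) |
| depth           | floor at mean | call set missing iff depth **<** floor / **>** ceiling |
| invariant       | on       | drop sites whose non-missing calls are one homozygote |
| linkage         | 128 bp   | greedy scan per contig; drop site iff **<** 128 bp from last kept |

The depth-floor threshold may be the dataset mean call depth, kept
real-valued rather than rounded. Masking calls can empty a site (it is
then dropped) and creates missingness that the missingness rules only see
if they run afterwards — filter order matters, so the order is an
explicit parameter, logged per run, with the default
`sample_missing, depth, site_missing, maf, het, invariant, linkage`
(depth before missingness). All-heterozygous sites are polymorphic and
survive the invariant filter. An optional `max_het` supports the
opposite reading of a heterozygosity filter (excess-het / paralog
removal).

Linkage pruning is greedy left-to-right (keep first, drop any site
strictly closer than the minimum to the last *kept* site), not a maximum
independent set: deterministic, standard thinning behaviour, and it
guarantees by construction that no two surviving sites on a contig are
closer than the minimum — there is no residue of linked pairs to remove
manually. Position ties prefer the site with fewer missing calls, then
the lower site id. Sites without genomic coordinates (de novo tag pairs)
pass through with a warning; `anchor_pairs` can place them on a reference
first when one is available.

## Sweeps

`sweep_filter` holds a base configuration fixed and varies one rule's
threshold over a grid, recording surviving SNP counts and optionally the
RF distance of each setting's NJ tree to the base-setting tree (the
computable version of "the tree did not change"). Default grids are MAF
0.01–0.06, missingness 0.1–0.9, linkage {0, 64, 128, 256}.
`depth_simulation` sweeps a depth floor and ceiling over integer offsets
around the mean and flags the plateau point — the first threshold whose
count change drops below 1 %. Sweeps never mutate the input matrix.
Counts are monotone non-increasing in each rule's stringency direction
when the swept rule alone changes (asserted on random matrices); a depth
sweep inside a chain with MAF/het rules can in principle be non-monotone,
because masking calls changes those per-site statistics in either
direction.

## Trees and concordance

Distances are allele-sharing: mean over sites non-missing in both
samples of |gᵢ − gⱼ|/2, so a heterozygote-homozygote pair contributes
0.5. Neighbour joining uses the standard Q criterion with deterministic
tie-breaking (lexicographically smallest label pair; an internal node
carries the smallest label among its leaves); negative branch lengths are
clamped to zero with the deficit logged. On additive matrices NJ is
exact — output path lengths reproduce the input to < 1e-9 — which the
suite asserts on random additive instances, and which makes the
error-free simulation a deterministic truth check. Bootstrap support is
the percentage of site-resampled replicate trees containing each
main-tree bipartition (default 500 replicates, seeded and reproducible).

Trees are unrooted throughout. Topologies are compared as sets of
non-trivial bipartitions (Robinson–Foulds); `Tree.collapsed(min_length)`
removes internal edges below a length threshold so that arbitrary
resolutions of effectively identical samples (zero-length edges) do not
count as topology. `concordance_suite` restricts named matrices to their
shared samples, builds bootstrapped trees, and reports pairwise RF,
normalised RF (rf / 2(n−3)), and shared clades supported at ≥ 80 % in
both trees. ML and coalescent engines are deliberately not
re-implemented; `export_alignment` writes the IUPAC-coded supermatrix
(PHYLIP/NEXUS/FASTA) for external tools, and NJ+bootstrap serves as the
built-in desk-scale engine — the concordance machinery is agnostic to
where the trees came from.

## Synthetic data

The generator emulates the data regime the toolkit targets: barcoded
64-bp tags from a known species tree, negative-binomial depth (default
mean 7, dispersion 1.5 — GBS-like skew; variance m + m²/k), optional
per-base sequencing error, optional whole-locus dropout, and optional
within-species heterozygosity. Loci are non-overlapping tag windows
spaced 200 bp apart on synthetic contigs (50 per contig), so linkage
pruning is exercisable; each locus carries exactly one biallelic SNP
placed on a tree branch with probability proportional to branch length,
and every sample of a derived species is homozygous derived
(species-fixed genotypes — no incomplete lineage sorting — so tree
recovery is exact and testable). A locus-level rate field would be
redundant under this design: invariant tags carry no signal and are
removed by the invariant-site filter anyway, so the generator simply
does not emit them. Yule trees drawn for `tree="random_yule"` have their
tips extended by the waiting time to the next speciation so no species
pair is genetically identical.

`inject_linked_pairs` appends pairs of loci a chosen distance apart on
fresh contigs and records which member of each pair a correct 128-bp
pruning must remove, giving the pruning rule a constructed ground truth.
Spacing must be at least the tag length (windows must not overlap) and
less than the background locus spacing (gap + tag length), else the
injection would be meaningless.

What the simulations do **not** model: restriction-enzyme site
distribution and allele dropout at cut-site polymorphisms, PCR
duplicates, base-quality variation, paralogy, and incomplete lineage
sorting. Passing tests therefore demonstrate algorithmic correctness and
the direction of filter effects, not calibrated performance on real
libraries.

## Problem sizes and numerical choices

The test suite runs the concordance check at 8 species × 3 samples, 500
loci, 20× depth — large enough that every branch of the balanced test
tree receives many loci (≈ 36 expected per edge) and bootstrap support
for true clades is exactly 100 %, small enough to run in seconds. For
that exactness check the depth dispersion is set high (effectively
Poisson, no zero-depth cells): with dropout, the within-species star
(identical samples) is resolved arbitrarily by NJ with near-zero edges,
and distance-to-truth comparisons stop being well-posed; robustness to
missingness is covered separately by the sweep and error-direction
tests, which keep the overdispersed default. Error-direction runs use
10 species × 4 samples so that a singleton allele (MAF 1/80) falls below
the 0.02 threshold. Branch lengths are serialised at 12 significant
digits, Newick round-trips preserve lengths to 1e-9; VCF declares GQ as
a Float (not the reserved Integer) so genotype qualities round-trip
exactly; internal coordinates are 0-based half-open with conversion at
the VCF boundary (de novo sites are written on per-pair contigs at
position 33, the centre of a 64-bp tag, marked `UNPOS`).

## Known limitations

Mapping is ungapped and indel-blind by design; candidate sites with more
than two observed alleles are discarded rather than modelled; the
genotype model has one global error rate; bootstrap is the only support
measure; and the unique-best-hit mapping rule discards tags tied across
repeats rather than rescuing them with mapping-quality models.
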