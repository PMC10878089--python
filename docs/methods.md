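# Methods notes

This note records the models, conventions and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates, genetic code, and I/O conventions

All intervals are 0-based half-open internally; GFF3 input/output converts
to and from 1-based inclusive coordinates at the boundary. The default
genetic code is NCBI translation table 4 (mold/protozoan mitochondrial):
only TAA and TAG terminate, TGA encodes tryptophan. This matches the stop
codon usage of linear ciliate mitogenomes; every translation entry point
takes a `table` argument for other systems. A CDS with an internal stop
translates with a warning rather than an error, because in this domain that
almost always flags an annotation needing review, not an unusable record.
Duplicate gene labels (e.g., a gene split into two fragments) are
disambiguated positionally as `name_a`, `name_b`.

For region accounting each base is attributed to exactly one class with the
priority telomere > central repeat > PCG > rRNA > tRNA > other, and
uncovered bases are intergenic. The priority rule exists so that class
lengths always partition the genome length — a property the tests rely on.
With `exclude_telomeres` the fraction denominator for non-telomeric classes
is the genome length minus telomeric bases, matching how protein-coding
fractions are conventionally reported for telomere-bearing assemblies.

## Rearrangement event model

Events are scored per reference gene against each compared genome, with
equal weight for loss, inversion and translocation (score 0–2 for a
retained gene, 1 for a lost one). The literature that popularized this
scoring states the weights but not the adjacency convention for
"translocation"; this package operationalizes it deterministically: a
retained gene is translocated when its immediate predecessor differs
between the two orders *after restricting both to their shared genes*, with
a start sentinel because these genomes are linear (no wraparound
adjacency). The restriction matters: without it every gene downstream of a
loss would be spuriously translocated. An alternative criterion — changed
positional index in the restricted orders — is available via
`translocation="position"` for sensitivity analysis; the two agree on
simple cases but diverge on compound shuffles, which is exactly why the
default is pinned and oracle-tested by exhaustive enumeration over all
signed permutations of small gene sets.

Genes private to the target genome are ignored (no insertion penalty), and
the RF denominator is 2N — the maximum score a retained gene can accumulate
over N genomes — which puts RF on a 0–100 scale and makes a
lost-everywhere gene score exactly 50.

## NG86 Ka/Ks

The estimator is Nei–Gojobori (1986) counting with a Jukes–Cantor
correction: per-codon synonymous site fractions are the share of the three
possible point changes at each position that preserve the amino acid
(changes into stop codons count as nonsynonymous, so sites sum to exactly 3
per codon — the convention also used by Biopython's implementation, against
which the package is cross-checked to 1e-9); difference counts average over
all mutational pathways between two codons, excluding pathways through
stops (falling back to all pathways in the rare case all are blocked);
pN and pS are corrected by d = −3/4 ln(1 − 4p/3). Codon columns with gaps,
ambiguity or stops are dropped. When p ≥ 0.75 the corrected value is
reported missing with a saturation flag. The ratio is missing when Ks = 0,
with one deliberate exception: when there is *no* nonsynonymous divergence
at all (pN = 0) but synonymous differences exist, the ratio is reported as
0 even if pS is saturated — zero divided by any positive divergence is
zero, and tiny strongly conserved fragments otherwise produce no usable
number.

NG86 assumes equal rates across change types; with a transition/transversion
bias it mildly underestimates high ω. The calibration in the acceptance
suite (κ = 2, t = 0.3 substitutions/codon, 500-codon genes, 100 replicates)
quantifies this: recovery of planted ω ∈ {0.1, 0.5, 1.0} is within 25%
relative error, with the largest bias at ω = 1. Sliding-window defaults
(30 codons, step 6) are package choices sized so a window holds enough
codons for the counts to be meaningful on mitochondrial gene lengths.

## Telomere and CR detection

There is no community-standard algorithm for calling mitogenome telomeres,
so the definition here is chosen to be exactly recoverable on constructed
fixtures: scan unit lengths p = 1…max_unit at a genome end and report the
*smallest* p for which the terminal sequence contains ≥ min_copies (default
5) consecutive tandem copies of the terminal p-mer, each copy within a 5%
per-copy Hamming mismatch tolerance. Smallest-p wins so the reported unit
is the primitive period. The search examines the terminal 25% of the
genome and expands to the full sequence if the repeat reaches the window
edge (telomeres of real linear ciliate mitogenomes can occupy >10% of the
molecule). Copy number counts full copies only; tolerance-based partial
extension would make exact recovery of planted fixtures dependent on the
flanking sequence.

Central repeats are maximal merged runs of sliding windows (100 bp, step
10) with AT ≥ 0.9465 — the lower bound observed for ciliate CR regions —
trimmed until the merged interval itself satisfies the threshold, minimum
length 100 bp, with telomere intervals excludable. ORF scanning is a
six-frame start-to-stop scan under table 4 (default minimum 75 nt,
open-ended ORFs at contig ends allowed), tested against an independent
exhaustive scan.

## Homology and trees

RBH orthogrouping aligns proteins (not nucleotides — extreme AT content
distorts nucleotide distances) globally under BLOSUM62 with affine gaps
(−11/−1), takes reciprocal best hits per genome pair with lexicographic
tie-breaking for determinism, and single-links the RBH edges. Core genes
are single-copy-in-all orthogroups. Codon alignments are protein-guided so
gaps are always whole codons; multi-taxon protein alignment delegates to
mafft when sequences differ in length (equal-length proteins are aligned
ungapped, which is exact for the generator's indel-free output). The tree
is neighbor-joining on p- or JC69 distances with pairwise deletion;
bootstrap resamples alignment columns under a fixed seed, so identical
seeds give identical supports. Maximum-likelihood inference and clock
dating are out of scope by design — the module exports relaxed PHYLIP and a
RAxML-style partition file for external tools, since dating depends on
external calibrations that cannot be validated desk-side.

## Synteny

Anchors are maximal exact matches obtained by merging overlapping k-mer
hits (default k = 15) along diagonals, in both orientations; for ~50 kb
genomes the expected number of chance 15-mer matches (≈ len²/4¹⁵) is ≪ 1,
so exact matching needs no significance machinery. Chaining joins
co-oriented anchors whose gaps on both genomes are ≤ 1 kbp; overlapping
candidate chains are resolved greedily by total anchor length, ties by
leftmost start. Block totals are measured on the first genome's
coordinates (an arbitrary but fixed convention; totals on the second genome
differ only through indels). Telomere/CR intervals should be masked before
anchoring, since tandem repeats generate dense spurious self-similarity.

## Population statistics

Input is an allele-depth matrix rather than BAM: read mapping and raw
variant calling are upstream concerns, and the statistical contract —
consensus, SNP, heteroplasmy, π, LD, IBS — is testable without reads.
Consensus takes the majority base per site (ties resolved to the reference,
then alphabetically; below min_depth the site is masked). Heteroplasmy
defaults (minor-allele fraction ≥ 0.05 at depth ≥ 50) are package defaults
chosen so that, at depth 200 with 0.5% sequencing error, a binomial
calculation puts both the miss rate for a 10% heteroplasmy and the
false-positive rate well below 1% — the acceptance suite verifies both
empirically. π is the mean over strain pairs of pairwise differences per
jointly covered site; r² is the haploid D²/(p_A p_a p_B p_b) on biallelic
fully-covered sites. The Mantel statistic is the Pearson correlation
between off-diagonal log(IBS) and log(km + 1) (natural log; +1 absorbs
zero distances between co-collected strains), with a joint row/column
permutation null (default 999 permutations, seeded). Raw p-values are
reported without multiple-testing correction: each of these is a single
pre-specified hypothesis.

## Synthetic data: what it emulates and what it does not

The generators define the test conditions. Gene-order evolution applies
single-gene losses, strand flips and relocations in random order
(block events exist in real genomes but single-gene moves are the unit the
scoring model counts). The codon simulator is M0: one ω per gene, uniform
sense-codon frequencies, κ-scaled transitions, no indels, stop codons
unreachable; children are sampled through the matrix exponential of the
rate matrix, with time in expected substitutions per codon. The population
simulator mutates strains independently from one reference (star genealogy,
making expected SNP counts analytic: E[SNPs] ≈ L(1 − (1 − θ)ⁿ)) or serially
("chain"), which shares mutations along lineages and produces non-trivial
linkage structure while still lacking recombination; depths are Poisson,
errors uniform across the three wrong bases; heteroplasmy is a binomial
mixture at specified (strain, site, fraction) triples; coordinates are
uniform over a latitude/longitude box spanning the sampling region of a
continental soil survey. Defaults (8 strains, depth 100×, error 0.5%,
θ = 0.01/site) sit in the range typical of deep short-read mitogenome
resequencing of protist isolates.

None of the generators emulates indels, rate heterogeneity along genes,
mapping artifacts, strand bias, or contamination — so green tests certify
the statistical machinery on clean signals, not robustness to those
real-data pathologies.

## Problem sizes

The test and acceptance workloads are sized for a laptop-class single CPU:
exhaustive event-model enumeration over 6-gene signed permutations with ≤ 2
losses (74,880 cases), 200 replicates for the RS-monotonicity and LD-null
checks, 100 replicates × 3 ω values for NG86 calibration on 500-codon
genes, and a 4,000-site single-strain matrix for heteroplasmy operating
characteristics. The full suite runs in well under a minute of compute for
any individual module and a few tens of seconds overall.

## Known limitations

- The translocation convention is one deterministic reading of
  equal-weight event scoring; published RF/RS values computed with other
  tools may differ in detail, which is why the positional alternative is
  kept behind a flag.
- NG86 is a counting method; for strong transition bias or high divergence
  a likelihood codon model would be preferable (the estimator interface
  accepts alternatives).
- The telomere caller assumes indel-free tandem copies; a unit with large
  internal duplications could be reported at a shorter period if the
  shorter period satisfies the copy threshold within tolerance.
- NJ with column bootstrap is a scaffold for topology sanity, not a
  substitute for model-based phylogenetics.
- The Mantel permutation test assumes exchangeable strains; strong
  within-species structure would call for restricted permutations.
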