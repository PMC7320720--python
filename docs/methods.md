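# Methods

## Index model

The reference is concatenated into one coordinate space (k-mers never span
contig boundaries) and every plus-strand k-mer without N is hashed:

    w(W) ∈ [0, 4^k)   base-4 encoding, 5'-most base most significant
    s = fmix64(w) mod H

`fmix64` is the MurmurHash3 64-bit finalizer, fixed bit-exactly
(`x ^= x>>33; x *= 0xff51afd7ed558ccd; x ^= x>>33;
x *= 0xc4ceb9fe1a85ec53; x ^= x>>33`) so that the on-disk format has a
one-line contract. H is the smallest prime ≥ 1.6× the reference length,
floored at 65,537; a prime far above the word count keeps slot collisions
rare, and the user can override H where the collision regime itself is
under study.

Each row is 5 bytes (tally byte + 32-bit value). Tally codes:

| code | meaning | value field |
| --- | --- | --- |
| 0x00 | empty / absent | — |
| 0xFF | pin (unique across both strands) | coordinate |
| 0xFE | singleton (unique on plus, revcomp present) | coordinate |
| 0x81–0xFC | multi-list head, low 7 bits = skip 1–124 | first coordinate |
| 0xFD | head whose skip overflows 7 bits | absolute row pointer |
| 0x01–0x7D | list interior, skip 1–125 | coordinate |
| 0x7F | interior overflow | absolute row pointer |
| 0x7E | list end | coordinate |

The high bit marks present slots; list interiors and empty rows keep it
clear. Interior rows are taken from the nearest empty rows scanning
forward from the head (wrapping at H), lists built in increasing slot
order. Slots whose abundance exceeds t (default 32) on *either* strand
are excluded entirely: their rows stay empty and are available to linked
lists, so an excluded slot is indistinguishable from a never-seen slot at
lookup time — the count-level classifier (`classify_slot`) is the only
place the distinction exists. Counting the minus strand prevents a word
that is rare on the plus strand but abundant in reverse complement from
masquerading as confident evidence.

Collisions (different words, one slot) merge position lists with no
stored disambiguation. The cost is a occasional wasted extension attempt
that dies within a few flank columns; the benefit is 5 bytes per row,
period. For the same reason the seed block itself is never verified:
flanking sequence is checked first, because in the non-collision case the
seed always matches while flanks often do not.

## Search

For a read of length L there are n = L−k+1 word positions, visited at

    position_j = (stride · j) mod n,   stride = smallest prime ≥ k+5
                                                not dividing n

(a prime not dividing n is coprime to n, so the loop is a permutation;
for L=150, k=24 this is the stride-29 order 0, 29, 58, …). The stride
exceeds k because neighbouring words fail for the same local reason — a
repeat, a variant, an error — and skipping ahead finds usable words
sooner. At each position the plus-strand word is processed before the
minus-strand word.

*Pass 1 (brace).* Pins are drawn alternately from R1 and R2; every new
pin is tested against the mate's pins collected so far. Orientation must
be FR and the implied fragment within `max_frag` (default 1000 nt) — a
test requiring only the coordinates already in hand. A candidate brace is
aligned; if both mates align over the full query with score ≥ |Q| − 10
(the *good-brace margin*, tolerating a few mismatches) the search stops.
Each hash row is fetched at most once here and cached per query,
modelling the per-thread buffer contract; later passes reuse the cache,
and failed extension locations are never retried.

*Pass 2.* Seeds from non-pin slots with ≤2 positions. Termination is
checked only after **all** positions of a slot have been extended: an
exact two-copy repeat then necessarily surfaces both copies, forcing
T = S and MAPQ 0 instead of a spuriously confident early exit.

*Pass 3.* All remaining indexed slots (pins whose mate never offered a
brace included) up to abundance t. The `veryfast` preset drops this pass,
caps abundance at 3, tightens the x-drop to 8 and gap-extends at most 2
HSPs; the canonical veryfast artifact is an index built with t = 3, but
the search-time cap lets it run against a t = 32 index (with a warning).

Single-end braces are two pins within one read, ≥ k apart (overlapping
pins share sequence and are not independent evidence), on implied starts
agreeing within the 16-nt diagonal tolerance.

## Alignment and scores

Matches score +1 (so the best score equals |Q|), mismatch −2, gap open
−4, gap extend −1 (a gap of length g costs 4+g). Only the match score is
structurally constrained — the MAPQ formula needs T comparable to |Q| —
the penalties are conventional BLAST-like choices. Gapless x-drop
extension (x = 16) stops when the running score falls more than x below
its maximum; extensions scoring ≥ ⌈|Q|/2⌉ become HSPs. An HSP covering
the whole query is promoted directly to an alignment with an all-M CIGAR.
Otherwise the top 4 HSPs are extended by a three-state affine-gap DP,
semi-global over the query (reference prefix/suffix free), restricted to
a band of half-width 16 around the HSP diagonal. With the band opened to
the full matrix this DP is exactly textbook semi-global alignment, which
is how it is validated (against Biopython's `PairwiseAligner` on random
instances).

Best/second-best bookkeeping clusters alignments within 5 nt on the same
strand into one locus (indel jitter), then

    MAPQ = round_half_up((T − S) · (T/|Q|)²),  clamped to [0, 254]

with S = T/2 when no second locus was found, and S = T (MAPQ 0) on a
score tie at distinct loci — ambiguity must surface as zero confidence.
Pairing picks the FR-consistent combination maximizing T₁+T₂ within
`max_frag` (proper pair); otherwise each read keeps its best alignment
and the pair is flagged discordant. Alignments with non-positive score
are discarded as carrying no placement evidence.

## Benchmark

The diploid genome applies VCF-style variants left-to-right per
haplotype; unphased variants are assigned by a seeded coin flip.
Monotone haplotype→reference coordinate maps (inserted bases map to
their anchor) convert simulated-read truth into reference coordinates.

Read pairs are anchored: for each locus, `pairs` (default 10) FR pairs
with Normal(350, 35) fragments truncated to [L, 1000], placed uniformly
among the positions putting the locus inside R1 or R2; a coin decides
which physical end is R1. Reference-origin loci are random non-N
positions; variant-origin loci are variant positions on the carrying
haplotype. Desk-scale defaults are 1,000 loci × 10 pairs (configurable) —
small enough to run in seconds on a megabase genome, large enough for
sub-percent error estimates.

Substitution errors are injected per base with probability 10^(−q/10);
indel errors are not modelled (they are rare on Illumina). Qualities come
from a donor FASTQ when provided, else from a synthetic profile: mean Q38
over cycles 1–100 decaying linearly to Q25 at the last cycle, Gaussian
jitter (sd 3), clamped to [2, 41] — emulating end-of-read quality decay.

Scoring: a read is *confident* iff MAPQ ≥ 10 and *correct* iff reference
name and strand match and the reported start is within 10 nt of truth
(the tolerance absorbs indel-induced start shifts; both thresholds are
configurable). The eight metrics:

* S_r — correct-confident reads / all reads (%)
* E_r — wrong reads among confident reads (%); 0 when nothing is confident
* S_l — loci with ≥3 confident reads whose majority (strictly more than
  half) is correct, / **all** loci (%)
* E_l — loci with ≥3 confident reads in which a majority clusters at the
  same wrong position (within the coordinate tolerance), / loci with ≥3
  confident reads (%); 0 when no locus qualifies

The two locus metrics deliberately use different denominators: S_l is a
sensitivity (a locus drowned below 3 confident reads is a miss), E_l an
error rate among loci that produced a call at all. A locus can never
count for both (two different strict majorities of one set cannot
coexist).

Pairwise summaries: MI_XY = mean over the four (read/locus × genome)
combinations of S_X − S_Y − E_X + E_Y; IM_XY = number of the eight
metrics where X is strictly better; TI_X = Σ_Y MI_XY. Rendered as
`X >>(MI) Y` / `X <<(MI) Y` for clean sweeps, else `X >n(MI) Y`.

MAPQ calibration: per reported q with ≥50 mapped reads,
q_measured = −10·log₁₀(n_error/n), +∞ when no read at q is wrong.

## Mappability

Error-free FR pairs (fragment 350) tile each contig at stride
fragment/depth (depth 10 by default); tiling is the default because it is
exactly reproducible, with seeded uniform placement available (region
boundaries then jitter by up to one read length). A base is mappable iff
some read — either mate — covers it at its *reported* position with
MAPQ ≥ Q (default 3). Unmappable regions are maximal runs ≥ L of
unmappable bases in which every length-L window holds fewer than 10 Ns
(so N-gaps, which no read can cover, are not reported as unmappable
sequence). Lowering the threshold Q shrinks the unmappable base set
monotonically, since the per-base criterion is a threshold on one
precomputed quantity. Consensus across runs is the base-level
intersection of the region sets, which requires the sets to name the same
chromosomes.

## Synthetic data

`fixtures` generates i.i.d. random backbones with planted features at
recorded coordinates: exact repeats (interior words → multi slots),
inverted repeats (singletons — the reverse complement of each interior
word occurs on the plus strand), N-runs (nothing indexed) and
over-abundant words (excluded slots). Variant sets are clustered by
default — cluster centres as a Poisson process, Poisson(µ−1)+1 variants
per cluster with geometric within-cluster spacing — because real variants
cluster, and reads carrying several variants are precisely the hard case
a plain Poisson spacing under-produces; geometric (Bernoulli-process)
spacing is available for comparison. Everything is reproducible
byte-for-byte from (spec, seed).

What the generator does *not* emulate: realistic repeat families
(Alu/LINE structure), GC or coverage bias, indel sequencing errors,
structural variants, and quality-correlated error bursts beyond the
positional decay. Passing tests therefore demonstrate algorithmic
correctness and calibration behaviour on idealized genomes, not
performance on real human data.

## Numerical choices and degenerate inputs

* MAPQ rounding is round-half-up; the SAM clamp is [0, 254].
* Reads shorter than k are reported unmapped; words containing N are
  neither indexed nor used as seeds; N positions never score as matches.
* Alignment windows are clipped at contig bounds; a window too short to
  hold the whole query makes that candidate infeasible (dropped).
* Locus clustering for second-best bookkeeping uses a 5 nt merge radius.
* Ties anywhere are broken toward the smaller coordinate, making the
  whole mapper deterministic: identical inputs give byte-identical SAM.
* Table capacity: H must be prime, > reference length and < 2³²; a
  reference ≥ 4 Gb exceeds the 32-bit coordinate space and is rejected.

## Known limitations

* No mate rescue: an unseeded mate stays unmapped even when its partner
  is confidently placed.
* No split/chimeric alignments, secondary/supplementary records, BAM
  output, or multithreading (the per-query cache models the per-thread
  buffer contract instead).
* MAPQ is a two-score heuristic: at high reported values the measured
  quality can fall short of the reported one for the small minority of
  reads whose competing locus was never visited after early termination.
* At table loads near 1 the linked-list allocator can exhaust empty rows;
  H should stay well above the word count (the default 1.6× ratio does).
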