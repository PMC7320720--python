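# pinmap

A short-read mapper built around *pins* — k-mers whose hash slot occurs
exactly once in the reference, counting both strands — together with the
tooling needed to judge it: a locus-anchored simulation benchmark and a
genome-mappability scanner. Everything runs on synthetic genomes at desk
scale; no downloads are required.

## Who this is for

People studying read-mapping behaviour — seed design, mapping-quality
calibration, systematic mapping errors, unmappable regions — who want a
compact, fully inspectable mapper plus a benchmark harness, rather than a
production aligner.

## The algorithm

**Index.** Every plus-strand k-mer (default k = 24) is encoded base-4
(A=0, C=1, G=2, T=3) and hashed with the MurmurHash3 64-bit finalizer into
a table of H rows (H prime, ≈1.6× the reference length). Each row is five
bytes: a tally byte plus a 32-bit value. Slots found once on the plus
strand with no reverse-complement occurrence are **pins**; once on the
plus strand but with minus-strand hits, **singletons**; 2..t occurrences
are stored as linked lists threaded through nearby empty rows with 7-bit
skip pointers (32-bit absolute pointers on overflow); slots exceeding
abundance t (default 32) on either strand are excluded. Collisions merge
position lists silently — alignment exposes them immediately through
hopeless flanking mismatches.

**Search.** Query words are visited at a prime stride ≥ k+5 (29 for
k = 24, i.e. positions 0, 29, 58, … mod 127 for 150 nt reads), both
strands per position. Pass 1 looks for a **brace**: a pin in R1 and a pin
in R2 whose coordinates imply one forward-reverse fragment. A brace whose
mates both align near-perfectly ends the search — the reverse complement
of a pin occurs nowhere, so a good brace is almost certainly the true
location. Pass 2 seeds from non-pin slots with ≤2 positions; pass 3 from
everything else up to abundance t. Seeds are extended gaplessly under an
x-drop rule into high-scoring segment pairs (HSPs); only when no HSP
covers the query are the top HSPs extended into banded affine-gap
semi-global alignments.

**Mapping quality.** With T the best and S ≤ T the second-best alignment
score (S := T/2 when only one alignment was found, as a prior under early
termination), and |Q| the read length:

    MAPQ = (T − S) · (T/|Q|)²,   P_error = 10^(−MAPQ/10)

**Benchmark.** Reads are simulated in anchored groups: for each locus,
ten pairs are placed so that R1 or R2 covers the locus; variant-genome
loci sit on experimentally-styled (clustered, phased) variants applied to
two haplotypes. Substitution errors follow each base's Phred quality.
Eight metrics result: per-read sensitivity/error (S_r, E_r) and per-locus
sensitivity/systematic-error (S_l, E_l), each for reference-origin and
variant-origin reads, plus pairwise method summaries (MI/IM/TI) and a
MAPQ calibration table.

**Mappability.** Error-free pairs at 10× depth are mapped back; a base is
mappable iff a read with MAPQ ≥ Q covers it. Maximal unmappable runs of
length ≥ L (filtered by an uncalled-base window rule) are reported as
BED3, and region sets from different configurations can be intersected.

## Worked example

```
$ cat spec.json
{"length": 100000, "seed": 7,
 "features": [{"kind": "repeat", "length": 600, "copies": 2},
              {"kind": "inverted_repeat", "length": 300}]}

$ pinmap fixture --spec spec.json --out-prefix toy --variant-density 0.002
$ pinmap index --ref toy.fasta --out toy.idx
INFO pinmap: indexed 1 sequences, 100000 bases, H=160001

$ pinmap bench --ref toy.fasta --vcf toy.vcf --idx toy.idx \
      --loci 200 --pairs 10 --seed 1 --report report.tsv
$ cat report.tsv
metric  value
sr_ref  99.3750
er_ref  0.0503
sl_ref  100.0000
el_ref  0.0000
sr_var  98.0747
er_var  0.2921
sl_var  100.0000
el_var  0.0000
```

99.4% of reference-origin reads (98.1% of the harder variant-carrying
reads) map to the correct coordinate with MAPQ ≥ 10; 0.05% of confident
placements are wrong, and no locus shows a systematic error (a majority
of its confident reads clustered at the same wrong position).

```
$ pinmap unmap --ref toy.fasta --idx toy.idx --bed unmap.bed
$ cat unmap.bed
chr1    185     515
chr1    850     1180
```

The two reported intervals are the interiors of the planted 600 bp
duplication (copies at 60–660 and 720–1320): fragments falling wholly
inside either copy cannot be placed confidently, while reads overlapping
the distinctive flanks can — hence the ~150 nt (one read length) margins.

Single files of paired FASTQ map with
`pinmap map --idx toy.idx --r1 r1.fq --r2 r2.fq --samout out.sam`;
`--veryfast` switches to the speed-over-sensitivity preset (abundance cap
t = 3, tighter x-drop, no high-abundance pass).

## Layout

| module | contents |
| --- | --- |
| `pinmap.seqio` | FASTA/FASTQ/SAM/BED readers and writers |
| `pinmap.kindex` | hash-table index: build, classify, linked lists, (de)serialize |
| `pinmap.align` | x-drop extension, banded semi-global DP, MAPQ |
| `pinmap.mapper` | word schedule, brace search, three-pass mapping, pairing |
| `pinmap.urbench` | diploid genome, read simulation, metrics, calibration |
| `pinmap.mappability` | coverage simulation, unmappable regions, consensus |
| `pinmap.fixtures` | synthetic genomes/variants with planted truth |
| `pinmap.cli` | `pinmap index / map / bench / unmap / unmap-intersect / fixture` |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
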