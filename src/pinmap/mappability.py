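"""Unmappable-region detection by error-free simulated coverage.

Error-free FR read pairs are simulated from the reference at a target
depth (the best-case scenario for a mapper: no variants, no errors) and
mapped back.  A base is *mappable* iff at least one read with reported
MAPQ >= Q covers it — coverage is taken at the *reported* location and
either mate counts.  Unmappable regions are maximal runs of unmappable
bases of length >= L, discarded if any length-L window inside the run
holds 10 or more uncalled (N) bases, so N-gaps are not reported as
unmappable sequence.  The consensus of several region sets is their
base-level intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import ScoringScheme
from .kindex import N_CODE, ReferenceIndex
from .mapper import SearchParams, map_pair
from .seqio import BedInterval, SequenceRecord
from .urbench import revcomp

__all__ = [
    "MappabilityParams",
    "simulate_coverage",
    "regions_from_coverage",
    "find_unmappable",
    "consensus_intersect",
]


@dataclass(frozen=True)
class MappabilityParams:
    """L: read length; Q: MAPQ threshold; depth: target coverage;
    max_uncalled: N budget per length-L window; frag: fragment length."""

    L: int = 150
    Q: int = 3
    depth: int = 10
    max_uncalled: int = 10
    frag: int = 350

    def __post_init__(self) -> None:
        if self.depth < 1 or self.L < 1:
            raise ValueError("L and depth must be positive")


def simulate_coverage(
    reference: SequenceRecord,
    index: ReferenceIndex,
    params: MappabilityParams,
    scoring: Optional[ScoringScheme] = None,
    search: Optional[SearchParams] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Per-base best reported MAPQ from error-free simulated pairs.

    Pairs tile the contig at stride frag/depth (deterministic, the
    default); with ``seed`` set, the same number of pairs is instead
    placed uniformly at random.  Returns an int array (−1 where no
    mapped read covers the base).
    """
    n = len(reference.sequence)
    L, frag = params.L, min(params.frag, n)
    best = np.full(n, -1, dtype=np.int32)
    if n < frag or frag < L:
        return best
    stride = max(1, frag // params.depth)
    starts = list(range(0, n - frag + 1, stride))
    if seed is not None:
        rng = np.random.default_rng(seed)
        starts = sorted(int(s) for s in rng.integers(0, n - frag + 1, len(starts)))
    for i, s in enumerate(starts):
        r1 = SequenceRecord(f"cov_{i}/1", reference.sequence[s : s + L])
        r2 = SequenceRecord(
            f"cov_{i}/2", revcomp(reference.sequence[s + frag - L : s + frag])
        )
        pr = map_pair(r1, r2, index, scoring, search)
        for res in (pr.r1, pr.r2):
            aln = res.alignment
            if aln is None:
                continue
            rname, off, length = index.contig_of(aln.ref_start)
            if rname != reference.name:
                continue
            a = aln.ref_start - off
            b = min(a + L, length)
            np.maximum(best[a:b], res.mapq, out=best[a:b])
    return best


def regions_from_coverage(
    reference: SequenceRecord,
    best_mapq: np.ndarray,
    params: MappabilityParams,
) -> list[BedInterval]:
    """Maximal unmappable runs >= L passing the uncalled-base window rule."""
    L = params.L
    unmappable = best_mapq < params.Q
    is_n = np.frombuffer(reference.sequence.encode(), dtype=np.uint8) == ord("N")
    ncum = np.concatenate([[0], np.cumsum(is_n)])
    out = []
    n = len(unmappable)
    i = 0
    while i < n:
        if not unmappable[i]:
            i += 1
            continue
        j = i
        while j < n and unmappable[j]:
            j += 1
        if j - i >= L:
            # every length-L window inside [i, j) must hold < max_uncalled Ns
            win_n = ncum[i + L : j + 1] - ncum[i : j + 1 - L]
            if win_n.size == 0 or int(win_n.max()) < params.max_uncalled:
                out.append(BedInterval(reference.name, i, j))
        i = j
    return out


def find_unmappable(
    reference: SequenceRecord,
    index: ReferenceIndex,
    params: Optional[MappabilityParams] = None,
    scoring: Optional[ScoringScheme] = None,
    search: Optional[SearchParams] = None,
    seed: Optional[int] = None,
) -> list[BedInterval]:
    """Simulate, map, and report the unmappable regions of one contig."""
    params = params or MappabilityParams()
    best = simulate_coverage(reference, index, params, scoring, search, seed)
    return regions_from_coverage(reference, best, params)


def consensus_intersect(
    region_sets: Sequence[Sequence[BedInterval]],
) -> list[BedInterval]:
    """Base-level intersection of two or more BED interval sets.

    All sets must cover the same chromosome names; output is sorted and
    merged per chromosome.
    """
    if len(region_sets) < 2:
        raise ValueError("need at least two region sets to intersect")
    chrom_sets = [set(iv.chrom for iv in s) for s in region_sets]
    universe = set().union(*chrom_sets)
    for cs in chrom_sets:
        missing = universe - cs
        if missing:
            raise ValueError(
                f"chromosome name mismatch across sets: {sorted(missing)}"
            )

    def merged(ivs: Sequence[BedInterval], chrom: str) -> list[tuple[int, int]]:
        spans = sorted((iv.start, iv.end) for iv in ivs if iv.chrom == chrom)
        out: list[tuple[int, int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    result = []
    for chrom in sorted(universe):
        current = merged(region_sets[0], chrom)
        for other_set in region_sets[1:]:
            other = merged(other_set, chrom)
            nxt: list[tuple[int, int]] = []
            i = j = 0
            while i < len(current) and j < len(other):
                s = max(current[i][0], other[j][0])
                e = min(current[i][1], other[j][1])
                if s < e:
                    nxt.append((s, e))
                if current[i][1] <= other[j][1]:
                    i += 1
                else:
                    j += 1
            current = nxt
        result.extend(BedInterval(chrom, s, e) for s, e in current)
    return result
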