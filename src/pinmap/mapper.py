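"""Three-pass seed-and-extend search over the k-mer index.

Per read pair the search proceeds:

1. **Brace pass** — walk the query words of both mates in stride order,
   looking up one hash row per word position and strand.  Pins found in R1
   and R2 whose reference coordinates imply one forward-reverse fragment
   form a *brace*; distant pin pairs are rejected on coordinates alone.  A
   brace whose two mates both align over their full length with a
   near-perfect score (a *good brace*) ends the search immediately: a good
   brace is almost certainly the true location, because the reverse
   complement of a pin occurs nowhere in the reference.
2. **Low-abundance pass** — seeds from all non-pin slots with at most two
   indexed positions, using the rows cached in pass 1.  The search for a
   read stops once a slot yields a high-scoring alignment — only after
   every position of that slot has been tried, so an exact two-copy repeat
   surfaces both copies and collapses MAPQ to 0.
3. **High-abundance pass** — all remaining indexed slots up to abundance t.

Word positions are visited at a prime stride >= k+5 (29 for k=24) modulo
the word count, which permutes the positions and skips ahead past locally
correlated failures (a repeat, variant or error usually damages a run of
neighbouring words).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import sympy

from . import seqio
from .align import Alignment, Hsp, ScoringScheme, compute_mapq, gapped_extend, xdrop_extend
from .kindex import (
    N_CODE,
    ReferenceIndex,
    SlotRecord,
    hash_slot,
    kmer_codes,
    lookup_positions,
    seq_to_codes,
)
from .seqio import SamRecord, SequenceRecord, sam_flags_paired

__all__ = [
    "SearchParams",
    "QueryContext",
    "PinHit",
    "Brace",
    "ReadResult",
    "PairResult",
    "schedule_positions",
    "find_braces",
    "map_pair",
    "map_single",
    "veryfast_params",
]


# complement lookup on genome codes; N (4) maps to itself
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


@dataclass(frozen=True)
class SearchParams:
    """Search-stage tuning knobs.

    max_frag        largest fragment (outer distance) accepted for a brace
                    or a proper pair, in nt
    good_margin     an alignment is "good" (terminates the search stage)
                    when its score >= |Q| - good_margin
    top_hsps        number of highest-scoring partial HSPs extended into
                    gapped alignments
    pass2_max_abundance  slot position-list cap for the low-abundance pass
    enable_pass3    whether the high-abundance pass runs
    runtime_t_cap   optional abundance cap applied at search time (lets a
                    veryfast search run against a t=32 index)
    diag_tolerance  diagonal slack for the two pins of a single-end brace
    """

    max_frag: int = 1000
    good_margin: int = 10
    top_hsps: int = 4
    pass2_max_abundance: int = 2
    enable_pass3: bool = True
    runtime_t_cap: Optional[int] = None
    diag_tolerance: int = 16


def veryfast_params() -> tuple[SearchParams, ScoringScheme]:
    """The veryfast preset: index abundance cap t=3, tighter x-drop, no
    high-abundance pass, fewer gapped extensions."""
    return (
        SearchParams(enable_pass3=False, top_hsps=2, runtime_t_cap=3),
        ScoringScheme(x=8),
    )


def schedule_positions(read_length: int, k: int) -> tuple[int, list[int]]:
    """Query-word visit order: (stride, positions).

    With n = L-k+1 words, the stride is the smallest prime >= k+5 that does
    not divide n (a prime not dividing n is coprime to it, so the loop
    position_j = (stride*j) mod n visits each word exactly once).  For
    L=150, k=24 this gives stride 29 over 127 words: 0, 29, 58, ...
    """
    n = read_length - k + 1
    if n < 1:
        raise ValueError(f"read length {read_length} shorter than k={k}")
    stride = int(sympy.nextprime(k + 4))
    while n % stride == 0:
        stride = int(sympy.nextprime(stride))
    if n == 1:
        return stride, [0]
    return stride, [(stride * j) % n for j in range(n)]


@dataclass(frozen=True)
class PinHit:
    """A pin slot found in a read: a single candidate reference location."""

    q_pos: int  # position within the strand-oriented query
    strand: str
    coord: int  # global plus-strand coordinate of the pinned word

    @property
    def implied_start(self) -> int:
        return self.coord - self.q_pos


@dataclass(frozen=True)
class Brace:
    """A pin from each mate implying one forward-reverse fragment."""

    pin1: PinHit
    pin2: PinHit
    frag_start: int
    frag_end: int


class QueryContext:
    """Per-read search state: slot values, cached hash rows, HSPs.

    Models the per-thread buffer contract: each hash row is fetched at most
    once per word position/strand in pass 1 and reused by later passes;
    failed extension locations are never retried.
    """

    def __init__(
        self, read: SequenceRecord, index: ReferenceIndex, scoring: ScoringScheme
    ):
        self.read = read
        self.L = len(read.sequence)
        self.k = index.params.k
        self.codes = seq_to_codes(read.sequence)
        self.rc_codes = _RC_CODE[self.codes[::-1]]
        self.mappable = self.L >= self.k
        self.row_fetches = 0
        self._cache: dict[int, SlotRecord] = {}
        self.attempted: set[tuple[str, int]] = set()  # (strand, diagonal)
        self.alignments: dict[tuple[str, int], Alignment] = {}
        self.hsps: list[Hsp] = []
        self.done = False
        if self.mappable:
            self.stride, self.schedule = schedule_positions(self.L, self.k)
            fwd, rev, valid = kmer_codes(self.codes, self.k)
            H = index.H
            self.slot_plus = np.where(valid, hash_slot(fwd, H), -1)
            self.slot_minus = np.where(valid, hash_slot(rev, H), -1)
        else:
            self.stride, self.schedule = 0, []

    def oriented(self, strand: str) -> np.ndarray:
        return self.codes if strand == "+" else self.rc_codes

    def oriented_qpos(self, p: int, strand: str) -> int:
        """Word position translated onto the strand-oriented query."""
        return p if strand == "+" else self.L - self.k - p

    def slot_at(self, p: int, strand: str) -> int:
        arr = self.slot_plus if strand == "+" else self.slot_minus
        return int(arr[p])

    def fetch(self, index: ReferenceIndex, slot: int) -> SlotRecord:
        rec = self._cache.get(slot)
        if rec is None:
            rec = lookup_positions(index, slot)
            self.row_fetches += 1
            self._cache[slot] = rec
        return rec

    def iter_pins(self, index: ReferenceIndex) -> Iterator[PinHit]:
        """Pins in stride order; at each position plus before minus."""
        for p in self.schedule:
            for strand in "+-":
                slot = self.slot_at(p, strand)
                if slot < 0:
                    continue
                rec = self.fetch(index, slot)
                if rec.status == "pin":
                    yield PinHit(self.oriented_qpos(p, strand), strand, rec.positions[0])


def find_braces(
    ctx1: QueryContext,
    ctx2: QueryContext,
    index: ReferenceIndex,
    max_frag: int,
) -> Iterator[Brace]:
    """Candidate braces in alternating pin order (next R1 pin, next R2 pin).

    A candidate requires opposite strands (FR orientation) and a positive
    implied fragment no longer than ``max_frag``; rejection needs only the
    coordinates stored in the pins' rows.
    """
    pins1: list[PinHit] = []
    pins2: list[PinHit] = []
    it1 = ctx1.iter_pins(index)
    it2 = ctx2.iter_pins(index)
    L1, L2 = ctx1.L, ctx2.L
    alive1 = alive2 = True

    def pair(p1: PinHit, p2: PinHit) -> Optional[Brace]:
        if p1.strand == p2.strand:
            return None
        if p1.strand == "+":
            fwd_start, rev_start, rev_len = p1.implied_start, p2.implied_start, L2
        else:
            fwd_start, rev_start, rev_len = p2.implied_start, p1.implied_start, L1
        frag = rev_start + rev_len - fwd_start
        if frag <= 0 or frag > max_frag:
            return None
        return Brace(p1, p2, fwd_start, fwd_start + frag)

    while alive1 or alive2:
        if alive1:
            p1 = next(it1, None)
            if p1 is None:
                alive1 = False
            else:
                for p2 in pins2:
                    br = pair(p1, p2)
                    if br is not None:
                        yield br
                pins1.append(p1)
        if alive2:
            p2 = next(it2, None)
            if p2 is None:
                alive2 = False
            else:
                for p1 in pins1:
                    br = pair(p1, p2)
                    if br is not None:
                        yield br
                pins2.append(p2)


@dataclass
class ReadResult:
    """Best placement of one read, with the scores behind its MAPQ."""

    read: SequenceRecord
    alignment: Optional[Alignment] = None
    T: int = 0
    S: float = 0.0
    mapq: int = 0
    second_found: bool = False


@dataclass
class PairResult:
    r1: ReadResult
    r2: Optional[ReadResult] = None
    proper: bool = False
    tlen: int = 0
    stats: dict = field(default_factory=dict)

    def to_sam(self, index: ReferenceIndex) -> list[SamRecord]:
        if self.r2 is None:
            return [_sam_single(self.r1, index)]
        return _sam_pair(self, index)


def _ref_span(cigar: str) -> int:
    span = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MD=XN":
                span += int(num)
            num = ""
    return span


def _extend_candidate(
    ctx: QueryContext,
    index: ReferenceIndex,
    q_pos: int,
    strand: str,
    coord: int,
    scoring: ScoringScheme,
) -> Optional[Alignment]:
    """Seed-extend one candidate location; record HSPs and failures."""
    diag = coord - q_pos
    key = (strand, diag)
    if key in ctx.attempted:
        return None
    ctx.attempted.add(key)
    lo, hi = index.contig_bounds(coord)
    query = ctx.oriented(strand)
    hsp = xdrop_extend(
        query, index.genome, q_pos, coord, ctx.k, scoring, strand, lo, hi
    )
    if hsp is None:
        return None  # failed location, never re-extended (attempted set)
    if hsp.q_start == 0 and hsp.q_end == ctx.L:
        aln = Alignment(hsp.ref_start, strand, f"{ctx.L}M", hsp.score, ctx.L)
        return _register(ctx, aln)
    ctx.hsps.append(hsp)
    return None


def _register(ctx: QueryContext, aln: Alignment) -> Optional[Alignment]:
    if aln.score < 1:
        return None  # a non-positive score carries no placement evidence
    key = (aln.strand, aln.ref_start)
    old = ctx.alignments.get(key)
    if old is None or aln.score > old.score:
        ctx.alignments[key] = aln
    return ctx.alignments[key]


def _gapped_from_hsps(
    ctx: QueryContext,
    index: ReferenceIndex,
    scoring: ScoringScheme,
    params: SearchParams,
) -> None:
    """Extend the top few HSPs into gapped semi-global alignments."""
    pad = scoring.band + 8
    done_diags: set[tuple[str, int]] = set()
    for hsp in sorted(ctx.hsps, key=lambda h: (-h.score, h.ref_start))[
        : params.top_hsps
    ]:
        dkey = (hsp.strand, hsp.diagonal)
        if dkey in done_diags:
            continue
        done_diags.add(dkey)
        lo, hi = index.contig_bounds(hsp.ref_start)
        w_lo = max(lo, hsp.diagonal - pad)
        w_hi = min(hi, hsp.diagonal + ctx.L + pad)
        if w_hi - w_lo < ctx.L:
            continue  # window clipped too short to hold the query
        aln = gapped_extend(
            ctx.oriented(hsp.strand),
            index.genome[w_lo:w_hi],
            hsp,
            scoring,
            window_start=w_lo,
        )
        if aln is not None:
            _register(ctx, aln)


def _good(ctx: QueryContext, aln: Optional[Alignment], params: SearchParams) -> bool:
    return aln is not None and aln.score >= ctx.L - params.good_margin


def _pass_seed_slots(
    ctx: QueryContext,
    index: ReferenceIndex,
    scoring: ScoringScheme,
    params: SearchParams,
    lo_ab: int,
    hi_ab: int,
    include_pins: bool,
) -> None:
    """Try every scheduled word whose slot abundance lies in [lo_ab, hi_ab].

    Termination is checked per slot, after *all* of the slot's positions
    were extended, so equal-scoring repeat copies are all discovered.
    """
    t_cap = params.runtime_t_cap
    for p in ctx.schedule:
        if ctx.done:
            return
        for strand in "+-":
            slot = ctx.slot_at(p, strand)
            if slot < 0:
                continue
            rec = ctx.fetch(index, slot)
            if rec.status == "absent":
                continue
            if rec.status == "pin" and not include_pins:
                continue
            ab = len(rec.positions)
            if not (lo_ab <= ab <= hi_ab):
                continue
            if t_cap is not None and ab > t_cap:
                continue
            q_pos = ctx.oriented_qpos(p, strand)
            found_good = False
            for coord in rec.positions:
                aln = _extend_candidate(ctx, index, q_pos, strand, coord, scoring)
                if _good(ctx, aln, params):
                    found_good = True
            if found_good:
                ctx.done = True
                return


def _finalize_read(
    ctx: QueryContext,
    index: ReferenceIndex,
    scoring: ScoringScheme,
    params: SearchParams,
    locus_merge: int = 5,
) -> ReadResult:
    """Pick best and second-best alignments and derive the MAPQ inputs."""
    _gapped_from_hsps(ctx, index, scoring, params)
    result = ReadResult(read=ctx.read)
    if not ctx.alignments:
        return result
    # Cluster alignments into loci: same strand, starts within locus_merge.
    alns = sorted(
        ctx.alignments.values(), key=lambda a: (a.strand, a.ref_start)
    )
    loci: list[Alignment] = []
    for aln in alns:
        if (
            loci
            and loci[-1].strand == aln.strand
            and aln.ref_start - loci[-1].ref_start <= locus_merge
        ):
            if aln.score > loci[-1].score:
                loci[-1] = aln
        else:
            loci.append(aln)
    loci.sort(key=lambda a: (-a.score, a.ref_start, a.strand))
    best = loci[0]
    result.alignment = best
    result.T = best.score
    if len(loci) >= 2:
        result.S = min(loci[1].score, best.score)
        result.second_found = True
    else:
        result.S = best.score / 2.0  # prior when search terminated early
    return result


def _select_pair(
    res1: ReadResult, res2: ReadResult, ctx1: QueryContext, ctx2: QueryContext,
    index: ReferenceIndex, params: SearchParams
) -> tuple[bool, int]:
    """Re-pick per-read alignments as the FR-consistent pair maximizing
    T1+T2 within max_frag; fall back to independent bests (discordant)."""
    best_sum, best_combo = None, None
    for a1 in ctx1.alignments.values():
        for a2 in ctx2.alignments.values():
            if a1.strand == a2.strand:
                continue
            fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
            frag = rev.ref_start + _ref_span(rev.cigar) - fwd.ref_start
            if frag <= 0 or frag > params.max_frag:
                continue
            if index.contig_of(a1.ref_start) != index.contig_of(a2.ref_start):
                continue
            s = a1.score + a2.score
            key = (s, -a1.ref_start, -a2.ref_start)
            if best_sum is None or key > best_sum:
                best_sum = key
                best_combo = (a1, a2, frag if a1.strand == "+" else -frag)
    if best_combo is None:
        return False, 0
    a1, a2, tlen = best_combo
    for res, aln, ctx in ((res1, a1, ctx1), (res2, a2, ctx2)):
        if res.alignment is not aln:
            res.alignment = aln
            res.T = aln.score
            # Second-best = best score at any other locus, clamped to T.
            others = [
                a.score
                for a in ctx.alignments.values()
                if a is not aln
                and not (
                    a.strand == aln.strand
                    and abs(a.ref_start - aln.ref_start) <= 5
                )
            ]
            if others:
                res.S = min(max(others), res.T)
                res.second_found = True
            else:
                res.S = res.T / 2.0
                res.second_found = False
    return True, tlen


def map_pair(
    r1: SequenceRecord,
    r2: SequenceRecord,
    index: ReferenceIndex,
    scoring: Optional[ScoringScheme] = None,
    params: Optional[SearchParams] = None,
) -> PairResult:
    """Map one read pair through the three search passes."""
    scoring = scoring or ScoringScheme()
    params = params or SearchParams()
    ctx1 = QueryContext(r1, index, scoring)
    ctx2 = QueryContext(r2, index, scoring)
    stats = {"braces_tried": 0, "early_pass": 0, "pass2": 0, "pass3": 0}

    if ctx1.mappable and ctx2.mappable:
        for brace in find_braces(ctx1, ctx2, index, params.max_frag):
            stats["braces_tried"] += 1
            a1 = _extend_candidate(
                ctx1, index, brace.pin1.q_pos, brace.pin1.strand,
                brace.pin1.coord, scoring,
            )
            if not _good(ctx1, a1, params):
                continue
            a2 = _extend_candidate(
                ctx2, index, brace.pin2.q_pos, brace.pin2.strand,
                brace.pin2.coord, scoring,
            )
            if _good(ctx2, a2, params):
                ctx1.done = ctx2.done = True
                stats["early_pass"] = 1
                break

    for ctx in (ctx1, ctx2):
        if ctx.mappable and not ctx.done:
            stats["pass2"] += 1
            _pass_seed_slots(
                ctx, index, scoring, params,
                lo_ab=1, hi_ab=params.pass2_max_abundance, include_pins=False,
            )
    if params.enable_pass3:
        for ctx in (ctx1, ctx2):
            if ctx.mappable and not ctx.done:
                stats["pass3"] += 1
                _pass_seed_slots(
                    ctx, index, scoring, params,
                    lo_ab=1, hi_ab=index.params.t, include_pins=True,
                )

    res1 = _finalize_read(ctx1, index, scoring, params)
    res2 = _finalize_read(ctx2, index, scoring, params)
    proper, tlen = _select_pair(res1, res2, ctx1, ctx2, index, params)
    for res in (res1, res2):
        if res.alignment is not None:
            res.mapq = compute_mapq(res.T, res.S, len(res.read.sequence))
    pr = PairResult(res1, res2, proper, tlen, stats)
    pr.stats["row_fetches"] = ctx1.row_fetches + ctx2.row_fetches
    return pr


def map_single(
    read: SequenceRecord,
    index: ReferenceIndex,
    scoring: Optional[ScoringScheme] = None,
    params: Optional[SearchParams] = None,
) -> PairResult:
    """Map a single-end read.

    The brace here is two non-overlapping pins within the read on the same
    strand whose implied starts agree within the diagonal tolerance.
    """
    scoring = scoring or ScoringScheme()
    params = params or SearchParams()
    ctx = QueryContext(read, index, scoring)
    stats = {"braces_tried": 0, "early_pass": 0, "pass2": 0, "pass3": 0}

    if ctx.mappable:
        seen: list[PinHit] = []
        for pin in ctx.iter_pins(index):
            hit = False
            for prev in seen:
                if prev.strand != pin.strand:
                    continue
                if abs(prev.q_pos - pin.q_pos) < ctx.k:
                    continue  # overlapping pins are not independent evidence
                if abs(prev.implied_start - pin.implied_start) > params.diag_tolerance:
                    continue
                stats["braces_tried"] += 1
                aln = _extend_candidate(
                    ctx, index, pin.q_pos, pin.strand, pin.coord, scoring
                )
                if _good(ctx, aln, params):
                    ctx.done = True
                    stats["early_pass"] = 1
                    hit = True
                break
            if hit:
                break
            seen.append(pin)
        if not ctx.done:
            stats["pass2"] += 1
            _pass_seed_slots(
                ctx, index, scoring, params,
                lo_ab=1, hi_ab=params.pass2_max_abundance, include_pins=False,
            )
        if not ctx.done and params.enable_pass3:
            stats["pass3"] += 1
            _pass_seed_slots(
                ctx, index, scoring, params,
                lo_ab=1, hi_ab=index.params.t, include_pins=True,
            )

    res = _finalize_read(ctx, index, scoring, params)
    if res.alignment is not None:
        res.mapq = compute_mapq(res.T, res.S, len(read.sequence))
    pr = PairResult(res, None, False, 0, stats)
    pr.stats["row_fetches"] = ctx.row_fetches
    return pr


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def _seq_and_qual(res: ReadResult) -> tuple[str, str]:
    rec = res.read
    reverse = res.alignment is not None and res.alignment.strand == "-"
    seq = rec.sequence
    if reverse:
        comp = str.maketrans("ACGTN", "TGCAN")
        seq = seq.translate(comp)[::-1]
    if rec.qualities is None:
        qual = "*"
    else:
        quals = rec.qualities[::-1] if reverse else rec.qualities
        qual = "".join(chr(q + 33) for q in quals)
    return seq, qual


def _sam_single(res: ReadResult, index: ReferenceIndex) -> SamRecord:
    seq, qual = _seq_and_qual(res)
    name = _strip_mate_suffix(res.read.name)
    if res.alignment is None:
        return SamRecord(name, seqio.FLAG_UNMAPPED, seq=seq, qual=qual)
    aln = res.alignment
    rname, off, _ = index.contig_of(aln.ref_start)
    flag = seqio.FLAG_REVERSE if aln.strand == "-" else 0
    return SamRecord(
        name, flag, rname, aln.ref_start - off + 1, res.mapq, aln.cigar,
        seq=seq, qual=qual,
        tags=[f"AS:i:{aln.score}", f"XS:i:{int(res.S)}" if res.second_found else "XS:i:-1"],
    )


def _sam_pair(pr: PairResult, index: ReferenceIndex) -> list[SamRecord]:
    res1, res2 = pr.r1, pr.r2
    assert res2 is not None
    a1, a2 = res1.alignment, res2.alignment
    f1, f2 = sam_flags_paired(
        a1 is not None,
        a2 is not None,
        a1 is not None and a1.strand == "-",
        a2 is not None and a2.strand == "-",
        pr.proper,
    )
    name = _strip_mate_suffix(res1.read.name)
    out = []
    for res, flag, mate_aln, mate_res in (
        (res1, f1, a2, res2),
        (res2, f2, a1, res1),
    ):
        seq, qual = _seq_and_qual(res)
        aln = res.alignment
        if aln is None:
            out.append(SamRecord(name, flag, seq=seq, qual=qual))
            continue
        rname, off, _ = index.contig_of(aln.ref_start)
        rnext, pnext = "*", 0
        if mate_aln is not None:
            mname, moff, _ = index.contig_of(mate_aln.ref_start)
            rnext = "=" if mname == rname else mname
            pnext = mate_aln.ref_start - moff + 1
        # pr.tlen is signed for R1 (positive when R1 is the leftmost mate).
        tlen = 0 if not pr.proper else (pr.tlen if res is res1 else -pr.tlen)
        out.append(
            SamRecord(
                name, flag, rname, aln.ref_start - off + 1, res.mapq,
                aln.cigar, rnext, pnext, tlen, seq, qual,
                tags=[f"AS:i:{aln.score}"],
            )
        )
    return out
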