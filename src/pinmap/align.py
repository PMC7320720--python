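"""Seed extension and alignment scoring.

A seed (an indexed k-mer hit) implies a gapless aligned block of length k.
It is extended into flanking sequence with gapless x-drop alignment, which
stops once the running score falls more than ``x`` below the best score
seen so far.  Extensions above a score threshold become high-scoring
segment pairs (HSPs).  Because a hash collision is betrayed by hopeless
flanking mismatches almost immediately, the seed block itself is assumed to
match and is never verified — checking flanks first is cheaper.

If an HSP covers the whole query it is promoted directly to an alignment.
Otherwise the top HSPs are extended into gapped *semi-global* alignments
(the entire query must be aligned, the reference is free at both ends) with
dynamic programming restricted to a band around the HSP diagonal.

Identities score +1, so the best possible score equals the query length
|Q| and the ratio T/|Q| of the top score to its maximum is a natural
confidence weight.  Mapping quality is

    MAPQ = (T - S) * (T/|Q|)^2,   P_error = 10^(-MAPQ/10)

where S <= T is the second-best alignment score (the caller substitutes
S = T/2 as a prior when only one alignment was found).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kindex import N_CODE

__all__ = [
    "ScoringScheme",
    "Hsp",
    "Alignment",
    "xdrop_extend",
    "gapped_extend",
    "compute_mapq",
    "mapq_to_perror",
]

NEG_INF = -(10**9)


@dataclass(frozen=True)
class ScoringScheme:
    """Match is fixed at +1 so that scores are comparable to |Q|.

    Gap scoring is affine: a gap of length g costs gap_open + g*gap_extend.
    ``x`` is the x-drop threshold for gapless extension; ``band`` the width
    of the terminal DP band; ``hsp_min_frac`` sets the HSP acceptance
    threshold as a fraction of the query length (ceil).
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    x: float = 16
    band: int = 16
    hsp_min_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.match != 1:
            raise ValueError("match score is fixed at +1")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if self.x <= 0 or self.band < 1:
            raise ValueError("x and band must be positive")

    def hsp_min_score(self, qlen: int) -> int:
        return int(-(-qlen * self.hsp_min_frac // 1))


@dataclass(frozen=True)
class Hsp:
    """Gapless high-scoring segment pair anchored on a seed.

    Query coordinates are 0-based half-open on the (possibly reverse
    complemented) query; ``ref_start`` is a global plus-strand coordinate.
    """

    q_start: int
    q_end: int
    ref_start: int
    strand: str  # '+' or '-'
    score: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + (self.q_end - self.q_start)

    @property
    def diagonal(self) -> int:
        return self.ref_start - self.q_start


@dataclass(frozen=True)
class Alignment:
    """Semi-global alignment of a whole query against a reference window."""

    ref_start: int  # global, 0-based, plus strand
    strand: str
    cigar: str
    score: int
    qlen: int

    def __post_init__(self) -> None:
        if self.score > self.qlen:
            raise ValueError("alignment score cannot exceed query length")


def xdrop_extend(
    query: np.ndarray,
    ref: np.ndarray,
    q_seed: int,
    r_seed: int,
    k: int,
    scoring: ScoringScheme,
    strand: str = "+",
    ref_lo: int = 0,
    ref_hi: Optional[int] = None,
) -> Optional[Hsp]:
    """Gapless x-drop extension of a length-k seed block.

    ``query`` and ``ref`` are uint8 code arrays; the seed aligns
    query[q_seed:q_seed+k] to ref[r_seed:r_seed+k] and contributes +k
    without verification.  ``ref_lo``/``ref_hi`` clip the extension (contig
    bounds).  Returns the maximal-scoring extension, or None if its score
    is below the HSP threshold.
    """
    if ref_hi is None:
        ref_hi = len(ref)
    match, mismatch, x = scoring.match, scoring.mismatch, scoring.x
    # Rightward from the seed end.
    score = 0
    best_r, off_r = 0, 0
    qi, ri = q_seed + k, r_seed + k
    while qi < len(query) and ri < ref_hi:
        qc, rc = query[qi], ref[ri]
        score += match if (qc == rc and qc != N_CODE) else mismatch
        qi += 1
        ri += 1
        if score > best_r:
            best_r, off_r = score, qi - (q_seed + k)
        elif score < best_r - x:
            break
    # Leftward from the seed start.
    score = 0
    best_l, off_l = 0, 0
    qi, ri = q_seed - 1, r_seed - 1
    while qi >= 0 and ri >= ref_lo:
        qc, rc = query[qi], ref[ri]
        score += match if (qc == rc and qc != N_CODE) else mismatch
        if score > best_l:
            best_l, off_l = score, (q_seed - qi)
        elif score < best_l - x:
            break
        qi -= 1
        ri -= 1
    total = k + best_l + best_r
    if total < scoring.hsp_min_score(len(query)):
        return None
    return Hsp(
        q_start=q_seed - off_l,
        q_end=q_seed + k + off_r,
        ref_start=r_seed - off_l,
        strand=strand,
        score=total,
    )


def _compress_cigar(ops: list[str]) -> str:
    out = []
    prev, run = None, 0
    for op in ops:
        if op == prev:
            run += 1
        else:
            if prev is not None:
                out.append(f"{run}{prev}")
            prev, run = op, 1
    if prev is not None:
        out.append(f"{run}{prev}")
    return "".join(out)


def gapped_extend(
    query: np.ndarray,
    ref: np.ndarray,
    hsp: Hsp,
    scoring: ScoringScheme,
    window_start: int = 0,
    band: Optional[int] = None,
) -> Optional[Alignment]:
    """Banded affine-gap semi-global alignment constrained to an HSP.

    ``ref`` is the reference window (uint8 codes) and ``window_start`` its
    global offset; the HSP diagonal (in window coordinates) centers a band
    of half-width ``band``.  The whole query must be aligned; reference
    overhangs at either end are free.  Returns None if the band cannot
    reach the query ends inside the window.
    """
    if band is None:
        band = scoring.band
    m = len(query)
    n = len(ref)
    if m == 0 or n == 0:
        return None
    d0 = hsp.diagonal - window_start  # window column minus query row
    # Clamp the band to the feasible diagonal range j - i for j in [0, n],
    # i in [0, m]; the whole query must fit, so row m needs a column <= n.
    lo_d = max(d0 - band, -m)
    hi_d = min(d0 + band, n)
    if lo_d > hi_d or m + lo_d > n or hi_d < 0:
        return None

    q = query.tolist()
    r = ref.tolist()
    mm, mis = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    open_cost = go + ge  # first gap base; each further base adds ge
    width = hi_d - lo_d + 1
    # Cell (i, off) is matrix cell (row i, column j = i + lo_d + off).
    # Three affine states: M (i,j aligned), D (gap in query, consumes ref),
    # I (gap in ref, consumes query).  Row 0 M-cells are free (semi-global
    # reference prefix); row 0 I/D are invalid except D, which would be a
    # leading deletion and is dominated by the free prefix.
    M = [[NEG_INF] * width for _ in range(m + 1)]
    D = [[NEG_INF] * width for _ in range(m + 1)]
    I = [[NEG_INF] * width for _ in range(m + 1)]
    TM = [[0] * width for _ in range(m + 1)]
    TD = [[0] * width for _ in range(m + 1)]
    TI = [[0] * width for _ in range(m + 1)]
    for off in range(width):
        j = lo_d + off
        if 0 <= j <= n:
            M[0][off] = 0
    for i in range(1, m + 1):
        qc = q[i - 1]
        Mi, Di, Ii = M[i], D[i], I[i]
        Mp, Dp, Ip = M[i - 1], D[i - 1], I[i - 1]
        TMi, TDi, TIi = TM[i], TD[i], TI[i]
        base = i + lo_d
        for off in range(width):
            j = base + off
            if j < 0 or j > n:
                continue
            # M: diagonal predecessor (i-1, j-1) = (i-1, off) in band coords.
            if j >= 1:
                best, st = Mp[off], 0
                if Dp[off] > best:
                    best, st = Dp[off], 1
                if Ip[off] > best:
                    best, st = Ip[off], 2
                if best > NEG_INF:
                    sub = mm if (qc == r[j - 1] and qc != N_CODE) else mis
                    Mi[off] = best + sub
                    TMi[off] = st
            # D: predecessor (i, j-1) = (i, off-1).
            if off >= 1:
                o = off - 1
                best, st = Mi[o] + open_cost, 0
                if Di[o] + ge > best:
                    best, st = Di[o] + ge, 1
                if Ii[o] + open_cost > best:
                    best, st = Ii[o] + open_cost, 2
                if best > NEG_INF // 2:
                    Di[off] = best
                    TDi[off] = st
            # I: predecessor (i-1, j) = (i-1, off+1).
            if off + 1 < width:
                o = off + 1
                best, st = Mp[o] + open_cost, 0
                if Dp[o] + open_cost > best:
                    best, st = Dp[o] + open_cost, 1
                if Ip[o] + ge > best:
                    best, st = Ip[o] + ge, 2
                if best > NEG_INF // 2:
                    Ii[off] = best
                    TIi[off] = st

    # Final: best state at i = m over valid columns (free reference suffix).
    best, best_off, best_state = NEG_INF, -1, 0
    base = m + lo_d
    for off in range(width):
        j = base + off
        if j < 0 or j > n:
            continue
        for state, row in ((0, M[m]), (1, D[m]), (2, I[m])):
            if row[off] > best:
                best, best_off, best_state = row[off], off, state
    if best <= NEG_INF // 2:
        return None

    # Traceback.  An optimal path never ends (or starts) with D because the
    # reference suffix (prefix) is free, and D rows carry its penalty.
    ops: list[str] = []
    i, off, state = m, best_off, best_state
    while i > 0:
        if state == 0:
            ops.append("M")
            state = TM[i][off]
            i -= 1
        elif state == 1:
            ops.append("D")
            state = TD[i][off]
            off -= 1
        else:
            ops.append("I")
            state = TI[i][off]
            i -= 1
            off += 1
    ops.reverse()
    q_used = sum(1 for op in ops if op != "D")
    if q_used != m:  # pragma: no cover - guarded by construction
        raise AssertionError("semi-global alignment must consume whole query")
    end_j = m + lo_d + best_off
    ref_used = sum(1 for op in ops if op != "I")
    start_j = end_j - ref_used  # window coordinate of the first ref base
    if start_j < 0 or end_j > n:
        return None
    return Alignment(
        ref_start=window_start + start_j,
        strand=hsp.strand,
        cigar=_compress_cigar(ops),
        score=int(best),
        qlen=m,
    )


def compute_mapq(T: int, S: float, qlen: int) -> int:
    """MAPQ = round_half_up((T - S) * (T/qlen)^2), clamped to [0, 254].

    ``S`` is the second-best score; pass S = T/2 when no second alignment
    was found (a prior, since the search terminates early on success).
    """
    if qlen <= 0:
        raise ValueError("qlen must be positive")
    if not (S <= T <= qlen):
        raise ValueError(f"need S <= T <= qlen, got S={S} T={T} qlen={qlen}")
    if T <= 0:
        return 0
    raw = (T - S) * (T / qlen) ** 2
    mapq = int(np.floor(raw + 0.5))
    return max(0, min(254, mapq))


def mapq_to_perror(mapq: float) -> float:
    """P_error = 10^(-MAPQ/10); MAPQ 0 -> 1.0, 10 -> 0.1."""
    if mapq < 0:
        raise ValueError("MAPQ must be non-negative")
    return 10.0 ** (-mapq / 10.0)
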