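"""Independent reference implementations used only to check the package.

Everything here is deliberately written from scratch (plain-Python big
ints, string slicing, exhaustive enumeration) so that it shares no code
path with the implementation under test.
"""

from __future__ import annotations

MASK64 = (1 << 64) - 1

_DIGIT = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def py_fmix64(x: int) -> int:
    """MurmurHash3 64-bit finalizer on Python big ints."""
    x &= MASK64
    x ^= x >> 33
    x = (x * 0xFF51AFD7ED558CCD) & MASK64
    x ^= x >> 33
    x = (x * 0xC4CEB9FE1A85EC53) & MASK64
    x ^= x >> 33
    return x


def word_to_int(word: str) -> int:
    v = 0
    for ch in word:
        v = v * 4 + _DIGIT[ch]
    return v


def revcomp_str(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def census(seq: str, k: int, H: int, t: int) -> dict[int, tuple[str, tuple[int, ...]]]:
    """Brute-force both-strand k-mer census, classified per slot.

    Returns slot -> (status, plus-strand positions) for every slot that
    occurs on either strand, with statuses pin / singleton / multi /
    excluded.  Hash collisions merge by construction of the keying.
    """
    plus: dict[int, list[int]] = {}
    minus: dict[int, int] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        s = py_fmix64(word_to_int(word)) % H
        plus.setdefault(s, []).append(i)
        s_rc = py_fmix64(word_to_int(revcomp_str(word))) % H
        minus[s_rc] = minus.get(s_rc, 0) + 1
    out: dict[int, tuple[str, tuple[int, ...]]] = {}
    for s in set(plus) | set(minus):
        p = plus.get(s, [])
        m = minus.get(s, 0)
        if len(p) > t or m > t:
            status = "excluded"
        elif len(p) == 1 and m == 0:
            status = "pin"
        elif len(p) == 1:
            status = "singleton"
        elif len(p) >= 2:
            status = "multi"
        else:
            continue  # occurs only on the minus strand: nothing indexed
        out[s] = (status, tuple(sorted(p)))
    return out


def exhaustive_gapless(
    query: str, ref: str, q_seed: int, r_seed: int, k: int,
    match: int = 1, mismatch: int = -2,
) -> tuple[int, int, int]:
    """Best gapless extension of a seed by enumerating every endpoint pair.

    Returns (score, left_extension, right_extension); the seed block
    contributes +k unverified, mirroring the flank-first contract.
    """

    def col(qi: int, ri: int) -> int:
        return match if query[qi] == ref[ri] and query[qi] != "N" else mismatch

    best = (k, 0, 0)
    max_l = min(q_seed, r_seed)
    max_r = min(len(query) - q_seed - k, len(ref) - r_seed - k)
    left_scores = [0]
    run = 0
    for l in range(1, max_l + 1):
        run += col(q_seed - l, r_seed - l)
        left_scores.append(run)
    right_scores = [0]
    run = 0
    for r in range(1, max_r + 1):
        run += col(q_seed + k + r - 1, r_seed + k + r - 1)
        right_scores.append(run)
    for l, ls in enumerate(left_scores):
        for r, rs in enumerate(right_scores):
            total = k + ls + rs
            if total > best[0]:
                best = (total, l, r)
    return best


def make_semiglobal_oracle(match=1, mismatch=-2, gap_open=-4, gap_extend=-1):
    """Biopython full-matrix semi-global aligner (free reference ends)."""
    import warnings

    from Bio import Align

    warnings.filterwarnings(
        "ignore", message=".*was renamed to.*", module="Bio.Align"
    )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # first gap base costs open+extend in the package's convention
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    aligner.query_left_open_gap_score = 0
    aligner.query_left_extend_gap_score = 0
    aligner.query_right_open_gap_score = 0
    aligner.query_right_extend_gap_score = 0

    def score(ref: str, query: str) -> int:
        return int(aligner.score(ref, query))

    return score
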