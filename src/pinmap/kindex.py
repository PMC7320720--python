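"""Hash-table k-mer index with pin/singleton anchors and linked-list rows.

The index stores the positions of every plus-strand k-mer of the reference
in a table of H 5-byte rows (one tally byte + one 32-bit value).  A word W
is encoded as a base-4 integer w(W) (A=0, C=1, G=2, T=3, 5'-most base most
significant) and assigned the slot s = murmur64(w) mod H, where murmur64 is
the MurmurHash3 64-bit finalizer.  Slots are classified by their abundance
on both reference strands:

* ``pin``       — found exactly once in the reference counting both strands;
                  a pin found in a read implies a single candidate location.
* ``singleton`` — once on the plus strand, but its reverse complement also
                  occurs on the plus strand (>= 2 candidates).
* ``multi``     — 2..t plus-strand occurrences, stored as a linked list
                  threaded through nearby empty rows with 7-bit skip
                  pointers (32-bit absolute pointers on overflow).
* over-abundant — more than t occurrences on either strand; excluded from
                  the index entirely (its row stays empty and may be reused
                  by a linked list).

Hash collisions merge position lists silently; verification is delegated to
alignment, which abandons a collided seed quickly on mismatched flanks.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import sympy

from .seqio import SequenceRecord

__all__ = [
    "IndexParams",
    "SlotRecord",
    "ReferenceIndex",
    "IndexCorruptionError",
    "CapacityError",
    "encode_word",
    "decode_word",
    "revcomp_word",
    "fmix64",
    "hash_slot",
    "choose_table_size",
    "classify_slot",
    "build_index",
    "lookup_positions",
    "serialize_index",
    "deserialize_index",
    "seq_to_codes",
    "codes_to_seq",
    "kmer_codes",
]

# Tally byte codes.  The high bit marks a present slot; rows with the high
# bit clear are empty or borrowed by a linked list (their own slot is absent).
TALLY_EMPTY = 0x00
TALLY_PIN = 0xFF
TALLY_SINGLETON = 0xFE
TALLY_HEAD_OVERFLOW = 0xFD  # head whose skip does not fit 7 bits; value = row ptr
TALLY_LIST_END = 0x7E  # value = coordinate
TALLY_LIST_OVERFLOW = 0x7F  # value = absolute row pointer
PRESENT_BIT = 0x80
MAX_HEAD_SKIP = 0x7C  # head codes 0x81..0xFC encode skips 1..124
MAX_LIST_SKIP = 0x7D  # interior codes 0x01..0x7D encode skips 1..125

N_CODE = 4  # genome code for N / any ambiguity

_BASE_TO_CODE = np.full(256, N_CODE, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_TO_CODE[_b] = _c
_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class IndexCorruptionError(RuntimeError):
    """A hash row chain is malformed (bad pointer, cycle, bad coordinate)."""


class CapacityError(ValueError):
    """Reference too large for 32-bit coordinates."""


def seq_to_codes(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 codes (A=0 C=1 G=2 T=3, N=4)."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def encode_word(word: str) -> int:
    """Encode a k-length ACGT word as a base-4 integer.

    The 5'-most base is the most significant digit.  Words containing N (or
    any non-ACGT letter) are not encodable and raise ``ValueError``; callers
    skip such words.
    """
    w = 0
    for ch in word:
        d = _BASE_TO_CODE[ord(ch)]
        if d == N_CODE:
            raise ValueError(f"word contains non-ACGT letter: {word!r}")
        w = (w << 2) | int(d)
    return w


def decode_word(w: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append("ACGT"[(w >> shift) & 3])
    return "".join(out)


def revcomp_word(w: int, k: int) -> int:
    """Reverse complement of an encoded word (an involution)."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (w & 3))
        w >>= 2
    return rc


_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)
_S33 = np.uint64(33)


def fmix64(x):
    """MurmurHash3 64-bit finalizer, bit-exact, scalar or ndarray."""
    x = np.uint64(x) if np.isscalar(x) or isinstance(x, int) else x.astype(np.uint64)
    with np.errstate(over="ignore"):
        x = x ^ (x >> _S33)
        x = x * _M1
        x = x ^ (x >> _S33)
        x = x * _M2
        x = x ^ (x >> _S33)
    return x


def hash_slot(w, H: int):
    """Slot of an encoded word: murmur64(w) mod H."""
    if H < 2:
        raise ValueError("H must be >= 2")
    h = fmix64(w)
    if np.isscalar(h) or h.ndim == 0:
        return int(h) % H
    return (h % np.uint64(H)).astype(np.int64)


MIN_TABLE_SIZE = 65_537
TABLE_RATIO = 1.6


def choose_table_size(reference_length: int, ratio: float = TABLE_RATIO) -> int:
    """Smallest prime >= ratio * reference_length, floored at 65,537.

    The ratio keeps the table substantially larger than the reference to
    limit collisions (a ~3.1 Gb genome gives a prime near 5e9).
    """
    if reference_length < 1:
        raise ValueError("reference_length must be >= 1")
    target = max(int(-(-reference_length * ratio // 1)), MIN_TABLE_SIZE)
    return int(sympy.nextprime(target - 1))


def classify_slot(plus_count: int, minus_count: int, t: int) -> str:
    """Classify a slot from its strand abundances under threshold t."""
    if plus_count < 0 or minus_count < 0:
        raise ValueError("counts must be non-negative")
    if plus_count > t or minus_count > t:
        return "excluded"
    if plus_count == 1 and minus_count == 0:
        return "pin"
    if plus_count == 1:
        return "singleton"
    if plus_count >= 2:
        return "multi"
    return "absent"


@dataclass(frozen=True)
class IndexParams:
    """Index construction parameters.

    k       word length in nt (default 24)
    t       maximum indexed slot abundance; slots occurring more than t
            times on either strand are excluded (default 32, 3 in the
            veryfast preset)
    H       table size in rows; prime, larger than the reference
    stride  smallest prime >= k+5, the base query-word visit interval
    """

    k: int = 24
    t: int = 32
    H: Optional[int] = None

    def __post_init__(self) -> None:
        if not (8 <= self.k <= 31):
            raise ValueError(f"k must be in [8, 31], got {self.k}")
        if self.t < 1:
            raise ValueError(f"t must be >= 1, got {self.t}")

    @property
    def stride(self) -> int:
        return int(sympy.nextprime(self.k + 4))


@dataclass(frozen=True)
class SlotRecord:
    slot: int
    status: str  # absent | pin | singleton | multi
    positions: tuple[int, ...] = ()


@dataclass
class ReferenceIndex:
    params: IndexParams
    catalog: list[tuple[str, int, int]]  # (name, global offset, length)
    genome: np.ndarray  # uint8 codes, N_CODE marks N
    tally: np.ndarray  # uint8[H]
    value: np.ndarray  # uint32[H]
    _offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._offsets = np.array([off for _, off, _ in self.catalog], dtype=np.int64)

    @property
    def H(self) -> int:
        return len(self.tally)

    @property
    def total_length(self) -> int:
        return int(len(self.genome))

    def contig_of(self, gpos: int) -> tuple[str, int, int]:
        """(name, offset, length) of the contig containing global position."""
        i = int(np.searchsorted(self._offsets, gpos, side="right")) - 1
        if i < 0 or gpos >= self.catalog[i][1] + self.catalog[i][2]:
            raise IndexError(f"global position {gpos} outside reference")
        return self.catalog[i]

    def contig_bounds(self, gpos: int) -> tuple[int, int]:
        _, off, length = self.contig_of(gpos)
        return off, off + length

    def to_global(self, name: str, local: int) -> int:
        for n, off, length in self.catalog:
            if n == name:
                return off + local
        raise KeyError(name)

    def header_info(self) -> list[tuple[str, int]]:
        return [(name, length) for name, _, length in self.catalog]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encoded plus-strand words, their reverse complements, and a validity
    mask (True where the window contains no N) for one code array.

    Returns arrays of length ``len(codes) - k + 1`` (empty if shorter).
    """
    n = len(codes) - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e.copy(), np.empty(0, dtype=bool)
    c64 = codes.astype(np.uint64)
    four = np.uint64(4)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            fwd = fwd * four + c64[j : j + n]
            # reverse complement read 3'->5' on the complement strand
            rev = rev * four + (np.uint64(3) - c64[k - 1 - j : k - 1 - j + n])
    bad = (codes == N_CODE).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    # rev computed with complemented N codes is garbage where invalid; the
    # mask gates every downstream use.
    return fwd, rev, valid


def _next_empty(tally: np.ndarray, start: int) -> int:
    """Index of the first empty row at or after ``start``, wrapping at H.

    Scans in growing chunks: at typical load factors the first chunk hits.
    """
    H = len(tally)
    pos = start
    scanned = 0
    chunk = 128
    while scanned < H:
        end = min(pos + chunk, H)
        idx = np.flatnonzero(tally[pos:end] == TALLY_EMPTY)
        if len(idx):
            return pos + int(idx[0])
        scanned += end - pos
        pos = end % H
        chunk = min(chunk * 4, H)
    raise IndexCorruptionError("hash table full: no empty row for linked list")


def build_index(
    sequences: Iterable[SequenceRecord],
    params: Optional[IndexParams] = None,
) -> ReferenceIndex:
    """Build the index from reference sequences.

    Every plus-strand k-mer without N is counted; slot classification
    follows :func:`classify_slot`.  Linked-list interior rows are taken from
    the nearest empty rows scanning forward from the head (wrapping at H),
    processing multi slots in increasing slot order.
    """
    params = params or IndexParams()
    k = params.k
    catalog: list[tuple[str, int, int]] = []
    code_chunks: list[np.ndarray] = []
    offset = 0
    for rec in sequences:
        catalog.append((rec.name, offset, len(rec.sequence)))
        code_chunks.append(seq_to_codes(rec.sequence))
        offset += len(rec.sequence)
    if not catalog:
        raise ValueError("no reference sequences")
    if offset >= 2**32:
        raise CapacityError("total reference length must be < 4 Gb")
    genome = (
        np.concatenate(code_chunks) if len(code_chunks) > 1 else code_chunks[0]
    )

    H = params.H if params.H is not None else choose_table_size(offset)
    if H <= offset:
        raise ValueError(f"H={H} must exceed the reference length {offset}")
    if H >= 2**32:
        raise ValueError("H must fit in 32-bit row pointers")
    if not sympy.isprime(H):
        raise ValueError(f"H={H} is not prime")

    # k-mers never span contig boundaries: enumerate per contig.
    slot_list, pos_list, rc_slot_list = [], [], []
    for (name, off, length), codes in zip(catalog, code_chunks):
        fwd, rev, valid = kmer_codes(codes, k)
        if len(fwd) == 0:
            continue
        pos = np.flatnonzero(valid).astype(np.int64)
        slot_list.append(hash_slot(fwd[valid], H))
        rc_slot_list.append(hash_slot(rev[valid], H))
        pos_list.append(pos + off)

    tally = np.zeros(H, dtype=np.uint8)
    value = np.zeros(H, dtype=np.uint32)
    index = ReferenceIndex(
        params=IndexParams(k=k, t=params.t, H=H),
        catalog=catalog,
        genome=genome,
        tally=tally,
        value=value,
    )
    if not slot_list:
        return index

    slots = np.concatenate(slot_list)
    positions = np.concatenate(pos_list)
    rc_slots = np.concatenate(rc_slot_list)

    plus_count = np.bincount(slots, minlength=H)
    minus_count = np.bincount(rc_slots, minlength=H)

    order = np.argsort(slots, kind="stable")
    s_sorted = slots[order]
    p_sorted = positions[order]
    uniq, start_idx, counts = np.unique(
        s_sorted, return_index=True, return_counts=True
    )
    ok = (counts <= params.t) & (minus_count[uniq] <= params.t)

    # Vectorized pins and singletons (abundance exactly 1 on plus strand).
    one = ok & (counts == 1)
    pin_mask = one & (minus_count[uniq] == 0)
    single_mask = one & ~pin_mask
    tally[uniq[pin_mask]] = TALLY_PIN
    value[uniq[pin_mask]] = p_sorted[start_idx[pin_mask]]
    tally[uniq[single_mask]] = TALLY_SINGLETON
    value[uniq[single_mask]] = p_sorted[start_idx[single_mask]]

    # Multi slots: reserve head rows first so list placement never steals a
    # head, then thread the lists in increasing slot order.
    multi_mask = ok & (counts >= 2)
    multi_slots = uniq[multi_mask]
    tally[multi_slots] = TALLY_HEAD_OVERFLOW  # placeholder; rewritten below
    for s, i0, m in zip(
        multi_slots, start_idx[multi_mask], counts[multi_mask]
    ):
        s = int(s)
        coords = np.sort(p_sorted[i0 : i0 + m])
        _write_list(tally, value, s, coords)
    return index


def _write_list(
    tally: np.ndarray, value: np.ndarray, head: int, coords: np.ndarray
) -> None:
    """Thread one multi-slot linked list through nearby empty rows."""
    H = len(tally)
    m = len(coords)
    e = _next_empty(tally, (head + 1) % H)
    gap = (e - head) % H
    ci = 0
    if 1 <= gap <= MAX_HEAD_SKIP:
        tally[head] = PRESENT_BIT | gap
        value[head] = coords[0]
        ci = 1
    else:
        tally[head] = TALLY_HEAD_OVERFLOW
        value[head] = e
    cur = e
    while True:
        if ci == m - 1:
            tally[cur] = TALLY_LIST_END
            value[cur] = coords[ci]
            return
        e = _next_empty(tally, (cur + 1) % H)
        gap = (e - cur) % H
        if gap <= MAX_LIST_SKIP:
            tally[cur] = gap
            value[cur] = coords[ci]
            ci += 1
        else:
            tally[cur] = TALLY_LIST_OVERFLOW
            value[cur] = e
        cur = e


def lookup_positions(index: ReferenceIndex, slot: int) -> SlotRecord:
    """Decode the row(s) for a slot into a :class:`SlotRecord`.

    Slots excluded at build time for over-abundance are indistinguishable
    from never-seen slots (both decode as ``absent``): their rows are left
    empty and may be borrowed by linked lists.
    """
    H = index.H
    if not (0 <= slot < H):
        raise ValueError(f"slot {slot} outside [0, {H})")
    tally, value = index.tally, index.value
    glen = index.total_length
    t0 = int(tally[slot])
    if t0 == TALLY_PIN or t0 == TALLY_SINGLETON:
        coord = int(value[slot])
        if coord >= glen:
            raise IndexCorruptionError(
                f"slot {slot}: coordinate {coord} beyond reference end"
            )
        status = "pin" if t0 == TALLY_PIN else "singleton"
        return SlotRecord(slot, status, (coord,))
    if t0 == TALLY_EMPTY or not (t0 & PRESENT_BIT):
        # Empty, or a row borrowed as a list interior: this slot is absent.
        return SlotRecord(slot, "absent")

    positions: list[int] = []
    if t0 == TALLY_HEAD_OVERFLOW:
        cur = int(value[slot])
    else:
        positions.append(int(value[slot]))
        cur = (slot + (t0 & 0x7F)) % H
    seen = {slot}
    max_steps = 4 * index.params.t + 16
    for _ in range(max_steps):
        if not (0 <= cur < H):
            raise IndexCorruptionError(f"slot {slot}: pointer {cur} out of range")
        if cur in seen:
            raise IndexCorruptionError(f"slot {slot}: cycle in linked list")
        seen.add(cur)
        tc = int(tally[cur])
        if tc == TALLY_LIST_END:
            positions.append(int(value[cur]))
            break
        if tc == TALLY_LIST_OVERFLOW:
            cur = int(value[cur])
        elif 0x01 <= tc <= MAX_LIST_SKIP:
            positions.append(int(value[cur]))
            cur = (cur + tc) % H
        else:
            raise IndexCorruptionError(
                f"slot {slot}: unexpected tally 0x{tc:02X} inside list"
            )
    else:
        raise IndexCorruptionError(f"slot {slot}: linked list does not terminate")
    if any(p >= glen for p in positions):
        raise IndexCorruptionError(f"slot {slot}: coordinate beyond reference end")
    return SlotRecord(slot, "multi", tuple(positions))


MAGIC = b"URPYIDX1"
FORMAT_VERSION = 1
_ROW_DTYPE = np.dtype([("tally", "u1"), ("value", "<u4")])  # 5 bytes/row


def serialize_index(index: ReferenceIndex, path) -> None:
    """Write the index container: magic, version, params, catalog, packed
    genome, then exactly H 5-byte rows (little-endian)."""
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<IIIQ", FORMAT_VERSION, index.params.k,
                             index.params.t, index.H))
        fh.write(struct.pack("<I", len(index.catalog)))
        for name, off, length in index.catalog:
            nb = name.encode("utf-8")
            fh.write(struct.pack("<H", len(nb)))
            fh.write(nb)
            fh.write(struct.pack("<QQ", off, length))
        fh.write(struct.pack("<Q", index.total_length))
        fh.write(index.genome.tobytes())
        rows = np.empty(index.H, dtype=_ROW_DTYPE)
        rows["tally"] = index.tally
        rows["value"] = index.value
        fh.write(rows.tobytes())


def _read_exact(fh, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise ValueError("truncated index file")
    return data


def deserialize_index(path) -> ReferenceIndex:
    with open(path, "rb") as fh:
        if _read_exact(fh, 8) != MAGIC:
            raise ValueError("not an index file (bad magic)")
        version, k, t, H = struct.unpack("<IIIQ", _read_exact(fh, 20))
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported index format version {version}")
        (n_seqs,) = struct.unpack("<I", _read_exact(fh, 4))
        catalog = []
        for _ in range(n_seqs):
            (nlen,) = struct.unpack("<H", _read_exact(fh, 2))
            name = _read_exact(fh, nlen).decode("utf-8")
            off, length = struct.unpack("<QQ", _read_exact(fh, 16))
            catalog.append((name, off, length))
        (glen,) = struct.unpack("<Q", _read_exact(fh, 8))
        genome = np.frombuffer(_read_exact(fh, glen), dtype=np.uint8).copy()
        rows = np.frombuffer(_read_exact(fh, 5 * H), dtype=_ROW_DTYPE).copy()
        if fh.read(1):
            raise ValueError("trailing bytes after index rows")
    return ReferenceIndex(
        params=IndexParams(k=k, t=t, H=int(H)),
        catalog=catalog,
        genome=genome,
        tally=rows["tally"].copy(),
        value=rows["value"].copy(),
    )
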