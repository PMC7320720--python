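"""Locus-anchored mapping benchmark on simulated diploid reads.

The benchmark builds a diploid genome by applying phased variants to a
reference, simulates read pairs anchored on loci (each pair must cover its
locus with R1 or R2), injects substitution errors at the rate implied by
per-base Phred qualities, maps the reads, and scores the result with four
sensitivity/error metrics per source genome:

* ``S_r`` — % of all reads mapped to the correct coordinate with MAPQ >= 10
* ``E_r`` — % of confident (MAPQ >= 10) reads mapped to a wrong position
* ``S_l`` — % of loci with >= 3 confident reads whose majority is correct
* ``E_l`` — % of loci with >= 3 confident reads in which a majority maps to
  the *same* incorrect position (a systematic error, the kind most likely
  to contaminate downstream analysis)

computed separately for reads drawn from the reference (``ref``) and from
the variant genome (``var``), eight metrics in all.  Pairwise method
summaries (MI/IM/TI) and a MAPQ calibration table complete the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import (
    FLAG_READ2,
    FLAG_REVERSE,
    FLAG_UNMAPPED,
    SamRecord,
    SequenceRecord,
)

__all__ = [
    "VariantSpec",
    "DiploidGenome",
    "ReadPairTruth",
    "QualityModel",
    "MetricsReport",
    "Comparison",
    "CalibrationPoint",
    "Verdict",
    "build_diploid",
    "simulate_pairs",
    "inject_errors",
    "score_mapping",
    "compute_metrics",
    "compare_methods",
    "render_comparison",
    "calibration_table",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class VariantSpec:
    """A SNP or indel on one haplotype, VCF-style (1-based, anchored).

    ``ref``/``alt`` follow VCF conventions: indels share a leading anchor
    base.  ``haplotype`` is meaningful when ``phased``; unphased variants
    are assigned a haplotype by seeded coin flip in :func:`build_diploid`.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    haplotype: int = 0
    phased: bool = True

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"variant at {self.chrom}:{self.pos} has ref == alt")
        if self.haplotype not in (0, 1):
            raise ValueError("haplotype must be 0 or 1")


@dataclass
class DiploidGenome:
    """Two haplotypes of one chromosome plus haplotype->reference maps.

    ``maps[h][i]`` is the reference coordinate (0-based) of haplotype-h
    base i; inserted bases map to their anchor base.
    """

    chrom: str
    haplotypes: tuple[str, str]
    maps: tuple[np.ndarray, np.ndarray]
    variants: tuple[list[VariantSpec], list[VariantSpec]]

    def to_reference(self, haplotype: int, pos: int) -> int:
        return int(self.maps[haplotype][pos])


def build_diploid(
    reference: SequenceRecord,
    variants: Sequence[VariantSpec],
    seed: int = 0,
) -> DiploidGenome:
    """Apply variants to a reference, producing two haplotypes.

    Variants are applied left to right; unphased variants are assigned to a
    haplotype by a seeded coin flip.  Variants overlapping a previous
    variant's reference span on the same haplotype are an error.
    """
    rng = np.random.default_rng(seed)
    per_hap: tuple[list[VariantSpec], list[VariantSpec]] = ([], [])
    for v in sorted(variants, key=lambda v: v.pos):
        if v.chrom != reference.name:
            raise ValueError(f"variant chrom {v.chrom!r} != {reference.name!r}")
        ref_at = reference.sequence[v.pos - 1 : v.pos - 1 + len(v.ref)]
        if ref_at != v.ref:
            raise ValueError(
                f"variant at {v.chrom}:{v.pos}: ref allele {v.ref!r} does not "
                f"match reference {ref_at!r}"
            )
        h = v.haplotype if v.phased else int(rng.integers(0, 2))
        per_hap[h].append(v)

    haps, maps = [], []
    for h in (0, 1):
        seq_parts: list[str] = []
        map_parts: list[np.ndarray] = []
        cursor = 0
        last_end = -1
        offenders = []
        for v in per_hap[h]:
            start = v.pos - 1
            if start < last_end:
                offenders.append(v)
                continue
            seq_parts.append(reference.sequence[cursor:start])
            map_parts.append(np.arange(cursor, start, dtype=np.int64))
            seq_parts.append(v.alt)
            # SNP/MNP bases map positionally; inserted bases map to the
            # anchor; a deletion consumes reference without emitting bases.
            alt_map = [start + min(i, len(v.ref) - 1) for i in range(len(v.alt))]
            map_parts.append(np.array(alt_map, dtype=np.int64))
            cursor = start + len(v.ref)
            last_end = cursor
        if offenders:
            locs = ", ".join(f"{v.chrom}:{v.pos}" for v in offenders)
            raise ValueError(f"overlapping variants on haplotype {h}: {locs}")
        seq_parts.append(reference.sequence[cursor:])
        map_parts.append(np.arange(cursor, len(reference.sequence), dtype=np.int64))
        haps.append("".join(seq_parts))
        maps.append(
            np.concatenate(map_parts)
            if map_parts
            else np.empty(0, dtype=np.int64)
        )
    return DiploidGenome(
        chrom=reference.name,
        haplotypes=(haps[0], haps[1]),
        maps=(maps[0], maps[1]),
        variants=per_hap,
    )


def write_vcf(
    variants: Sequence[VariantSpec], contigs: Sequence[tuple[str, int]], path
) -> None:
    """Write variants as a minimal single-sample VCF (v4.2).

    Phased variants carry a phased GT (``1|0`` for haplotype 0, ``0|1``
    for haplotype 1); unphased ones ``0/1``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            if v.phased:
                gt = "1|0" if v.haplotype == 0 else "0|1"
            else:
                gt = "0/1"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_vcf(path) -> list[VariantSpec]:
    """Read the first sample's het variants from a VCF via pysam.

    GT ``a|b`` puts allele a on haplotype 0 and b on haplotype 1; a
    homozygous ALT yields one spec per haplotype.
    """
    import pysam

    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            sample = rec.samples[0] if rec.samples else None
            if sample is None or sample.get("GT") is None:
                out.append(VariantSpec(rec.chrom, rec.pos, rec.ref, alt, 0, False))
                continue
            gt = sample["GT"]
            phased = bool(sample.phased)
            carriers = [h for h, a in enumerate(gt[:2]) if a and a > 0]
            if not carriers:
                continue
            if not phased and len(carriers) == 1:
                out.append(VariantSpec(rec.chrom, rec.pos, rec.ref, alt, 0, False))
            else:
                for h in carriers:
                    out.append(
                        VariantSpec(rec.chrom, rec.pos, rec.ref, alt, h, True)
                    )
    return out


@dataclass(frozen=True)
class ReadPairTruth:
    """Ground truth for one simulated pair, in reference coordinates."""

    locus_id: int
    origin: str  # "ref" or "var"
    chrom: str
    r1_start: int
    r1_strand: str
    r2_start: int
    r2_strand: str
    frag_len: int


def simulate_pairs(
    seq: str,
    loci: Sequence[int],
    pairs_per_locus: int,
    L: int,
    rng: np.random.Generator,
    chrom: str = "chr1",
    origin: str = "ref",
    frag_mean: float = 350.0,
    frag_sd: float = 35.0,
    frag_max: int = 1000,
    coord_map: Optional[np.ndarray] = None,
    locus_ids: Optional[Sequence[int]] = None,
) -> list[tuple[SequenceRecord, SequenceRecord, ReadPairTruth]]:
    """Simulate FR read pairs anchored on loci.

    For each locus, ``pairs_per_locus`` pairs are placed at random
    positions such that R1 or R2 contains the locus.  Fragment lengths are
    Normal(frag_mean, frag_sd) truncated to [L, frag_max].  Which physical
    end of the fragment is R1 is decided by a coin flip, so R1 maps to
    either strand.  ``coord_map`` (haplotype->reference) converts truth
    coordinates when simulating from a variant haplotype; reads whose
    loci sit too close to the sequence end to place any fragment are
    skipped.  Reads carry no qualities; see :func:`inject_errors`.
    """
    out = []
    n = len(seq)
    ids = list(locus_ids) if locus_ids is not None else list(range(len(loci)))
    for locus, lid in zip(loci, ids):
        for p in range(pairs_per_locus):
            f = int(np.clip(round(rng.normal(frag_mean, frag_sd)), L, frag_max))
            f = min(f, n)
            # Valid fragment starts: locus inside [s, s+L) or [s+f-L, s+f).
            cands = []
            for lo, hi in ((locus - L + 1, locus), (locus - f + 1, locus - f + L)):
                lo, hi = max(lo, 0), min(hi, n - f)
                if lo <= hi:
                    cands.append((lo, hi))
            if not cands:
                continue  # locus unplaceable at this fragment length
            total = sum(hi - lo + 1 for lo, hi in cands)
            r = int(rng.integers(0, total))
            for lo, hi in cands:
                if r <= hi - lo:
                    s = lo + r
                    break
                r -= hi - lo + 1
            left = seq[s : s + L]
            right = revcomp(seq[s + f - L : s + f])
            r1_is_left = bool(rng.integers(0, 2))
            name = f"{origin}_L{lid}_P{p}"
            if coord_map is not None:
                g1, g2 = int(coord_map[s]), int(coord_map[s + f - L])
            else:
                g1, g2 = s, s + f - L
            if r1_is_left:
                r1, r2 = left, right
                truth = ReadPairTruth(lid, origin, chrom, g1, "+", g2, "-", f)
            else:
                r1, r2 = right, left
                truth = ReadPairTruth(lid, origin, chrom, g2, "-", g1, "+", f)
            out.append(
                (
                    SequenceRecord(name + "/1", r1),
                    SequenceRecord(name + "/2", r2),
                    truth,
                )
            )
    return out


@dataclass
class QualityModel:
    """Pool of read-length quality strings.

    The synthetic profile emulates position-dependent Illumina quality
    decay: mean Q38 over the first 100 cycles falling linearly to Q25 at
    cycle 150 (interpolated for other read lengths), with per-base
    Gaussian jitter (sd 3) clamped to [2, 41].  ``from_fastq`` instead
    samples quality strings from a donor FASTQ.
    """

    L: int
    pool: Optional[list[list[int]]] = None

    @classmethod
    def from_fastq(cls, records: Iterable[SequenceRecord], L: int) -> "QualityModel":
        pool = [
            rec.qualities
            for rec in records
            if rec.qualities is not None and len(rec.qualities) == L
        ]
        if not pool:
            raise ValueError(f"donor FASTQ contains no length-{L} quality strings")
        return cls(L=L, pool=pool)

    def sample(self, rng: np.random.Generator) -> list[int]:
        if self.pool is not None:
            return self.pool[int(rng.integers(0, len(self.pool)))]
        cyc = np.arange(self.L)
        plateau = min(100, self.L)
        mean = np.full(self.L, 38.0)
        if self.L > plateau:
            mean[plateau:] = 38.0 + (25.0 - 38.0) * (
                (cyc[plateau:] - (plateau - 1)) / max(self.L - plateau, 1)
            )
        q = np.clip(np.round(mean + rng.normal(0, 3, self.L)), 2, 41)
        return [int(v) for v in q]


def inject_errors(
    read: SequenceRecord, qualities: Sequence[int], rng: np.random.Generator
) -> SequenceRecord:
    """Substitute each base with probability 10^(-q/10); attach qualities.

    Only substitutions are injected (Illumina indel errors are very rare);
    the substituted base is uniform over the three other bases.
    """
    if len(qualities) != len(read.sequence):
        raise ValueError("quality string length != read length")
    q = np.asarray(qualities, dtype=float)
    p = 10.0 ** (-q / 10.0)
    hits = np.flatnonzero(rng.random(len(p)) < p)
    seq = list(read.sequence)
    for i in hits:
        base = seq[i]
        if base == "N":
            continue
        choices = [b for b in "ACGT" if b != base]
        seq[i] = choices[int(rng.integers(0, 3))]
    return SequenceRecord(read.name, "".join(seq), list(int(v) for v in qualities))


@dataclass(frozen=True)
class Verdict:
    """Per-read scoring outcome against the simulation truth."""

    locus_id: int
    origin: str
    mate: int  # 1 or 2
    mapq: int
    mapped: bool
    confident: bool
    correct: bool
    reported_chrom: str = "*"
    reported_start: int = -1  # 0-based

    @property
    def kind(self) -> str:
        if not self.confident:
            return "not-confident"
        return "correct-confident" if self.correct else "wrong-confident"


def score_mapping(
    sam_records: Iterable[SamRecord],
    truths: dict[str, ReadPairTruth],
    tolerance: int = 10,
    mapq_threshold: int = 10,
) -> list[Verdict]:
    """Judge each primary SAM record against the simulation truth.

    A read is *confident* iff MAPQ >= ``mapq_threshold`` (and mapped);
    *correct* iff reference name and strand match the truth and the
    reported leftmost coordinate is within ``tolerance`` bases.
    """
    out = []
    for rec in sam_records:
        truth = truths.get(rec.qname)
        if truth is None:
            raise KeyError(f"SAM read {rec.qname!r} not in truth set")
        mate = 2 if rec.flag & FLAG_READ2 else 1
        t_start = truth.r1_start if mate == 1 else truth.r2_start
        t_strand = truth.r1_strand if mate == 1 else truth.r2_strand
        mapped = not (rec.flag & FLAG_UNMAPPED)
        if not mapped:
            out.append(Verdict(truth.locus_id, truth.origin, mate, 0, False, False, False))
            continue
        strand = "-" if rec.flag & FLAG_REVERSE else "+"
        start0 = rec.pos - 1
        correct = (
            rec.rname == truth.chrom
            and strand == t_strand
            and abs(start0 - t_start) <= tolerance
        )
        confident = rec.mapq >= mapq_threshold
        out.append(
            Verdict(
                truth.locus_id, truth.origin, mate, rec.mapq, True,
                confident, correct, rec.rname, start0,
            )
        )
    return out


@dataclass
class MetricsReport:
    """The eight benchmark metrics, as percentages, plus raw counts."""

    sr_ref: float = float("nan")
    er_ref: float = float("nan")
    sl_ref: float = float("nan")
    el_ref: float = float("nan")
    sr_var: float = float("nan")
    er_var: float = float("nan")
    sl_var: float = float("nan")
    el_var: float = float("nan")
    counts: dict = field(default_factory=dict)

    def metric(self, name: str, origin: str) -> float:
        return getattr(self, f"{name}_{origin}")

    def as_dict(self) -> dict[str, float]:
        return {
            f"{m}_{o}": self.metric(m, o)
            for o in ("ref", "var")
            for m in ("sr", "er", "sl", "el")
        }


def _cluster_majority(
    wrongs: list[tuple[str, int]], need: int, tolerance: int
) -> bool:
    """True if > ``need`` of the confident reads share one wrong position
    (clustered within ``tolerance``)."""
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in wrongs:
        by_chrom.setdefault(chrom, []).append(pos)
    for positions in by_chrom.values():
        positions.sort()
        i = 0
        for j in range(len(positions)):
            while positions[j] - positions[i] > tolerance:
                i += 1
            if j - i + 1 > need:
                return True
    return False


def compute_metrics(
    verdicts: Iterable[Verdict],
    min_confident: int = 3,
    tolerance: int = 10,
) -> MetricsReport:
    """Aggregate verdicts into the eight benchmark metrics.

    ``S_l`` counts all loci in its denominator; ``E_l`` only loci with
    >= ``min_confident`` confident reads ("majority" is strictly more than
    half of the confident reads; same-wrong-position clusters use the
    coordinate tolerance).  With zero confident reads E_r is 0; with zero
    qualifying loci E_l is 0.
    """
    report = MetricsReport()
    by_origin: dict[str, list[Verdict]] = {}
    for v in verdicts:
        by_origin.setdefault(v.origin, []).append(v)
    for origin, vs in by_origin.items():
        n_reads = len(vs)
        n_cc = sum(1 for v in vs if v.kind == "correct-confident")
        n_conf = sum(1 for v in vs if v.confident)
        n_wc = sum(1 for v in vs if v.kind == "wrong-confident")
        sr = 100.0 * n_cc / n_reads if n_reads else 0.0
        er = 100.0 * n_wc / n_conf if n_conf else 0.0

        loci: dict[int, list[Verdict]] = {}
        for v in vs:
            loci.setdefault(v.locus_id, []).append(v)
        n_loci = len(loci)
        n_sl = n_el = n_qual = 0
        for lv in loci.values():
            conf = [v for v in lv if v.confident]
            if len(conf) < min_confident:
                continue
            n_qual += 1
            need = len(conf) // 2  # majority: strictly more than half
            if sum(1 for v in conf if v.correct) > need:
                n_sl += 1
            else:
                wrongs = [
                    (v.reported_chrom, v.reported_start)
                    for v in conf
                    if not v.correct
                ]
                if _cluster_majority(wrongs, need, tolerance):
                    n_el += 1
        sl = 100.0 * n_sl / n_loci if n_loci else 0.0
        el = 100.0 * n_el / n_qual if n_qual else 0.0
        for name, val in (("sr", sr), ("er", er), ("sl", sl), ("el", el)):
            setattr(report, f"{name}_{origin}", val)
        report.counts[origin] = {
            "reads": n_reads,
            "correct_confident": n_cc,
            "confident": n_conf,
            "wrong_confident": n_wc,
            "loci": n_loci,
            "qualifying_loci": n_qual,
            "majority_correct_loci": n_sl,
            "systematic_error_loci": n_el,
        }
    return report


@dataclass(frozen=True)
class Comparison:
    x: str
    y: str
    mi: float  # mean improvement of x over y
    im: int  # metrics (of 8) where x is strictly better


_COMBOS = [("r", "ref"), ("l", "ref"), ("r", "var"), ("l", "var")]


def compare_methods(
    reports: dict[str, MetricsReport],
) -> tuple[list[Comparison], dict[str, float]]:
    """All ordered pairwise comparisons plus total improvement per method.

    MI_XY is the mean over the four (read/locus x genome) combinations of
    S_X - S_Y - E_X + E_Y; IM_XY counts the metrics (of eight) where X is
    strictly better (higher S, lower E); TI_X sums MI_XY over Y != X.
    """
    if len(reports) < 2:
        raise ValueError("need at least two method reports")
    names = list(reports)
    for name, rep in reports.items():
        if any(math.isnan(v) for v in rep.as_dict().values()):
            raise ValueError(f"report {name!r} is missing metrics")
    comparisons = []
    ti = {name: 0.0 for name in names}
    for x in names:
        for y in names:
            if x == y:
                continue
            rx, ry = reports[x], reports[y]
            mi = sum(
                rx.metric(f"s{u}", o) - ry.metric(f"s{u}", o)
                - rx.metric(f"e{u}", o) + ry.metric(f"e{u}", o)
                for u, o in _COMBOS
            ) / 4.0
            im = sum(
                1 for u, o in _COMBOS
                if rx.metric(f"s{u}", o) > ry.metric(f"s{u}", o)
            ) + sum(
                1 for u, o in _COMBOS
                if rx.metric(f"e{u}", o) < ry.metric(f"e{u}", o)
            )
            comparisons.append(Comparison(x, y, mi, im))
            ti[x] += mi
    return comparisons, ti


def render_comparison(cmp_xy: Comparison, cmp_yx: Comparison) -> str:
    """Render a pairwise comparison, e.g. ``"BWA >5(2.0) Bowtie2"``.

    ``>>``/``<<`` mark a clean sweep of all eight metrics; otherwise the
    count of better metrics on the winning side is shown, with the mean
    improvement of X over Y in parentheses.
    """
    x, y, mi = cmp_xy.x, cmp_xy.y, cmp_xy.mi
    mi_s = f"({mi:.1f})"
    if cmp_xy.im == 8:
        op = ">>"
    elif cmp_yx.im == 8:
        op = "<<"
    elif cmp_xy.im >= cmp_yx.im:
        op = f">{cmp_xy.im}"
    else:
        op = f"<{cmp_yx.im}"
    return f"{x} {op}{mi_s} {y}"


@dataclass(frozen=True)
class CalibrationPoint:
    q: int
    n: int
    n_error: int
    f_error: float
    q_measured: float  # +inf when no errors observed

    def __post_init__(self) -> None:
        if self.n_error > 0:
            expected = -10.0 * math.log10(self.f_error)
            if abs(self.q_measured - expected) > 1e-9:
                raise ValueError("inconsistent calibration point")


def calibration_table(
    verdicts: Iterable[Verdict], min_n: int = 50
) -> list[CalibrationPoint]:
    """Measured mapping quality per reported MAPQ value.

    For each reported q with at least ``min_n`` mapped reads,
    q_measured = -10*log10(n_error/n); +inf when no read at q is wrong.
    """
    groups: dict[int, list[Verdict]] = {}
    for v in verdicts:
        if v.mapped:
            groups.setdefault(v.mapq, []).append(v)
    points = []
    for q in sorted(groups):
        vs = groups[q]
        if len(vs) < min_n:
            continue
        n_err = sum(1 for v in vs if not v.correct)
        f = n_err / len(vs)
        qm = -10.0 * math.log10(f) if n_err else float("inf")
        points.append(CalibrationPoint(q, len(vs), n_err, f, qm))
    return points
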