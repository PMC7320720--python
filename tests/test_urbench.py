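import math

import numpy as np
import pytest

from pinmap.seqio import FLAG_READ1, FLAG_READ2, FLAG_REVERSE, SamRecord, SequenceRecord
from pinmap.urbench import (
    CalibrationPoint,
    Comparison,
    MetricsReport,
    QualityModel,
    ReadPairTruth,
    VariantSpec,
    Verdict,
    build_diploid,
    calibration_table,
    compare_methods,
    compute_metrics,
    inject_errors,
    read_vcf,
    render_comparison,
    score_mapping,
    simulate_pairs,
    write_vcf,
)


@pytest.fixture()
def reference():
    rng = np.random.default_rng(20)
    return SequenceRecord("chr1", "".join(rng.choice(list("ACGT"), size=5000)))


class TestBuildDiploid:
    def test_no_variants_identity(self, reference):
        d = build_diploid(reference, [])
        for h in (0, 1):
            assert d.haplotypes[h] == reference.sequence
            assert np.array_equal(d.maps[h], np.arange(len(reference.sequence)))

    def test_single_snp_on_hap0(self, reference):
        ref_base = reference.sequence[99]
        alt = "A" if ref_base != "A" else "C"
        v = VariantSpec("chr1", 100, ref_base, alt, haplotype=0, phased=True)
        d = build_diploid(reference, [v])
        diffs = [
            i for i, (a, b) in enumerate(zip(d.haplotypes[0], reference.sequence))
            if a != b
        ]
        assert diffs == [99]
        assert d.haplotypes[1] == reference.sequence

    def test_deletion_coordinate_map(self, reference):
        # 3 bp deletion at position p (1-based anchor 100): hap positions
        # before the anchor map identically, after it with offset +3
        p = 100
        ref = reference.sequence[p - 1 : p + 3]
        v = VariantSpec("chr1", p, ref, ref[0], haplotype=1, phased=True)
        d = build_diploid(reference, [v])
        assert len(d.haplotypes[1]) == len(reference.sequence) - 3
        m = d.maps[1]
        assert all(m[x] == x for x in range(p))
        assert all(m[x] == x + 3 for x in range(p, p + 50))

    def test_unphased_assignment_is_seeded(self, reference):
        vs = []
        for p in range(100, 2100, 100):
            b = reference.sequence[p - 1]
            vs.append(VariantSpec("chr1", p, b, "A" if b != "A" else "C",
                                  phased=False))
        d1 = build_diploid(reference, vs, seed=5)
        d2 = build_diploid(reference, vs, seed=5)
        d3 = build_diploid(reference, vs, seed=6)
        assert d1.haplotypes == d2.haplotypes
        assert d1.haplotypes != d3.haplotypes  # some coin must differ

    def test_ref_mismatch_rejected(self, reference):
        base = reference.sequence[49]
        wrong = "A" if base != "A" else "C"
        v = VariantSpec("chr1", 50, wrong, base)
        with pytest.raises(ValueError, match="does not match"):
            build_diploid(reference, [v])

    def test_overlapping_variants_rejected(self, reference):
        ref = reference.sequence[99:104]
        vs = [
            VariantSpec("chr1", 100, ref, ref[0], haplotype=0),
            VariantSpec("chr1", 102, reference.sequence[101],
                        "A" if reference.sequence[101] != "A" else "C",
                        haplotype=0),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            build_diploid(reference, vs)


class TestVcfRoundtrip:
    def test_roundtrip(self, tmp_path, reference):
        vs = [
            VariantSpec("chr1", 100, reference.sequence[99], "A"
                        if reference.sequence[99] != "A" else "C", 0, True),
            VariantSpec("chr1", 200, reference.sequence[199], "G"
                        if reference.sequence[199] != "G" else "T", 1, True),
            VariantSpec("chr1", 300, reference.sequence[299], "T"
                        if reference.sequence[299] != "T" else "A", 0, False),
        ]
        path = tmp_path / "v.vcf"
        write_vcf(vs, [("chr1", len(reference.sequence))], path)
        back = read_vcf(path)
        assert [(v.pos, v.ref, v.alt) for v in back] == [
            (v.pos, v.ref, v.alt) for v in vs
        ]
        assert [v.phased for v in back] == [True, True, False]
        assert [v.haplotype for v in back][:2] == [0, 1]


class TestSimulatePairs:
    def test_every_pair_covers_its_locus(self, reference):
        rng = np.random.default_rng(1)
        loci = [500, 1500, 2500, 3500, 4500]
        sims = simulate_pairs(reference.sequence, loci, 10, 150, rng)
        assert len(sims) == 50
        for r1, r2, t in sims:
            locus = loci[t.locus_id]
            in_r1 = t.r1_start <= locus < t.r1_start + 150
            in_r2 = t.r2_start <= locus < t.r2_start + 150
            assert in_r1 or in_r2

    def test_reads_match_genome(self, reference):
        from pinmap.urbench import revcomp

        rng = np.random.default_rng(2)
        sims = simulate_pairs(reference.sequence, [2000], 5, 150, rng)
        for r1, r2, t in sims:
            for rec, start, strand in (
                (r1, t.r1_start, t.r1_strand),
                (r2, t.r2_start, t.r2_strand),
            ):
                window = reference.sequence[start : start + 150]
                expected = window if strand == "+" else revcomp(window)
                assert rec.sequence == expected

    def test_determinism(self, reference):
        a = simulate_pairs(reference.sequence, [1000], 5, 150,
                           np.random.default_rng(3))
        b = simulate_pairs(reference.sequence, [1000], 5, 150,
                           np.random.default_rng(3))
        assert [(r1.sequence, r2.sequence, t) for r1, r2, t in a] == [
            (r1.sequence, r2.sequence, t) for r1, r2, t in b
        ]

    def test_abutting_mates_cover_locus_exactly_once(self, reference):
        rng = np.random.default_rng(4)
        sims = simulate_pairs(
            reference.sequence, [2500], 20, 150, rng,
            frag_mean=300, frag_sd=0,
        )
        for r1, r2, t in sims:
            assert t.frag_len == 300  # R1 and R2 abut
            in_r1 = t.r1_start <= 2500 < t.r1_start + 150
            in_r2 = t.r2_start <= 2500 < t.r2_start + 150
            assert in_r1 != in_r2


class TestInjectErrors:
    def test_q40_rate(self):
        rng = np.random.default_rng(5)
        n = 100_000
        read = SequenceRecord("r", "A" * n)
        out = inject_errors(read, [40] * n, rng)
        n_sub = sum(1 for c in out.sequence if c != "A")
        expected, sd = n * 1e-4, math.sqrt(n * 1e-4)
        assert abs(n_sub - expected) <= 3 * sd

    def test_q2_rate(self):
        rng = np.random.default_rng(6)
        n = 20_000
        out = inject_errors(SequenceRecord("r", "C" * n), [2] * n, rng)
        rate = sum(1 for c in out.sequence if c != "C") / n
        assert rate == pytest.approx(10 ** -0.2, abs=0.02)  # ~0.63

    def test_deterministic(self):
        read = SequenceRecord("r", "ACGT" * 50)
        q = [12] * 200
        a = inject_errors(read, q, np.random.default_rng(7))
        b = inject_errors(read, q, np.random.default_rng(7))
        assert a.sequence == b.sequence

    def test_quality_model_profile(self):
        qm = QualityModel(L=150)
        rng = np.random.default_rng(8)
        qs = np.array([qm.sample(rng) for _ in range(300)])
        assert qs.min() >= 2 and qs.max() <= 41
        assert abs(qs[:, :100].mean() - 38) < 1.0
        assert 24 < qs[:, -1].mean() < 27  # decayed tail


def _truth(locus=0, origin="ref"):
    return ReadPairTruth(locus, origin, "chr1", 1000, "+", 1200, "-", 350)


class TestScoreMapping:
    def _rec(self, pos0, mapq=60, flag=FLAG_READ1, rname="chr1"):
        return SamRecord("q", flag, rname, pos0 + 1, mapq, "150M",
                         seq="A" * 150)

    def test_exact_confident(self):
        v, = score_mapping([self._rec(1000)], {"q": _truth()})
        assert v.kind == "correct-confident"

    def test_low_mapq_not_confident(self):
        v, = score_mapping([self._rec(1000, mapq=5)], {"q": _truth()})
        assert v.kind == "not-confident"

    def test_tolerance_boundary(self):
        ok, = score_mapping([self._rec(1010)], {"q": _truth()}, tolerance=10)
        bad, = score_mapping([self._rec(1011)], {"q": _truth()}, tolerance=10)
        assert ok.kind == "correct-confident"
        assert bad.kind == "wrong-confident"

    def test_wrong_strand_is_wrong(self):
        rec = self._rec(1000, flag=FLAG_READ1 | FLAG_REVERSE)
        v, = score_mapping([rec], {"q": _truth()})
        assert v.kind == "wrong-confident"

    def test_mate2_uses_mate2_truth(self):
        rec = SamRecord("q", FLAG_READ2 | FLAG_REVERSE, "chr1", 1201, 60,
                        "150M", seq="A" * 150)
        v, = score_mapping([rec], {"q": _truth()})
        assert v.kind == "correct-confident"

    def test_unknown_read_rejected(self):
        with pytest.raises(KeyError):
            score_mapping([self._rec(0)], {"other": _truth()})


def _verdict(locus, correct, confident=True, origin="ref", pos=5000,
             mapq=None):
    if mapq is None:
        mapq = 30 if confident else 3
    return Verdict(locus, origin, 1, mapq, True, confident, correct,
                   "chr1", pos)


class TestComputeMetrics:
    def test_all_correct(self):
        vs = [_verdict(l, True) for l in range(4) for _ in range(5)]
        rep = compute_metrics(vs)
        assert (rep.sr_ref, rep.er_ref, rep.sl_ref, rep.el_ref) == (
            100.0, 0.0, 100.0, 0.0,
        )

    def test_systematic_error_locus(self):
        """4 loci x 5 reads; one locus has 3 confident reads clustered at
        the same wrong coordinate -> E_l = 25 with all 4 qualifying."""
        vs = []
        for l in range(3):
            vs.extend(_verdict(l, True) for _ in range(5))
        bad = [
            _verdict(3, False, pos=7000),
            _verdict(3, False, pos=7002),
            _verdict(3, False, pos=7005),
            _verdict(3, True, confident=False),
            _verdict(3, True, confident=False),
        ]
        vs.extend(bad)
        rep = compute_metrics(vs)
        assert rep.el_ref == 25.0
        assert rep.sl_ref == 75.0
        assert rep.counts["ref"]["qualifying_loci"] == 4

    def test_scattered_wrong_reads_are_not_systematic(self):
        vs = [
            _verdict(0, False, pos=7000),
            _verdict(0, False, pos=9000),
            _verdict(0, False, pos=11000),
        ]
        rep = compute_metrics(vs)
        assert rep.el_ref == 0.0

    def test_locus_below_three_confident_excluded(self):
        vs = [_verdict(0, True) for _ in range(5)]
        vs += [
            _verdict(1, True),
            _verdict(1, True),
            _verdict(1, True, confident=False),
        ]
        rep = compute_metrics(vs)
        # locus 1 has 2 confident reads: not in S_l numerator, not in E_l
        # denominator; S_l counts all loci in its denominator
        assert rep.sl_ref == 50.0
        assert rep.counts["ref"]["qualifying_loci"] == 1

    def test_majority_exclusivity(self):
        # a locus can never be both majority-correct and systematically
        # wrong: with 4 confident reads, 2+2 splits count for neither
        vs = [
            _verdict(0, True),
            _verdict(0, True),
            _verdict(0, False, pos=7000),
            _verdict(0, False, pos=7001),
        ]
        rep = compute_metrics(vs)
        assert rep.sl_ref == 0.0 and rep.el_ref == 0.0

    def test_zero_confident_reads_defines_er_zero(self):
        vs = [_verdict(0, True, confident=False) for _ in range(3)]
        rep = compute_metrics(vs)
        assert rep.er_ref == 0.0 and rep.el_ref == 0.0


def _report(s, e):
    return MetricsReport(
        sr_ref=s, er_ref=e, sl_ref=s, el_ref=e,
        sr_var=s, er_var=e, sl_var=s, el_var=e,
    )


class TestCompareMethods:
    def test_self_comparison_is_neutral(self):
        reports = {"X": _report(90, 1), "Y": _report(90, 1)}
        comps, ti = compare_methods(reports)
        for c in comps:
            assert c.mi == 0.0 and c.im == 0
        assert ti == {"X": 0.0, "Y": 0.0}

    def test_hand_computed_mi_im(self):
        x = MetricsReport(sr_ref=95, er_ref=1, sl_ref=90, el_ref=2,
                          sr_var=85, er_var=3, sl_var=80, el_var=4)
        y = MetricsReport(sr_ref=93, er_ref=2, sl_ref=91, el_ref=1,
                          sr_var=80, er_var=5, sl_var=75, el_var=6)
        comps, ti = compare_methods({"X": x, "Y": y})
        cxy = next(c for c in comps if c.x == "X")
        cyx = next(c for c in comps if c.x == "Y")
        # MI: mean of (2+1), (-1-1), (5+2), (5+2) over 4 combos
        assert cxy.mi == pytest.approx((3 - 2 + 7 + 7) / 4)
        assert cxy.im == 6  # X better in all but sl_ref / el_ref
        assert cyx.mi == -cxy.mi
        assert cxy.im + cyx.im <= 8
        assert ti["X"] == pytest.approx(cxy.mi)

    def test_missing_metrics_rejected(self):
        good = _report(90, 1)
        bad = MetricsReport(sr_ref=90)  # var metrics missing
        with pytest.raises(ValueError):
            compare_methods({"X": good, "Y": bad})

    def test_notation_rendering(self):
        s = render_comparison(
            Comparison("BWA", "Bowtie2", 2.0, 5),
            Comparison("Bowtie2", "BWA", -2.0, 3),
        )
        assert s == "BWA >5(2.0) Bowtie2"

    def test_notation_sweep(self):
        s = render_comparison(
            Comparison("X", "Y", 4.2, 8), Comparison("Y", "X", -4.2, 0)
        )
        assert s == "X >>(4.2) Y"
        s = render_comparison(
            Comparison("Y", "X", -4.2, 0), Comparison("X", "Y", 4.2, 8)
        )
        assert s == "Y <<(-4.2) X"


class TestCalibration:
    def test_q_measured_formula(self):
        vs = [_verdict(0, i != 0, mapq=30) for i in range(1000)]
        pts = calibration_table(vs, min_n=50)
        assert len(pts) == 1
        assert pts[0].q == 30 and pts[0].n == 1000 and pts[0].n_error == 1
        assert pts[0].q_measured == pytest.approx(30.0)

    def test_zero_errors_is_infinite(self):
        vs = [_verdict(0, True, mapq=42) for _ in range(100)]
        (pt,) = calibration_table(vs, min_n=50)
        assert pt.q_measured == float("inf")

    def test_small_groups_dropped(self):
        vs = [_verdict(0, True, mapq=q) for q in (1, 2, 3)]
        assert calibration_table(vs, min_n=50) == []

    @pytest.mark.parametrize("f,expected", [(0.1, 10.0), (0.01, 20.0)])
    def test_point_examples(self, f, expected):
        pt = CalibrationPoint(30, 1000, int(1000 * f), f,
                              -10 * math.log10(f))
        assert pt.q_measured == pytest.approx(expected)

    def test_planted_error_rate_recovered(self):
        """Scoring against a truth with planted wrong placements recovers
        the planted rate within binomial error."""
        rng = np.random.default_rng(30)
        planted = 0.05
        n = 4000
        wrong = rng.random(n) < planted
        vs = [_verdict(0, not w, mapq=25) for w in wrong]
        (pt,) = calibration_table(vs, min_n=50)
        sd = math.sqrt(n * planted * (1 - planted)) / n
        assert abs(pt.f_error - planted) <= 3 * sd


class TestEndToEnd:
    def test_megabase_pipeline_accuracy(self, mb_fixture):
        """Full pipeline on the 1 Mb fixture: simulate -> inject errors ->
        map -> score.  Reference-origin reads from a mostly unique genome
        must be recovered almost completely with few confident errors."""
        from pinmap.cli import run_benchmark
        from pinmap.fixtures import make_variants

        genome, truth, index = mb_fixture
        variants = make_variants(genome, density=0.002, seed=21)
        report, points = run_benchmark(
            genome, index, n_loci=200, pairs_per_locus=10, L=150, seed=22,
            variants=variants,
        )
        assert report.sr_ref > 95.0
        assert report.er_ref < 1.0
        assert report.sr_var > 80.0  # variant reads are harder
        assert report.counts["ref"]["reads"] == 4000
        # reported MAPQ >= 10 should imply a small measured error rate
        high_q = [p for p in points if p.q >= 10]
        assert high_q, "expected calibration points at high MAPQ"
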