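import numpy as np
import pytest

from mtg4.coverage import (
    AnnotationSet,
    StrandCoverageTrack,
    metagene,
    metagene_profiles,
    pileup,
    read_bedgraph,
    region_fold_change,
    strand_contribution,
    write_bedgraph,
)
from mtg4.g4scan import G4Motif
from mtg4.seqstats import CircularSequence, GenomicInterval


def sam_text(genome_id, length, reads):
    """reads: list of (name, flag, pos1, seq)"""
    lines = [f"@SQ\tSN:{genome_id}\tLN:{length}"]
    for name, flag, pos, seq in reads:
        lines.append(
            f"{name}\t{flag}\t{genome_id}\t{pos}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t*"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def genome():
    return CircularSequence("mt", "ACGT" * 50)  # 200 nt


def make_track(length, plus=None, minus=None, total=None):
    p = np.zeros(length) if plus is None else np.asarray(plus, dtype=float)
    m = np.zeros(length) if minus is None else np.asarray(minus, dtype=float)
    return StrandCoverageTrack("mt", p, m, total if total is not None else max(p.sum() + m.sum(), 1))


class TestPileup:
    def test_single_forward_read(self, tmp_path, genome):
        sam = tmp_path / "a.sam"
        sam.write_text(sam_text("mt", 200, [("r1", 0, 11, "A" * 10)]))
        track = pileup(sam, genome)
        assert track.depth_plus[10:20].tolist() == [1.0] * 10
        assert track.depth_plus.sum() == 10
        assert track.depth_minus.sum() == 0
        assert track.total_mapped == 1

    def test_counting_twice_doubles_depth_not_fractions(self, tmp_path, genome):
        reads = [("r1", 0, 11, "A" * 10), ("r2", 16, 31, "C" * 10)]
        one = tmp_path / "one.sam"
        two = tmp_path / "two.sam"
        one.write_text(sam_text("mt", 200, reads))
        two.write_text(sam_text("mt", 200, reads + [(n + "b", f, p, s) for n, f, p, s in reads]))
        t1, t2 = pileup(one, genome), pileup(two, genome)
        assert np.array_equal(2 * t1.depth_plus, t2.depth_plus)
        assert np.array_equal(t1.normalized("+"), t2.normalized("+"))

    def test_strandedness_flips_assignment(self, tmp_path, genome):
        sam = tmp_path / "a.sam"
        sam.write_text(sam_text("mt", 200, [("r1", 16, 11, "A" * 10)]))
        assert pileup(sam, genome, "r1-sense").depth_minus.sum() == 10
        assert pileup(sam, genome, "r1-antisense").depth_plus.sum() == 10

    def test_reference_length_mismatch(self, tmp_path, genome):
        sam = tmp_path / "a.sam"
        sam.write_text(sam_text("mt", 999, [("r1", 0, 11, "A" * 10)]))
        with pytest.raises(ValueError, match="length"):
            pileup(sam, genome)

    def test_low_mapq_reads_dropped(self, tmp_path, genome):
        sam = tmp_path / "a.sam"
        text = sam_text("mt", 200, [("r1", 0, 11, "A" * 10)]).replace("\t60\t", "\t3\t")
        sam.write_text(text)
        with pytest.raises(ValueError, match="no usable alignments"):
            pileup(sam, genome)

    def test_bedgraph_pair_roundtrip(self, tmp_path, genome):
        plus = np.zeros(200)
        plus[30:60] = 4
        minus = np.zeros(200)
        minus[100:110] = 2
        write_bedgraph(plus, "mt", tmp_path / "p.bg")
        write_bedgraph(minus, "mt", tmp_path / "m.bg")
        track = pileup((tmp_path / "p.bg", tmp_path / "m.bg"), genome)
        assert np.array_equal(track.depth_plus, plus)
        assert np.array_equal(track.depth_minus, minus)
        assert np.array_equal(read_bedgraph(tmp_path / "p.bg", 200), plus)


@pytest.fixture
def annotation():
    return AnnotationSet(
        [
            (GenomicInterval(1, 40, "+"), "mRNA"),
            (GenomicInterval(61, 80, "+"), "rRNA"),
            (GenomicInterval(121, 140, "-"), "tRNA"),
        ]
    )


class TestStrandContribution:
    def test_all_coverage_on_one_strand(self, annotation):
        track = make_track(200, minus=np.ones(200))
        s = strand_contribution(track, annotation)
        assert s.fraction_L == 1.0 and s.fraction_H == 0.0

    def test_equal_uniform_coverage_splits_evenly(self):
        # symmetric eligibility (no features): equal coverage -> 0.5/0.5
        track = make_track(200, plus=np.ones(200), minus=np.ones(200))
        s = strand_contribution(track, AnnotationSet([]))
        assert s.fraction_L == pytest.approx(0.5)
        assert s.fraction_L + s.fraction_H == 1.0

    def test_eligible_bases_exclude_sense_features_and_antisense_structural(self, annotation):
        track = make_track(200, plus=np.ones(200), minus=np.ones(200))
        s = strand_contribution(track, annotation)
        # + strand: minus mRNA..none; excludes own mRNA/rRNA (60) + antisense tRNA (20)
        assert s.eligible_bases_plus == 200 - 40 - 20 - 20
        # - strand: excludes own tRNA (20) + antisense rRNA (20)
        assert s.eligible_bases_minus == 200 - 20 - 20

    def test_boosted_l_strand_raises_fraction(self, annotation):
        base = np.ones(200)
        control = make_track(200, plus=base, minus=base)
        boosted = make_track(200, plus=base, minus=10 * base)
        c = strand_contribution(control, annotation)
        d = strand_contribution(boosted, annotation)
        assert d.fraction_L > c.fraction_L

    def test_scale_invariance(self, annotation):
        track = make_track(200, plus=np.arange(200.0), minus=np.ones(200), total=500)
        scaled = make_track(200, plus=7 * np.arange(200.0), minus=7 * np.ones(200), total=3500)
        a, b = strand_contribution(track, annotation), strand_contribution(scaled, annotation)
        assert a.fraction_L == pytest.approx(b.fraction_L)

    def test_zero_eligible_coverage(self, annotation):
        track = make_track(200, plus=np.zeros(200), minus=np.zeros(200), total=10)
        with pytest.raises(ValueError, match="eligible"):
            strand_contribution(track, annotation)


class TestMetagene:
    def motif(self, center, strand="+"):
        return G4Motif(center - 7, center + 8, strand, "", 4, [1, 1, 1])

    def test_self_ratio_is_flat_one(self, rng):
        depth = rng.poisson(30, size=400).astype(float)
        t = make_track(400, plus=depth, minus=depth)
        prof = metagene(t, t, [self.motif(200)], halfwidth=50)
        assert np.allclose(prof.ratio, 1.0)

    def test_tripled_depth_at_fixed_library_size(self):
        base = np.full(400, 10.0)
        control = make_track(400, plus=base, minus=base, total=100)
        treated = make_track(400, plus=3 * base, minus=3 * base, total=100)
        prof = metagene(treated, control, [self.motif(200)], halfwidth=50, pseudocount=0.0)
        assert np.allclose(prof.ratio, 3.0)

    def test_library_size_normalization_cancels(self):
        base = np.full(400, 10.0)
        a = make_track(400, plus=base, minus=base, total=100)
        b = make_track(400, plus=5 * base, minus=5 * base, total=500)
        prof = metagene(b, a, [self.motif(200)], halfwidth=50, pseudocount=0.0)
        assert np.allclose(prof.ratio, 1.0)
        # default pseudocount (0.5 reads/library) is negligible at real depth
        prof_pc = metagene(b, a, [self.motif(200)], halfwidth=50)
        assert np.allclose(prof_pc.ratio, 1.0, rtol=0.05)

    def test_minus_strand_window_is_transcript_oriented(self):
        # step up only 5' of the motif on the minus-strand transcript
        plus = np.ones(400)
        minus = np.ones(400)
        minus[210:260] = 9.0  # higher reference coords = transcript upstream
        treated = make_track(400, plus=plus, minus=minus, total=400)
        control = make_track(400, plus=plus, minus=np.ones(400), total=400)
        prof = metagene(treated, control, [self.motif(200, "-")], halfwidth=100)
        up = prof.ratio[prof.offsets < -5].mean()
        down = prof.ratio[prof.offsets > 5].mean()
        assert up > 3 * down

    def test_reflection_symmetry(self, rng):
        n = 400
        plus = rng.poisson(20, n).astype(float)
        minus = rng.poisson(20, n).astype(float)
        treated = make_track(n, plus=plus, minus=minus)
        control = make_track(n, plus=np.ones(n), minus=np.ones(n))
        prof = metagene(treated, control, [self.motif(200, "+")], halfwidth=60)
        # reflect the genome: reverse arrays and swap strands
        r_treated = make_track(n, plus=minus[::-1], minus=plus[::-1])
        r_control = make_track(n, plus=np.ones(n), minus=np.ones(n))
        r_motif = G4Motif(n - (200 + 8), n - (200 - 7), "-", "", 4, [1, 1, 1])
        r_prof = metagene(r_treated, r_control, [r_motif], halfwidth=60)
        assert np.allclose(prof.ratio, r_prof.ratio)

    def test_sense_and_antisense_profiles_use_opposite_strands(self):
        plus = np.ones(400)
        minus = 2 * np.ones(400)
        treated = make_track(400, plus=plus, minus=minus, total=400)
        control = make_track(400, plus=np.ones(400), minus=np.ones(400), total=400)
        profs = metagene_profiles(
            treated, control, [self.motif(200, "-")], halfwidth=50, pseudocount=0.0
        )
        assert np.allclose(profs["sense"].ratio, 2.0)
        assert np.allclose(profs["antisense"].ratio, 1.0)

    def test_halfwidth_bound(self):
        t = make_track(100, plus=np.ones(100), minus=np.ones(100))
        with pytest.raises(ValueError, match="halfwidth"):
            metagene(t, t, [self.motif(50)], halfwidth=50)

    def test_empty_motif_list(self):
        t = make_track(100, plus=np.ones(100), minus=np.ones(100))
        with pytest.raises(ValueError, match="motif"):
            metagene(t, t, [], halfwidth=10)


def test_region_fold_change_on_origin_spanning_interval():
    plus = np.ones(100)
    treated = make_track(100, plus=4 * plus, minus=plus, total=100)
    control = make_track(100, plus=plus, minus=plus, total=100)
    iv = GenomicInterval(91, 10, "+")  # spans the origin, 20 nt
    assert region_fold_change(treated, control, iv, "+") == pytest.approx(4.0)
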