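import numpy as np
import pytest

from mtg4.g4scan import scan_both_strands
from mtg4.seqstats import composition
from mtg4.shortrna import merge_pair
from mtg4 import synthetic as syn


class TestMakeGenome:
    def test_clean_background_has_no_motifs(self):
        cfg = syn.SimConfig(rng_seed=3, genome_length=4000, n_planted_g4=0)
        genome, truth = syn.make_genome(cfg)
        assert truth.motifs == []
        assert scan_both_strands(genome).motifs == []

    def test_background_composition_matches_config(self):
        cfg = syn.SimConfig(rng_seed=3, genome_length=4000, n_planted_g4=0)
        genome, _ = syn.make_genome(cfg)
        c = composition(genome)
        assert abs((c.n_a + c.n_t) - round(cfg.at_fraction * 4000)) <= 1
        n_gc = 4000 - round(cfg.at_fraction * 4000)
        assert abs(c.n_g - round(n_gc * (1 + cfg.gc_skew) / 2)) <= 1

    def test_planted_motifs_are_exactly_what_the_scanner_finds(self, small_genome):
        _, genome, truth = small_genome
        found = {
            (m.start % len(genome), m.end - m.start, m.strand)
            for m in scan_both_strands(genome).motifs
        }
        assert found == {(s, e - s, st) for s, e, st in truth.motifs}

    def test_deterministic_in_seed(self):
        cfg = syn.SimConfig(rng_seed=9, genome_length=3000, n_planted_g4=3, motif_spacing=800)
        a, ta = syn.make_genome(cfg)
        b, tb = syn.make_genome(cfg)
        assert a.residues == b.residues and ta.motifs == tb.motifs
        c, _ = syn.make_genome(syn.SimConfig(rng_seed=10, genome_length=3000,
                                             n_planted_g4=3, motif_spacing=800))
        assert c.residues != a.residues

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            syn.make_genome(syn.SimConfig(genome_length=1000, n_planted_g4=10, motif_spacing=200))


@pytest.fixture(scope="module")
def setup():
    cfg = syn.SimConfig(rng_seed=6, genome_length=8000, n_planted_g4=6,
                        motif_spacing=1200, coverage_depth=40.0)
    genome, truth = syn.make_genome(cfg)
    return cfg, genome, truth


class TestSimulateCoverage:
    def test_control_matches_expected_mean(self, setup):
        cfg, genome, truth = setup
        track = syn.simulate_coverage(genome, truth, "control", cfg)
        exp = truth.expected_depth["control"]
        assert np.all(exp["+"] == cfg.coverage_depth)
        for s in "+-":
            assert abs(track.depth(s).mean() - cfg.coverage_depth) < 3 * np.sqrt(
                cfg.coverage_depth / len(genome)
            )

    def test_deficient_boosts_upstream_of_each_motif(self, setup):
        cfg, genome, truth = setup
        syn.simulate_coverage(genome, truth, "deficient", cfg)
        exp = truth.expected_depth["deficient"]
        for start, end, strand in truth.motifs:
            center = (start + end) // 2
            up = center - 100 if strand == "+" else center + 100
            down = center + 100 if strand == "+" else center - 100
            assert exp[strand][up % len(genome)] == cfg.coverage_depth * cfg.accumulation_factor
            assert exp[strand][down % len(genome)] == cfg.coverage_depth

    def test_unit_accumulation_factor_is_null(self, setup):
        cfg, genome, truth = setup
        cfg1 = syn.SimConfig(**{**cfg.__dict__, "accumulation_factor": 1.0})
        control = syn.simulate_coverage(genome, truth, "control", cfg1, stream=0)
        deficient = syn.simulate_coverage(genome, truth, "deficient", cfg1, stream=1)
        log_ratio = np.log((deficient.depth_minus + 1) / (control.depth_minus + 1))
        se = log_ratio.std(ddof=1) / np.sqrt(len(log_ratio))
        assert abs(log_ratio.mean()) < 3 * se + 1e-3

    def test_same_stream_reproducible(self, setup):
        cfg, genome, truth = setup
        a = syn.simulate_coverage(genome, truth, "control", cfg, stream=4)
        b = syn.simulate_coverage(genome, truth, "control", cfg, stream=4)
        assert np.array_equal(a.depth_plus, b.depth_plus)

    def test_unknown_condition(self, setup):
        cfg, genome, truth = setup
        with pytest.raises(ValueError, match="condition"):
            syn.simulate_coverage(genome, truth, "mystery", cfg)


class TestSimulateReadPairs:
    def test_trna_like_geometry(self):
        # a 73-nt species with a CCA tail under 2x75 reads merges to 76 nt
        cfg = syn.SimConfig(rng_seed=12, genome_length=4000, n_planted_g4=0)
        genome, _ = syn.make_genome(cfg)
        start0 = 1000
        core = genome.fetch(start0, start0 + 73)
        assert genome.residues[start0 + 73] != "C"  # guarantee non-templated
        sp = syn.SpeciesDef(start0 + 1, start0 + 73, "+", "CCA", core + "CCA")
        pairs, truth = syn.simulate_read_pairs([sp], cfg)
        m = merge_pair(pairs[0])
        assert m is not None and len(m.sequence) == 76
        assert m.sequence == core + "CCA"
        assert truth.pair_true_overlap[0] == 2 * 75 - 76

    def test_boundary_molecule_rejected_by_merge(self):
        cfg = syn.SimConfig(rng_seed=14, genome_length=4000, n_planted_g4=0,
                            n_species=5, n_unmergeable=3)
        genome, _ = syn.make_genome(cfg)
        species = syn.make_species(genome, cfg)
        pairs, truth = syn.simulate_read_pairs(species, cfg)
        for pair, mergeable, olen in zip(pairs, truth.pair_mergeable, truth.pair_true_overlap):
            got = merge_pair(pair)
            assert (got is not None) == mergeable
            if not mergeable:
                assert olen == 4

    def test_truth_matches_merge_outcome_in_bulk(self):
        cfg = syn.preset_shortrna(21)
        genome, truth = syn.make_genome(cfg)
        species = syn.make_species(genome, cfg)
        pairs, truth = syn.simulate_read_pairs(species, cfg, truth)
        assert len(pairs) == cfg.n_read_pairs
        for pair, mergeable, olen in zip(pairs, truth.pair_mergeable, truth.pair_true_overlap):
            m = merge_pair(pair)
            assert (m is not None) == mergeable
            if m is not None:
                assert m.overlap == olen

    def test_fastq_roundtrip(self, tmp_path):
        from mtg4.shortrna import read_fastq_pairs

        cfg = syn.SimConfig(rng_seed=15, genome_length=3000, n_planted_g4=0, n_species=4,
                            n_unmergeable=0, n_read_pairs=20)
        genome, _ = syn.make_genome(cfg)
        pairs, _ = syn.simulate_read_pairs(syn.make_species(genome, cfg), cfg)
        syn.write_fastq_pairs(pairs, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        back = read_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        assert [(p.r1_seq, p.r2_seq) for p in back] == [(p.r1_seq, p.r2_seq) for p in pairs]


class TestSimulateTapms:
    def test_deterministic_and_seed_sensitive(self):
        a, _ = syn.simulate_tapms(syn.preset_tapms(3))
        b, _ = syn.simulate_tapms(syn.preset_tapms(3))
        c, _ = syn.simulate_tapms(syn.preset_tapms(4))
        get = lambda recs: [(r.protein_id, r.intensities["suv3"].tolist()) for r in recs]
        assert get(a) == get(b)
        assert get(a) != get(c)

    def test_decoy_classes_present(self):
        records, truth = syn.simulate_tapms(syn.preset_tapms(0))
        ids = {r.protein_id for r in records}
        assert len(records) == 200
        assert len(truth.tapms_passers) == 7
        for cls in ("DECOY_PARTIAL", "DECOY_NONMITO", "DECOY_NOCTRL"):
            assert sum(i.startswith(cls) for i in ids) == 2
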