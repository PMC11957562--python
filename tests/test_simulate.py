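import numpy as np
import pytest
from scipy import stats

from mitoscreen import simulate as sim
from mitoscreen.genome import reverse_complement
from mitoscreen.tracks import five_prime_track, load_alignments


class TestGenerateGenome:
    def test_length_and_gc(self):
        g = sim.generate_circular_genome(1000, 0.5, seed=1)
        assert g.length == 1000
        gc = (g.sequence.count("G") + g.sequence.count("C")) / 1000
        assert abs(gc - 0.5) < 0.06  # ~3.2 sigma of binomial sampling error

    def test_no_repeated_36mer_in_random_sequence(self):
        # brute-force k-mer census on the emitted sequence (circular)
        g = sim.generate_circular_genome(1000, 0.5, seed=1)
        seq = g.sequence + g.sequence[:35]
        kmers = [seq[i:i + 36] for i in range(1000)]
        assert len(set(kmers)) == 1000

    def test_duplication_copied_exactly(self):
        g = sim.generate_circular_genome(400, 0.5, duplications=[(0, 100, 300)], seed=2)
        assert g.sequence[300:400] == g.sequence[0:100]

    def test_determinism(self):
        a = sim.generate_circular_genome(500, 0.4, seed=7)
        b = sim.generate_circular_genome(500, 0.4, seed=7)
        assert a.sequence == b.sequence

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            sim.generate_circular_genome(0, 0.5)
        with pytest.raises(ValueError, match="fit"):
            sim.generate_circular_genome(100, 0.5, duplications=[(0, 200, 50)])


class TestPlantMotifs:
    def test_plus_strand_insertion(self):
        g = sim.generate_circular_genome(1000, 0.5, seed=1)
        planted, sites = sim.plant_motifs(g, "ACGTACGT", [(500, "+", 10.0, "occupancy")])
        assert planted.fetch(496, 8) == "ACGTACGT"
        assert sites[0].position == 500 and sites[0].kind == "occupancy"

    def test_minus_strand_inserts_reverse_complement(self):
        g = sim.generate_circular_genome(1000, 0.5, seed=1)
        planted, _ = sim.plant_motifs(g, "AAACCC", [(100, "-", 10.0, "occupancy")])
        assert planted.fetch(97, 6) == reverse_complement("AAACCC") == "GGGTTT"

    def test_artifact_leaves_sequence_unchanged(self):
        g = sim.generate_circular_genome(1000, 0.5, seed=1)
        planted, sites = sim.plant_motifs(g, "AAACCC", [(100, "both", 10.0, "artifact")])
        assert planted.sequence == g.sequence
        assert sites[0].kind == "artifact"

    def test_overlapping_occupancy_rejected(self):
        g = sim.generate_circular_genome(1000, 0.5, seed=1)
        with pytest.raises(ValueError, match="overlap"):
            sim.plant_motifs(g, "ACGTACGT",
                             [(500, "+", 10.0, "occupancy"),
                              (503, "+", 10.0, "occupancy")])

    def test_artifact_requires_both_strand(self):
        with pytest.raises(ValueError, match="both"):
            sim.TruthSite(10, "+", "", 5.0, "artifact")


class TestSimulateReads:
    def test_read_count_conserved(self, random_genome):
        aln = sim.simulate_reads(random_genome, [], sim.SimConfig(n_reads=1000, seed=3))
        assert len(aln) == 1000

    def test_determinism(self, random_genome):
        cfg = sim.SimConfig(n_reads=500, seed=9)
        a = sim.simulate_reads(random_genome, [], cfg)
        b = sim.simulate_reads(random_genome, [], cfg)
        assert a.reads == b.reads

    def test_background_uniformity_over_seeds(self, random_genome):
        # Monte-Carlo calibration: chi-square GoF on plus-strand 5' ends
        # should pass at alpha=0.01 in >= 95/100 seeds
        passes = 0
        for seed in range(100):
            aln = sim.simulate_reads(random_genome, [],
                                     sim.SimConfig(n_reads=1000, seed=seed))
            plus5 = [r.five_prime(1000) for r in aln.reads if r.strand == "+"]
            counts, _ = np.histogram(plus5, bins=20, range=(0, 1000))
            p = stats.chisquare(counts).pvalue
            passes += p > 0.01
        assert passes >= 95

    def test_occupancy_five_prime_means(self):
        g = sim.generate_circular_genome(10000, 0.5, seed=5)
        site = sim.TruthSite(5000, "+", "ACGTACGT", 20.0, "occupancy")
        aln = sim.simulate_reads(g, [site], sim.SimConfig(
            n_reads=20000, fragment_length_mean=200.0, background_fraction=0.0,
            seed=6))
        fp = five_prime_track(aln)
        plus_mean = np.average(np.arange(10000), weights=fp.plus)
        minus_mean = np.average(np.arange(10000), weights=fp.minus)
        assert abs(plus_mean - 4900) <= 10
        assert abs(minus_mean - 5100) <= 10

    def test_summit_separation_converges_to_fragment_length(self):
        g = sim.generate_circular_genome(10000, 0.5, seed=5)
        site = sim.TruthSite(5000, "+", "ACGTACGT", 20.0, "occupancy")
        aln = sim.simulate_reads(g, [site], sim.SimConfig(
            n_reads=20000, fragment_length_mean=200.0, background_fraction=0.0,
            seed=8))
        fp = five_prime_track(aln)
        sep = (np.average(np.arange(10000), weights=fp.minus)
               - np.average(np.arange(10000), weights=fp.plus))
        assert abs(sep - 200) <= 10

    def test_artifact_site_is_symmetric(self):
        g = sim.generate_circular_genome(10000, 0.5, seed=5)
        site = sim.TruthSite(5000, "both", "", 20.0, "artifact")
        aln = sim.simulate_reads(g, [site], sim.SimConfig(
            n_reads=20000, background_fraction=0.0, seed=10))
        fp = five_prime_track(aln)
        plus_mean = np.average(np.arange(10000), weights=fp.plus)
        minus_mean = np.average(np.arange(10000), weights=fp.minus)
        assert abs(plus_mean - minus_mean) < 10

    def test_control_suppresses_enrichment(self):
        g = sim.generate_circular_genome(10000, 0.5, seed=5)
        site = sim.TruthSite(5000, "+", "ACGTACGT", 20.0, "occupancy")
        aln = sim.simulate_reads(g, [site], sim.SimConfig(
            n_reads=5000, background_fraction=0.0, control=True, seed=11))
        fp = five_prime_track(aln)
        window = fp.total[4800:5200].sum()
        assert window < 0.2 * fp.total.sum()  # no pile-up at the site

    def test_site_outside_genome_rejected(self, random_genome):
        bad = sim.TruthSite(5000, "+", "ACGT", 5.0, "occupancy")
        with pytest.raises(ValueError, match="outside"):
            sim.simulate_reads(random_genome, [bad], sim.SimConfig(n_reads=10))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sim.SimConfig(n_reads=-1)
        with pytest.raises(ValueError):
            sim.SimConfig(n_reads=10, fragment_length_mean=10, read_length=36)
        with pytest.raises(ValueError):
            sim.SimConfig(n_reads=10, background_fraction=1.5)


class TestTruthBed:
    def test_single_site_coordinates(self, tmp_path):
        path = str(tmp_path / "t.bed")
        sites = [sim.TruthSite(500, "+", "", 5.0, "occupancy")]
        sim.write_truth(sites, 1000, path, width=1)
        lines = [l for l in open(path) if not l.startswith("#")]
        fields = lines[0].split("\t")
        assert (int(fields[1]), int(fields[2])) == (500, 501)

    def test_empty_list_writes_header_only(self, tmp_path):
        path = str(tmp_path / "t.bed")
        sim.write_truth([], 1000, path)
        lines = open(path).read().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_wrap_spanning_site_split_into_flagged_pair(self, tmp_path):
        path = str(tmp_path / "t.bed")
        sites = [sim.TruthSite(2, "both", "", 5.0, "artifact")]
        sim.write_truth(sites, 1000, path, width=10)
        lines = [l.split("\t") for l in open(path) if not l.startswith("#")]
        assert len(lines) == 2
        assert lines[0][3] == "site_0/part1" and lines[1][3] == "site_0/part2"
        assert (int(lines[0][1]), int(lines[0][2])) == (997, 1000)
        assert (int(lines[1][1]), int(lines[1][2])) == (0, 7)

    def test_roundtrip(self, tmp_path):
        path = str(tmp_path / "t.bed")
        sites = [sim.TruthSite(500, "+", "ACGT", 5.0, "occupancy"),
                 sim.TruthSite(2, "both", "", 30.0, "artifact")]
        sim.write_truth(sites, 1000, path)
        back = sim.read_truth(path)
        assert [(s.position, s.strand, s.enrichment, s.kind) for s in back] == \
               [(s.position, s.strand, s.enrichment, s.kind) for s in sites]


def test_sam_roundtrip(tmp_path, random_genome):
    cfg = sim.SimConfig(n_reads=200, seed=12)
    aln = sim.simulate_reads(random_genome, [], cfg)
    path = str(tmp_path / "reads.sam")
    sim.write_sam(aln, random_genome, path)
    back = load_alignments(path, random_genome.name)
    assert len(back) == 200
    assert sorted(r.duplicate_key for r in back.reads) == \
           sorted(r.duplicate_key for r in aln.reads)
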