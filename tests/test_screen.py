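import numpy as np
import pytest

from mitoscreen import simulate as sim
from mitoscreen.genome import Annotation
from mitoscreen.mappability import MappabilityTrack, compute_mappability
from mitoscreen.screen import (AsymmetryResult, CandidateRegion, ScreenParams,
                               asymmetry, call_candidates, classify,
                               screen_alignments)
from mitoscreen.tracks import StrandedTrack, five_prime_track


def _track(plus, minus, kind="coverage"):
    return StrandedTrack("chrM", kind, np.asarray(plus, float),
                         np.asarray(minus, float))


def _all_mappable(n):
    return MappabilityTrack("chrM", 36, np.ones(n, dtype=np.uint8))


class TestCallCandidates:
    def test_constant_track_yields_nothing(self):
        track = _track(np.full(1000, 5.0), np.full(1000, 5.0))
        assert call_candidates(track, _all_mappable(1000)) == []

    def test_single_block_detected(self):
        plus = np.full(2000, 5.0)
        plus[100:500] = 500.0
        track = _track(plus, np.full(2000, 5.0))
        regions = call_candidates(track, _all_mappable(2000))
        assert len(regions) == 1
        r = regions[0]
        assert r.start <= 100 and r.start + r.length >= 500
        assert r.fold > 20

    def test_origin_spanning_block_is_one_candidate(self):
        plus = np.full(2000, 5.0)
        plus[1900:] = 500.0
        plus[:100] = 500.0
        track = _track(plus, np.full(2000, 5.0))
        regions = call_candidates(track, _all_mappable(2000))
        assert len(regions) == 1
        r = regions[0]
        assert r.start + r.length > 2000  # wraps the origin

    def test_fold_min_monotonicity(self):
        rng = np.random.default_rng(0)
        plus = rng.poisson(5, 3000).astype(float)
        for pos in (300, 900, 1500, 2100):
            plus[pos : pos + 60] += rng.integers(20, 200)
        track = _track(plus, np.zeros(3000))
        counts = [len(call_candidates(track, _all_mappable(3000),
                                      ScreenParams(fold_min=f)))
                  for f in (2, 3, 5, 10, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_all_zero_track_empty_no_error(self):
        track = _track(np.zeros(500), np.zeros(500))
        assert call_candidates(track, _all_mappable(500)) == []


class TestAsymmetry:
    def test_delta_profiles_recover_lag(self):
        plus = np.zeros(2000)
        minus = np.zeros(2000)
        plus[100] = 50
        minus[300] = 50
        track = _track(plus, minus, kind="five_prime")
        region = CandidateRegion(50, 300, 2000)
        result = asymmetry(track, region, max_lag=400)
        assert result.best_lag == 200
        assert result.corr_best > 0.95
        assert abs(result.corr_zero) < 0.2

    def test_identical_strands_zero_lag(self):
        rng = np.random.default_rng(1)
        prof = rng.poisson(3, 2000).astype(float)
        prof[500:540] += 100
        track = _track(prof, prof.copy(), kind="five_prime")
        region = CandidateRegion(450, 150, 2000)
        result = asymmetry(track, region, max_lag=300)
        assert result.best_lag == 0
        assert result.score <= 0.05

    def test_simulated_occupancy_lag_within_tolerance(self):
        g = sim.generate_circular_genome(10000, 0.5, seed=2)
        site = sim.TruthSite(5000, "+", "ACGT" * 2, 20.0, "occupancy")
        aln = sim.simulate_reads(g, [site], sim.SimConfig(
            n_reads=20000, fragment_length_mean=200.0, background_fraction=0.1,
            seed=3))
        fp = five_prime_track(aln)
        region = CandidateRegion(4800, 400, 10000)
        result = asymmetry(fp, region, max_lag=400)
        assert 180 <= result.best_lag <= 220

    def test_zero_read_strand_flagged_undefined(self):
        plus = np.zeros(1000)
        plus[100] = 5
        track = _track(plus, np.zeros(1000), kind="five_prime")
        result = asymmetry(track, CandidateRegion(80, 60, 1000), max_lag=100)
        assert result.undefined

    def test_max_lag_bound(self):
        track = _track(np.ones(100), np.ones(100), kind="five_prime")
        with pytest.raises(ValueError, match="max_lag"):
            asymmetry(track, CandidateRegion(0, 10, 100), max_lag=60)


class TestClassify:
    def _region(self, start=1000, length=200, fold=50.0, n=10000):
        return CandidateRegion(start, length, n, fold, start + 50, start + 150)

    def test_mask_overrides_score(self):
        region = self._region(start=5000)
        asym = AsymmetryResult(200, 0.9, 0.1, 0.8)
        call = classify(region, asym, [Annotation(4900, 500, "dloop")])
        assert call.label == "masked"

    def test_good_lag_and_score_is_occupancy(self):
        call = classify(self._region(), AsymmetryResult(200, 0.9, 0.3, 0.6), [])
        assert call.label == "occupancy_like"

    def test_symmetric_high_fold_is_artifact(self):
        call = classify(self._region(fold=50.0),
                        AsymmetryResult(0, 0.9, 0.88, 0.02), [])
        assert call.label == "artifact_like"

    def test_symmetric_low_fold_is_ambiguous(self):
        call = classify(self._region(fold=4.0),
                        AsymmetryResult(0, 0.5, 0.49, 0.01), [])
        assert call.label == "ambiguous"

    def test_undefined_asymmetry_forced_ambiguous(self):
        call = classify(self._region(),
                        AsymmetryResult(0, float("nan"), float("nan"),
                                        float("nan"), undefined=True), [])
        assert call.label == "ambiguous"


class TestScreenPipeline:
    def test_planted_sites_recovered(self, occupancy_dataset, moddist):
        data = occupancy_dataset
        mp = compute_mappability(data["genome"], k=36, circular_kmers=True)
        calls, report = screen_alignments(data["aln"], mp, [data["mask"]])
        occ = [c for c in calls if c.label == "occupancy_like"]
        n = data["genome"].length
        for p in data["occupancy_positions"]:
            assert any(moddist(c.region.site_estimate, p, n) <= 50 for c in occ)
        # the symmetric artifact must never look like occupancy
        assert not any(moddist(c.region.site_estimate,
                               data["artifact_position"], n) <= 100
                       for c in occ)
        assert report["labels"]["occupancy_like"] == len(occ)

    def test_control_dataset_yields_no_occupancy(self, occupancy_dataset):
        data = occupancy_dataset
        aln = sim.simulate_reads(data["genome"], data["sites"], sim.SimConfig(
            n_reads=50000, background_fraction=0.3, control=True, seed=5))
        mp = compute_mappability(data["genome"], k=36, circular_kmers=True)
        calls, _ = screen_alignments(aln, mp, [data["mask"]])
        assert sum(c.label == "occupancy_like" for c in calls) == 0

    def test_empty_alignments_warning_report(self):
        from mitoscreen.tracks import AlignmentSet

        aln = AlignmentSet("chrM", 1000, [])
        calls, report = screen_alignments(aln, _all_mappable(1000))
        assert calls == [] and "warning" in report

    def test_rotation_equivariance(self, occupancy_dataset):
        data = occupancy_dataset
        mp = compute_mappability(data["genome"], k=36, circular_kmers=True)
        r = 4321
        calls, _ = screen_alignments(data["aln"], mp, [data["mask"]])
        calls_rot, _ = screen_alignments(
            data["aln"].rotate(r), mp.rotate(r),
            [Annotation((data["mask"].start + r) % data["genome"].length,
                        data["mask"].length, "dloop")])
        n = data["genome"].length
        got = sorted(((c.region.start, c.region.length, c.label) for c in calls_rot))
        expected = sorted((((c.region.start + r) % n, c.region.length, c.label)
                           for c in calls))
        assert got == expected
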