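import itertools

import numpy as np
import pytest

from mitoscreen.evidence import (DatasetRecord, Reagent, cluster_profiles,
                                 site_concordance, summary_table, tier_evidence)
from mitoscreen.screen import AsymmetryResult, CandidateRegion, PeakCall

N = 16569


def _call(summit, label="occupancy_like"):
    region = CandidateRegion((summit - 100) % N, 200, N, 30.0,
                             (summit - 50) % N, (summit + 50) % N)
    return PeakCall(region, AsymmetryResult(200, 0.9, 0.1, 0.8), label)


def _record(ds_id, summits, reagent=("antibody", "ab1"), target="TFX",
            corroboration=None, lot=None):
    return DatasetRecord(
        dataset_id=ds_id, target=target, cell_context="K562",
        reagent=Reagent(reagent[0], reagent[1], lot),
        calls=[_call(s) for s in summits], corroboration=corroboration)


class TestSiteConcordance:
    def test_identical_sets_full_overlap(self):
        calls = [_call(100), _call(5000)]
        matches, overlap = site_concordance(calls, list(calls), N)
        assert overlap == 1.0 and len(matches) == 2

    def test_disjoint_sets_zero(self):
        _, overlap = site_concordance([_call(100)], [_call(9000)], N)
        assert overlap == 0.0

    def test_d_max_boundary(self):
        a, b = [_call(100)], [_call(130)]
        matches, _ = site_concordance(a, b, N, d_max=50)
        assert len(matches) == 1
        matches, _ = site_concordance(a, b, N, d_max=20)
        assert len(matches) == 0

    def test_modular_distance_across_origin(self):
        matches, _ = site_concordance([_call(10)], [_call(N - 10)], N, d_max=50)
        assert len(matches) == 1

    def test_artifact_calls_ignored(self):
        a = [_call(100, label="artifact_like")]
        b = [_call(100)]
        matches, overlap = site_concordance(a, b, N)
        assert matches == [] and overlap == 0.0


class TestTierEvidence:
    def test_orthogonal_reagents_concordant(self):
        records = [
            _record("d1", [3000, 8000], reagent=("antibody", "abA")),
            _record("d2", [3010, 7990], reagent=("epitope_tag", "gfp")),
        ]
        summary = tier_evidence(records, N)
        assert summary.tier == "orthogonally_replicated"
        assert summary.orthogonal_reagents_with_peaks == 2
        assert not summary.discordant

    def test_two_of_ten_same_antibody_is_replicated_and_discordant(self):
        records = [_record(f"d{i}", [3000] if i < 2 else [])
                   for i in range(10)]
        summary = tier_evidence(records, N)
        assert summary.tier == "replicated_same_reagent"
        assert summary.discordant

    def test_single_corroborated_dataset(self):
        summary = tier_evidence([_record("d1", [3000], corroboration=0.8)], N)
        assert summary.tier == "single_dataset"
        assert summary.model_corroborated

    def test_corroboration_below_threshold(self):
        summary = tier_evidence([_record("d1", [3000], corroboration=0.3)], N)
        assert not summary.model_corroborated

    def test_lone_peak_among_many_is_discordant_only(self):
        records = [_record("d1", [3000]), _record("d2", []), _record("d3", [])]
        summary = tier_evidence(records, N)
        assert summary.tier == "discordant_only" and summary.discordant

    def test_no_evidence(self):
        summary = tier_evidence([_record("d1", []), _record("d2", [])], N)
        assert summary.tier == "no_evidence" and not summary.discordant

    def test_permutation_invariance(self):
        records = [
            _record("d1", [3000], reagent=("antibody", "abA")),
            _record("d2", [3010], reagent=("epitope_tag", "gfp")),
            _record("d3", []),
            _record("d4", [9000], reagent=("antibody", "abA")),
        ]
        tiers = set()
        for perm in itertools.permutations(records):
            s = tier_evidence(list(perm), N)
            tiers.add((s.tier, s.discordant, s.n_with_peaks))
        assert len(tiers) == 1

    def test_adding_peakless_dataset_never_raises_tier(self):
        base = [_record("d1", [3000], reagent=("antibody", "abA")),
                _record("d2", [3010], reagent=("antibody", "abB"))]
        order = ["no_evidence", "discordant_only", "single_dataset",
                 "replicated_same_reagent", "orthogonally_replicated"]
        before = tier_evidence(base, N)
        after = tier_evidence(base + [_record("d9", [])], N)
        assert order.index(after.tier) <= order.index(before.tier)
        assert after.discordant

    def test_lot_sensitivity_switch(self):
        records = [
            _record("d1", [3000], reagent=("antibody", "abA"), lot="lot1"),
            _record("d2", [3010], reagent=("antibody", "abA"), lot="lot2"),
        ]
        insensitive = tier_evidence(records, N, lot_sensitive=False)
        sensitive = tier_evidence(records, N, lot_sensitive=True)
        assert insensitive.tier == "replicated_same_reagent"
        assert sensitive.tier == "orthogonally_replicated"

    def test_mixed_targets_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            tier_evidence([_record("d1", [], target="A"),
                           _record("d2", [], target="B")], N)


class TestClusterProfiles:
    def test_identical_pair_merges_first(self):
        rng = np.random.default_rng(0)
        a = rng.random(500)
        profiles = np.stack([a, a.copy(), np.ones(500)])
        order, linkage = cluster_profiles(profiles)
        # first merge joins rows 0 and 1 at distance ~ 0
        assert set(linkage[0, :2].astype(int)) == {0, 1}
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_duplicating_a_track_preserves_other_distances(self):
        rng = np.random.default_rng(1)
        profiles = rng.random((4, 300))
        _, link_a = cluster_profiles(profiles)

        def corr_dist(x, y):
            return 1 - np.corrcoef(x / x.sum(), y / y.sum())[0, 1]

        base = corr_dist(profiles[0], profiles[1])
        with_dup = np.vstack([profiles, profiles[2:3]])
        _, link_b = cluster_profiles(with_dup)
        assert corr_dist(with_dup[0], with_dup[1]) == pytest.approx(base)

    def test_shared_sites_cluster_adjacent(self):
        rng = np.random.default_rng(2)
        n = 2000
        profiles = []
        for i in range(10):
            p = rng.poisson(5, n).astype(float)
            if i in (3, 7):  # two datasets share planted sites
                p[500:540] += 400
                p[1500:1540] += 300
            profiles.append(p)
        order, _ = cluster_profiles(np.stack(profiles))
        pos3, pos7 = order.index(3), order.index(7)
        assert abs(pos3 - pos7) == 1

    def test_zero_total_track_excluded(self, caplog):
        profiles = np.stack([np.random.default_rng(3).random(100),
                             np.zeros(100),
                             np.random.default_rng(4).random(100)])
        with caplog.at_level("WARNING"):
            order, linkage = cluster_profiles(profiles)
        assert len(order) == 2

    def test_fewer_than_two_tracks_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(np.ones((1, 50)))

    def test_distance_matrix_properties_via_linkage_heights(self):
        rng = np.random.default_rng(5)
        profiles = rng.random((5, 200))
        _, linkage = cluster_profiles(profiles)
        assert (linkage[:, 2] >= 0).all()


def test_summary_table_columns():
    summary = tier_evidence([_record("d1", [3000], corroboration=0.9)], N)
    table = summary_table([summary])
    assert list(table.loc["TFX", ["tier", "model_corroborated", "discordant"]]) \
        == ["single_dataset", True, False]
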