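"""Profile normalization, PCA embedding, clustering, and DS1/DS2 labels."""

import numpy as np
import pytest
from scipy.stats import ortho_group
from sklearn.metrics import silhouette_score

from lfpevents.classify import (auto_label_clusters, classify_ds,
                                cluster_events, normalize_profiles, pca_embed,
                                swap_labels)
from lfpevents.core import ConfigurationError, EventTable, default_event_row
from lfpevents.csd import CsdParams, CSDStack, event_csd_stack
from lfpevents.pipeline import classify_recording, select_channels


def _stack_from_maps(maps):
    maps = np.asarray(maps, dtype=float)
    n, c, t = maps.shape
    return CSDStack(csd=maps, lfp=np.zeros_like(maps), channels=np.arange(c),
                    event_ids=np.arange(n), times_ms=np.arange(t, dtype=float))


class TestNormalize:
    def test_scale_invariance(self, rng):
        maps = rng.normal(size=(4, 5, 7))
        f1, _ = normalize_profiles(_stack_from_maps(maps))
        f2, _ = normalize_profiles(_stack_from_maps(10.0 * maps))
        np.testing.assert_allclose(f1, f2, rtol=1e-12)

    def test_negative_peak_maps_to_minus_one(self):
        maps = np.zeros((2, 1, 1))
        maps[0, 0, 0] = -5.0
        maps[1, 0, 0] = 2.0
        feats, kept = normalize_profiles(_stack_from_maps(maps))
        assert feats[0, 0] == -1.0 and feats[1, 0] == 1.0

    def test_rows_have_unit_peak(self, rng):
        feats, _ = normalize_profiles(_stack_from_maps(rng.normal(size=(6, 4, 9))))
        np.testing.assert_allclose(np.abs(feats).max(axis=1), 1.0)

    def test_zero_map_excluded(self, rng):
        maps = rng.normal(size=(3, 2, 2))
        maps[1] = 0.0
        feats, kept = normalize_profiles(_stack_from_maps(maps))
        assert kept.tolist() == [0, 2]


class TestPcaEmbed:
    def _clouds(self, rng, n=40, sep=10.0):
        a = rng.normal(size=(n, 6)) * 0.3
        b = rng.normal(size=(n, 6)) * 0.3
        b[:, 0] += sep
        return np.vstack([a, b]), np.repeat([0, 1], n)

    def test_pc1_separates_clouds(self, rng):
        X, y = self._clouds(rng)
        coords, evr = pca_embed(X)
        assert silhouette_score(coords[:, :1], y) > 0.8
        assert evr[0] > 0.9

    def test_identical_events_give_zero_coordinates(self):
        X = np.ones((5, 4))
        coords, evr = pca_embed(X)
        np.testing.assert_array_equal(coords, 0.0)

    def test_rotation_invariance_up_to_sign(self, rng):
        X, _ = self._clouds(rng)
        R = ortho_group.rvs(6, random_state=1)
        c1, _ = pca_embed(X)
        c2, _ = pca_embed(X @ R.T)
        for k in range(2):
            agree = np.allclose(c1[:, k], c2[:, k], atol=1e-8)
            flipped = np.allclose(c1[:, k], -c2[:, k], atol=1e-8)
            assert agree or flipped


class TestCluster:
    def _coords(self, rng, n=60, ratio=10.0):
        spread = 0.3
        a = rng.normal(size=(n, 2)) * spread
        b = rng.normal(size=(n, 2)) * spread
        b[:, 0] += ratio * spread
        return np.vstack([a, b]), np.repeat([0, 1], n)

    def _accuracy(self, labels, y):
        acc = (labels == y).mean()
        return max(acc, 1 - acc)   # label permutation

    def test_kmeans_recovers_partition(self, rng):
        X, y = self._coords(rng)
        labels = cluster_events(X, "kmeans", k=2, seed=0)
        assert self._accuracy(labels, y) >= 0.99

    def test_dbscan_matches_kmeans_on_separated_clouds(self, rng):
        X, y = self._coords(rng)
        labels = cluster_events(X, "dbscan", epsilon=0.5, min_samples=5)
        assert (labels >= 0).all()          # no undefined points
        assert self._accuracy(labels, y) >= 0.99

    def test_single_cloud_kmeans_still_splits(self, rng):
        X = rng.normal(size=(50, 2)) * 0.1
        labels = cluster_events(X, "kmeans", k=2, seed=0)
        assert set(labels) == {0, 1}

    def test_kmeans_k_exceeding_events_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            cluster_events(rng.normal(size=(3, 2)), "kmeans", k=5)


def _two_sink_stack(sink_a=2, sink_b=5, n_per=10, n_ch=8, n_t=11):
    maps = np.zeros((2 * n_per, n_ch, n_t))
    for i in range(n_per):
        maps[i, sink_a, n_t // 2] = -1.0
        maps[n_per + i, sink_b, n_t // 2] = -1.0
    return _stack_from_maps(maps), np.repeat([0, 1], n_per)


class TestAutoLabel:
    def test_sink_near_fissure_is_ds1(self):
        stack, raw = _two_sink_stack()
        res = auto_label_clusters(raw, stack, stack.event_ids,
                                  theta_channel=0, ds_channel=7)
        assert (res.labels[:10] == "1").all()
        assert (res.labels[10:] == "2").all()
        assert res.sink_channel == {"1": 2, "2": 5}

    def test_swapping_planted_depths_swaps_labels(self):
        stack, raw = _two_sink_stack(sink_a=5, sink_b=2)
        res = auto_label_clusters(raw, stack, stack.event_ids,
                                  theta_channel=0, ds_channel=7)
        assert (res.labels[:10] == "2").all()
        assert (res.labels[10:] == "1").all()

    def test_single_cluster_rejected(self):
        stack, _ = _two_sink_stack()
        with pytest.raises(ConfigurationError):
            auto_label_clusters(np.zeros(20, dtype=int), stack,
                                stack.event_ids, 0, 7)

    def test_label_invariant_to_event_order(self, rng):
        stack, raw = _two_sink_stack()
        perm = rng.permutation(20)
        permuted = _stack_from_maps(stack.csd[perm])
        res_p = auto_label_clusters(raw[perm], permuted, permuted.event_ids,
                                    theta_channel=0, ds_channel=7)
        res = auto_label_clusters(raw, stack, stack.event_ids, 0, 7)
        assert res_p.labels.tolist() == res.labels[perm].tolist()


class TestSwap:
    def test_involution(self):
        stack, raw = _two_sink_stack()
        res = auto_label_clusters(raw, stack, stack.event_ids, 0, 7)
        twice = swap_labels(swap_labels(res))
        assert twice.labels.tolist() == res.labels.tolist()
        assert twice.counts == res.counts
        assert twice.sink_channel == res.sink_channel

    def test_counts_exchange_and_provenance(self):
        stack, raw = _two_sink_stack(n_per=7)
        res = auto_label_clusters(raw, stack, stack.event_ids, 0, 7)
        swapped = swap_labels(res)
        assert swapped.counts["1"] == res.counts["2"]
        assert swapped.counts["2"] == res.counts["1"]
        assert swapped.provenance["manual_swaps"] == 1


class TestEndToEnd:
    def test_simulated_classification_matches_truth(self, sim120, processed120):
        _, choice = select_channels(processed120)
        table, stack, result = classify_recording(processed120, choice, seed=0)
        truth = sim120.truth[sim120.truth["kind"] == "ds"]
        from lfpevents.synthetic import ground_truth_match
        m = ground_truth_match(table, truth, tolerance_ms=10.0)
        active = table.active().reset_index(drop=True)
        correct = sum(
            1 for ti, dj, _ in m["matches"]
            if str(truth.iloc[ti]["ds_type"]) == str(active.iloc[dj]["ds_type"]))
        assert len(m["matches"]) >= 2
        assert correct / len(m["matches"]) >= 0.95
        assert result.sink_channel["1"] == sim120.config.oml_channel
        assert result.sink_channel["2"] == sim120.config.mml_channel

    def test_ds_type_column_added_without_touching_others(self, processed120):
        _, choice = select_channels(processed120)
        table, _, _ = classify_recording(processed120, choice, seed=0)
        before = processed120.ds_table.df[
            processed120.ds_table.df["channel"] == choice.ds_channel
        ].reset_index(drop=True)
        after = table.df.reset_index(drop=True)
        for col in before.columns:
            if col == "ds_type":
                continue
            np.testing.assert_array_equal(before[col].to_numpy(),
                                          after[col].to_numpy())
        assert set(after["ds_type"]) <= {"1", "2", "undefined"}

    def test_rerun_same_seed_identical_labels(self, processed120):
        _, choice = select_channels(processed120)
        t1, _, _ = classify_recording(processed120, choice, seed=0)
        t2, _, _ = classify_recording(processed120, choice, seed=0)
        assert t1.df["ds_type"].tolist() == t2.df["ds_type"].tolist()
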