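"""Cluster-based population model: tuning, training, assignment, inference."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from sleepshift import (
    ClassifierSpec,
    assign_cluster,
    cbpm_predict,
    fit_cbpm,
    tune_hdbscan,
)
from sleepshift.cbpm import ClusterConfig, NoClusterStructureError


def blobs(n=150, k=3, sep=12.0, seed=0, d=4):
    X, comp = make_blobs(n_samples=n, centers=k, cluster_std=1.0,
                         center_box=(-sep, sep), random_state=seed, n_features=d)
    return X, comp


@pytest.fixture
def spec():
    return ClassifierSpec("passive-aggressive", seed=0)


class TestTuneHdbscan:
    def test_recovers_three_separated_blobs(self):
        X, _ = blobs(seed=1)
        config = tune_hdbscan(X)
        assert config.n_clusters == 3
        assert config.silhouette > 0.8

    def test_single_blob_has_no_structure(self):
        # grid sized to the sample: tiny min_cluster_size would carve
        # spurious micro-clusters out of plain Gaussian noise
        X = np.random.default_rng(0).normal(size=(120, 4))
        with pytest.raises(NoClusterStructureError):
            tune_hdbscan(X, (30, 40, 50), (10, 15))

    def test_silhouette_matches_pairwise_oracle(self):
        """Recompute the winning silhouette from raw pairwise distances."""
        from sklearn.cluster import HDBSCAN
        from sklearn.preprocessing import StandardScaler

        X, _ = blobs(seed=2)
        config = tune_hdbscan(X)
        Xs = StandardScaler().fit_transform(X)
        labels = HDBSCAN(min_cluster_size=config.min_cluster_size,
                         min_samples=config.min_samples, copy=True).fit_predict(Xs)
        mask = labels >= 0
        P, L = Xs[mask], labels[mask]
        sils = []
        for i in range(len(P)):
            d = np.linalg.norm(P - P[i], axis=1)
            a = d[(L == L[i])].sum() / max(1, (L == L[i]).sum() - 1)
            b = min(d[L == c].mean() for c in np.unique(L) if c != L[i])
            sils.append((b - a) / max(a, b))
        assert config.silhouette == pytest.approx(np.mean(sils), abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="training points"):
            tune_hdbscan(np.zeros((6, 2)))

    def test_grid_scores_cover_full_grid(self):
        X, _ = blobs(seed=3)
        config = tune_hdbscan(X, (5, 10), (1, 5))
        assert len(config.grid_scores) == 4
        assert (config.min_cluster_size, config.min_samples) in [
            (s["min_cluster_size"], s["min_samples"]) for s in config.grid_scores
        ]


class TestFitCbpm:
    def _fitted(self, spec, seed=0, single_class_cluster=False):
        X, comp = blobs(n=120, k=2, sep=15.0, seed=4)
        if single_class_cluster:
            y = np.where(comp == 0, "high", "low")  # each cluster one class
        else:
            # labels mixed inside every cluster -> no augmentation needed
            y = np.where(np.arange(len(X)) % 2 == 0, "high", "low")
        config = tune_hdbscan(X)
        return X, y, fit_cbpm(X, y, config, spec, seed=seed)

    def test_two_mixed_clusters_no_augmentation(self, spec):
        X, y, bank = self._fitted(spec)
        assert bank.n_clusters == 2
        assert all(v == 0 for v in bank.n_augmented.values())

    def test_single_class_cluster_augmented(self, spec):
        X, y, bank = self._fitted(spec, single_class_cluster=True)
        assert any(v > 0 for v in bank.n_augmented.values())
        # every per-cluster model saw both classes: it can emit either label
        for cid in bank.cluster_ids:
            assert set(bank.models[cid].classes_) == {"high", "low"}

    def test_noise_accounting(self, spec):
        X, y, bank = self._fitted(spec)
        n_members = sum((bank.train_cluster_labels == c).sum()
                        for c in bank.cluster_ids)
        assert n_members + bank.n_noise == len(X)

    def test_deterministic_and_permutation_invariant(self, spec):
        X, comp = blobs(n=120, k=2, sep=15.0, seed=5)
        y = np.where(comp == 0, "high", "low")
        config = tune_hdbscan(X)
        probe = np.random.default_rng(0).normal(size=(25, 4)) * 5
        p1 = cbpm_predict(fit_cbpm(X, y, config, spec, seed=3), probe)
        perm = np.random.default_rng(1).permutation(len(X))
        p2 = cbpm_predict(fit_cbpm(X[perm], y[perm], config, spec, seed=3), probe)
        np.testing.assert_array_equal(p1, p2)

    def test_all_noise_is_error(self, spec):
        X = np.random.default_rng(2).normal(size=(40, 3))
        config = ClusterConfig(min_cluster_size=30, min_samples=15,
                               silhouette=0.0, n_clusters=0)
        with pytest.raises(NoClusterStructureError):
            fit_cbpm(X, np.array(["high", "low"] * 20), config, spec, 0)


class TestAssignmentAndPrediction:
    def _bank(self, spec):
        X, comp = blobs(n=140, k=2, sep=15.0, seed=6)
        y = np.where(comp == 0, "high", "low")
        return X, comp, fit_cbpm(X, y, tune_hdbscan(X), spec, seed=1)

    def test_training_point_keeps_its_cluster(self, spec):
        X, comp, bank = self._bank(spec)
        member = np.flatnonzero(bank.train_cluster_labels == bank.cluster_ids[0])[0]
        # recover the raw-space point from the stored standardized copy
        raw = bank.scaler.inverse_transform(bank.train_points[member][None, :])[0]
        assert assign_cluster(bank, raw) == bank.cluster_ids[0]

    def test_every_vector_gets_exactly_one_prediction(self, spec, rng):
        X, comp, bank = self._bank(spec)
        probe = rng.normal(size=(50, 4)) * 30  # far outside the blobs
        preds = cbpm_predict(bank, probe)
        assert preds.shape == (50,)
        assert set(preds) <= {"high", "low"}

    def test_far_noise_point_falls_back_to_nearest_centroid(self, spec):
        X, comp, bank = self._bank(spec)
        c0 = bank.cluster_ids[0]
        # a point beyond cluster 0's centroid, colinear away from the others
        other = bank.cluster_ids[1]
        direction = bank.centroids[c0] - bank.centroids[other]
        far = bank.centroids[c0] + 50 * direction
        raw = bank.scaler.inverse_transform(far[None, :])[0]
        assert assign_cluster(bank, raw) == c0

    def test_opposite_constant_label_clusters_predict_by_region(self, spec):
        r = np.random.default_rng(8)
        X = np.vstack([r.normal(size=(60, 2)) + [-20, 0],
                       r.normal(size=(60, 2)) + [20, 0]])
        y = np.array(["high"] * 60 + ["low"] * 60)
        bank = fit_cbpm(X, y, tune_hdbscan(X), spec, seed=2)
        assert cbpm_predict(bank, np.array([-19.0, 0.5]))[0] == "high"
        assert cbpm_predict(bank, np.array([21.0, -0.5]))[0] == "low"

    def test_centroid_tie_breaks_to_lower_cluster_id(self, spec):
        X, comp, bank = self._bank(spec)
        # construct an exactly equidistant standardized point
        mid = (bank.centroids[bank.cluster_ids[0]]
               + bank.centroids[bank.cluster_ids[1]]) / 2
        d0 = np.linalg.norm(mid - bank.centroids[bank.cluster_ids[0]])
        d1 = np.linalg.norm(mid - bank.centroids[bank.cluster_ids[1]])
        assert d0 == pytest.approx(d1)
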