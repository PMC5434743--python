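import numpy as np
import pytest

from cortconn.clustering import (
    ClusterResult,
    assign_rois,
    build_feature_vectors,
    compute_erp,
    compute_ersp,
    compute_erp_image,
    compute_itc,
    kmeans_cluster,
)

FS = 128.0


class TestERP:
    def test_identical_trials_return_the_trial(self, rng):
        trial = rng.standard_normal(64)
        acts = np.tile(trial[:, None], (1, 7))
        np.testing.assert_allclose(compute_erp(acts), trial)

    def test_noise_erp_shrinks_as_standard_error(self):
        gen = np.random.default_rng(1)
        acts = gen.standard_normal((128, 1000))
        erp = compute_erp(acts)
        # RMS of the mean of N unit-variance trials ~ 1/sqrt(N)
        assert abs(erp.std() * np.sqrt(1000) - 1.0) < 0.15

    def test_single_trial_identity(self, rng):
        trial = rng.standard_normal((30, 1))
        np.testing.assert_allclose(compute_erp(trial), trial[:, 0])


class TestERSP:
    def test_stationary_process_near_zero_db(self):
        gen = np.random.default_rng(2)
        acts = gen.standard_normal((256, 200))
        _, _, ersp = compute_ersp(acts, FS)
        assert np.abs(ersp).max() < 1.5

    def test_late_burst_localized_in_time_and_frequency(self):
        gen = np.random.default_rng(3)
        T, N = 256, 100
        acts = gen.standard_normal((T, N))
        t = np.arange(T) / FS
        burst = 4.0 * np.sin(2 * np.pi * 10 * t) * (t >= 1.0)
        acts += burst[:, None]
        freqs, starts, ersp = compute_ersp(acts, FS, baseline=(0.0, 0.5))
        fi, wi = np.unravel_index(np.argmax(ersp), ersp.shape)
        assert abs(freqs[fi] - 10.0) <= 3.0
        assert starts[wi] >= 0.75

    def test_amplitude_doubling_adds_six_db(self):
        gen = np.random.default_rng(4)
        T, N = 256, 150
        t = np.arange(T) / FS
        base = np.sin(2 * np.pi * 12 * t)[:, None] * (1.0 + (t >= 1.0))[:, None]
        acts = base + 0.05 * gen.standard_normal((T, N))
        freqs, starts, ersp = compute_ersp(acts, FS, baseline=(0.0, 0.5))
        fi = np.argmin(np.abs(freqs - 12.0))
        late = ersp[fi, starts >= 1.0]
        assert abs(np.median(late) - 6.02) < 1.0

    def test_empty_baseline_raises(self, rng):
        with pytest.raises(ValueError):
            compute_ersp(rng.standard_normal((256, 10)), FS, baseline=(90.0, 99.0))


class TestITC:
    def test_identical_trials_give_unity(self, rng):
        trial = rng.standard_normal(256)
        acts = np.tile(trial[:, None], (1, 20))
        _, _, itc = compute_itc(acts, FS)
        np.testing.assert_allclose(itc, 1.0, atol=1e-12)

    def test_random_phases_follow_rayleigh_scaling(self):
        gen = np.random.default_rng(5)
        N = 500
        acts = gen.standard_normal((256, N))
        _, _, itc = compute_itc(acts, FS)
        # expected magnitude of a mean of N random unit phasors: sqrt(pi)/(2 sqrt(N))
        expected = np.sqrt(np.pi) / (2 * np.sqrt(N))
        assert abs(np.mean(itc) - expected) < 0.5 * expected

    def test_bounded_in_unit_interval(self, rng):
        _, _, itc = compute_itc(rng.standard_normal((128, 12)), FS)
        assert np.all(itc >= 0) and np.all(itc <= 1 + 1e-12)

    def test_single_trial_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_itc(rng.standard_normal((128, 1)), FS)


class TestFeatureVectors:
    def make_records(self, model, n, seed=0, T=128, N=12):
        gen = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            g = int(gen.integers(0, model.n_gridpoints))
            scalp = model.K[:, g] + 0.05 * gen.standard_normal(model.n_channels) * np.abs(model.K[:, g]).max()
            recs.append(
                {
                    "ic_id": (0, i),
                    "scalp_map": scalp,
                    "activations": gen.standard_normal((T, N)),
                }
            )
        return recs

    def test_reduced_dimension_is_pca_dims(self, small_model):
        feats = build_feature_vectors(self.make_records(small_model, 15), small_model, FS, pca_dims=10)
        assert all(f.reduced.shape == (10,) for f in feats)

    def test_duplicated_component_identical_reduction(self, small_model):
        recs = self.make_records(small_model, 12)
        recs.append(dict(recs[0], ic_id=(1, 0)))
        feats = build_feature_vectors(recs, small_model, FS, pca_dims=8)
        np.testing.assert_allclose(feats[0].reduced, feats[-1].reduced, atol=1e-8)

    def test_too_few_components_raise(self, small_model):
        with pytest.raises(ValueError, match="pca_dims"):
            build_feature_vectors(self.make_records(small_model, 5), small_model, FS, pca_dims=10)

    def test_pca_scores_match_eigendecomposition_oracle(self):
        """Projection variance equals the top eigenvalues of the covariance
        computed by brute force."""
        from cortconn.clustering import _pca_reduce

        gen = np.random.default_rng(6)
        X = gen.standard_normal((200, 12)) @ np.diag([5, 3, 2] + [0.3] * 9)
        scores = _pca_reduce(X, 3)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T, bias=False)))[::-1]
        var_scores = np.sort(scores.var(axis=0, ddof=1))[::-1]
        np.testing.assert_allclose(var_scores, evals[:3], rtol=1e-8)

    def test_permutation_equivariant(self, small_model):
        recs = self.make_records(small_model, 12, seed=7)
        f1 = build_feature_vectors(recs, small_model, FS, pca_dims=6)
        f2 = build_feature_vectors(recs[::-1], small_model, FS, pca_dims=6)
        r1 = {f.ic_id: f.reduced for f in f1}
        r2 = {f.ic_id: f.reduced for f in f2}
        for k in r1:
            np.testing.assert_allclose(np.abs(r1[k]), np.abs(r2[k]), atol=1e-8)


class FakeFeature:
    def __init__(self, ic_id, reduced, xyz):
        self.ic_id = ic_id
        self.reduced = np.asarray(reduced, float)
        self.dipole_xyz = np.asarray(xyz, float)


class TestKMeans:
    def test_separated_blobs_recovered_exactly(self):
        gen = np.random.default_rng(7)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        feats = []
        labels_true = []
        for ci, c in enumerate(centers):
            for i in range(20):
                v = c + 0.3 * gen.standard_normal(2)
                feats.append(FakeFeature((0, len(feats)), v, [0, 0, 0]))
                labels_true.append(ci)
        res = kmeans_cluster(feats, K=3, seed=0)
        from sklearn.metrics import adjusted_rand_score

        pred = [res.assignments[f.ic_id] for f in feats]
        assert adjusted_rand_score(labels_true, pred) == 1.0

    def test_k_one_centroid_is_grand_mean(self, rng):
        feats = [FakeFeature((0, i), rng.standard_normal(4), [0, 0, 0]) for i in range(10)]
        res = kmeans_cluster(feats, K=1, seed=0)
        X = np.vstack([f.reduced for f in feats])
        np.testing.assert_allclose(res.centroids[0], X.mean(axis=0), atol=1e-10)

    def test_invalid_k_raises(self, rng):
        feats = [FakeFeature((0, i), rng.standard_normal(3), [0, 0, 0]) for i in range(5)]
        with pytest.raises(ValueError):
            kmeans_cluster(feats, K=0)
        with pytest.raises(ValueError):
            kmeans_cluster(feats, K=9)


class TestAssignROIs:
    def test_centroid_at_region_seed_gets_that_region(self, mid_model):
        roi = "L Mot"
        center = mid_model.mesh.vertices[mid_model.roi_map[roi]].mean(axis=0)
        res = ClusterResult(assignments={(0, 0): 0}, centroids=np.zeros((1, 2)), centroid_xyz=center[None])
        labels = assign_rois(res, mid_model)
        assert labels[0][0] == roi

    def test_bilateral_dipole_cloud_yields_two_labels(self, mid_model):
        l_xyz = mid_model.mesh.vertices[mid_model.roi_map["L Occ"]].mean(axis=0)
        r_xyz = mid_model.mesh.vertices[mid_model.roi_map["R Occ"]].mean(axis=0)
        feats = [FakeFeature((0, i), np.zeros(2), l_xyz if i % 2 else r_xyz) for i in range(10)]
        res = ClusterResult(
            assignments={f.ic_id: 0 for f in feats},
            centroids=np.zeros((1, 2)),
            centroid_xyz=((l_xyz + r_xyz) / 2 + l_xyz * 0.02)[None],
        )
        labels = assign_rois(res, mid_model, features=feats)
        assert set(labels[0]) == {"L Occ", "R Occ"}

    def test_midline_merged_region_single_label(self, mid_model):
        sma = mid_model.mesh.vertices[mid_model.roi_map["SMA"]].mean(axis=0)
        feats = [FakeFeature((0, i), np.zeros(2), sma + 0.001 * (-1) ** i) for i in range(6)]
        res = ClusterResult(
            assignments={f.ic_id: 0 for f in feats},
            centroids=np.zeros((1, 2)),
            centroid_xyz=sma[None],
        )
        labels = assign_rois(res, mid_model, features=feats)
        assert labels[0] == ["SMA"]

    def test_centroid_outside_volume_warns_but_assigns(self, mid_model):
        res = ClusterResult(
            assignments={(0, 0): 0}, centroids=np.zeros((1, 2)),
            centroid_xyz=np.array([[0.5, 0.5, 0.5]]),
        )
        with pytest.warns(UserWarning, match="outside"):
            labels = assign_rois(res, mid_model)
        assert len(labels[0]) == 1


class TestERPImage:
    def test_fixed_grid_shape_and_mean_preservation(self, rng):
        acts = rng.standard_normal((100, 40)) + 2.0
        img = compute_erp_image(acts, grid=(8, 8))
        assert img.shape == (8, 8)
        assert abs(img.mean() - acts.mean()) < 0.2


class TestNineRoiRecovery:
    def test_cluster_then_label_recovers_all_nine_regions(self, mid_model):
        """Generative fixture: ICs whose scalp maps come from dipoles inside
        each of the nine regions; K=14 clustering plus nearest-region
        labeling must name all nine ROIs (duplicates allowed)."""
        gen = np.random.default_rng(9)
        recs = []
        t = np.arange(128) / FS
        for rep in range(5):
            for ri, (roi, verts) in enumerate(mid_model.roi_map.items()):
                g = int(gen.choice(verts))
                scalp = mid_model.K[:, g] * (1 + 0.02 * gen.standard_normal())
                scalp = scalp + 0.02 * np.abs(scalp).max() * gen.standard_normal(len(scalp))
                # each region oscillates at its own frequency: functional
                # features support the spatial ones, as in real recordings
                f_roi = 6.0 + 4.0 * ri
                osc = np.sin(2 * np.pi * f_roi * t + gen.uniform(0, 2 * np.pi))
                acts = osc[:, None] + 0.5 * gen.standard_normal((128, 10))
                recs.append({"ic_id": (rep, roi), "scalp_map": scalp, "activations": acts})
        feats = build_feature_vectors(recs, mid_model, FS, pca_dims=10)
        res = kmeans_cluster(feats, K=14, seed=0)
        labels = assign_rois(res, mid_model, features=feats)
        found = {name for lab in labels.values() for name in lab}
        assert found >= set(mid_model.roi_map)
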