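import numpy as np
import pytest

from viewmatch.camera import all_pixel_rays
from viewmatch.models import (
    ModelConfig,
    StimulusDataset,
    extract_features,
    info_nce,
    lfn_render,
    reduce_weights_pca,
    train_model,
)
from viewmatch.nn import Tensor
from viewmatch.observers import make_invariant_features


def small_config(**kw):
    defaults = dict(seed=3, epochs=4, batch_size=4, lr=2e-3, latent_dim=16,
                    enc_channels=(4, 8), field_hidden=16, field_layers=3,
                    hyper_hidden=24, rays_per_image=48, decoder_hidden=32)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestTrainContracts:
    def test_loss_decreases(self, tiny_dataset):
        # the classifier needs a longer run: with ~4 steps per epoch its
        # first-epoch mean is still near the chance plateau
        for kind, objective, epochs, lr in (
            ("lfn", "multi_view", 40, 2e-3),
            ("autoencoder", "single_view", 6, 2e-3),
            ("autoencoder", "multi_view", 6, 2e-3),
            ("contrastive", "multi_view", 6, 2e-3),
            ("classifier", "single_view", 30, 5e-3),
        ):
            model = train_model(kind, objective, tiny_dataset,
                                small_config(epochs=epochs, lr=lr))
            assert model.loss_trace[-1] < model.loss_trace[0], kind

    def test_objective_restrictions(self, tiny_dataset):
        with pytest.raises(ValueError):
            train_model("contrastive", "single_view", tiny_dataset, small_config())
        with pytest.raises(ValueError):
            train_model("classifier", "multi_view", tiny_dataset, small_config())

    def test_multi_view_needs_second_view(self, tiny_dataset):
        single = StimulusDataset(
            tiny_dataset.images[:, :1],
            [p[:1] for p in tiny_dataset.poses],
            tiny_dataset.object_ids,
            [v[:1] for v in tiny_dataset.viewpoint_ids],
            tiny_dataset.categories,
        )
        with pytest.raises(ValueError, match="2 views"):
            train_model("lfn", "multi_view", single, small_config())
        # single-view training runs fine on a one-view-per-object corpus
        model = train_model("autoencoder", "single_view", single,
                            small_config(epochs=2))
        assert len(model.loss_trace) == 2

    def test_fixed_seed_reproducible(self, tiny_dataset):
        a = train_model("contrastive", "multi_view", tiny_dataset, small_config(epochs=3))
        b = train_model("contrastive", "multi_view", tiny_dataset, small_config(epochs=3))
        assert abs(a.loss_trace[-1] - b.loss_trace[-1]) < 1e-12

    def test_autoencoder_beats_mean_image_baseline(self, tiny_dataset):
        model = train_model("autoencoder", "single_view", tiny_dataset,
                            small_config(epochs=150, decoder_hidden=128, lr=3e-3))
        images = tiny_dataset.images.reshape(-1, *tiny_dataset.resolution)
        mean_img = images.mean(axis=0)
        baseline = float(((images - mean_img) ** 2).mean())
        latent = model.encode(images)
        recon = model.decode(latent).data
        trained = float(((images - recon) ** 2).mean())
        assert trained < baseline


class TestInfoNCE:
    def test_closed_form_orthogonal_negative(self):
        # anchor == positive, one orthogonal negative, temperature 1:
        # -log(e / (e + 1)) ~ 0.31326
        anchors = Tensor(np.array([[1.0, 0.0]]))
        cands = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        loss = info_nce(anchors, cands, np.array([0]), temperature=1.0)
        assert loss.data == pytest.approx(-np.log(np.e / (np.e + 1.0)), abs=1e-8)

    def test_scale_invariance_of_cosine_scoring(self):
        rng = np.random.default_rng(0)
        z1 = rng.normal(size=(4, 8))
        z2 = rng.normal(size=(4, 8))
        idx = np.arange(4)
        a = info_nce(Tensor(z1), Tensor(z2), idx, 0.5).data
        b = info_nce(Tensor(z1 * 7.0), Tensor(z2 * 0.2), idx, 0.5).data
        assert a == pytest.approx(b, abs=1e-10)


class TestLFN:
    def test_forward_deterministic_and_shapes(self, tiny_dataset):
        cfg = small_config()
        model = train_model("lfn", "single_view", tiny_dataset, small_config(epochs=1))
        images = tiny_dataset.images[:2, 0]
        lat1, w1 = model.forward(images)
        lat2, w2 = model.forward(images)
        assert lat1.shape == (2, cfg.latent_dim)
        np.testing.assert_array_equal(lat1.data, lat2.data)
        np.testing.assert_array_equal(model.weights_flat(w1), model.weights_flat(w2))

    def test_zero_weights_render_constant(self, tiny_dataset):
        model = train_model("lfn", "single_view", tiny_dataset, small_config(epochs=1))
        flat = np.zeros(model.weights_flat(model.forward(tiny_dataset.images[:1, 0])[1]).shape[1])
        pose = tiny_dataset.poses[0][0]
        img = lfn_render(model, flat, pose)
        # zero weights: every pixel equals the (zero) output-layer bias
        np.testing.assert_allclose(img, 0.0, atol=1e-12)

    def test_render_deterministic(self, tiny_dataset):
        model = train_model("lfn", "multi_view", tiny_dataset, small_config(epochs=2))
        _, weights = model.forward(tiny_dataset.images[:1, 0])
        flat = model.weights_flat(weights)[0]
        pose = tiny_dataset.poses[0][1]
        np.testing.assert_array_equal(lfn_render(model, flat, pose),
                                      lfn_render(model, flat, pose))

    def test_weight_flat_round_trip(self, tiny_dataset):
        model = train_model("lfn", "single_view", tiny_dataset, small_config(epochs=1))
        _, weights = model.forward(tiny_dataset.images[:1, 0])
        flat = model.weights_flat(weights)[0]
        back = model.unflatten_weights(flat)
        for orig, rec in zip(weights, back):
            np.testing.assert_array_equal(orig.data[0], rec.data[0])

    def test_hypernetwork_is_image_sensitive(self, tiny_dataset):
        model = train_model("lfn", "multi_view", tiny_dataset, small_config(epochs=3))
        w_a = model.weights_flat(model.forward(tiny_dataset.images[:1, 0])[1])
        w_b = model.weights_flat(model.forward(tiny_dataset.images[1:2, 0])[1])
        assert np.abs(w_a - w_b).max() > 1e-8

    def test_single_scene_overfit_renders_faithfully(self, tiny_dataset):
        # one object, a handful of views: training MSE should fall well
        # below the variance of the target pixels
        one = tiny_dataset.subset([0])
        cfg = small_config(epochs=300, batch_size=1, lr=3e-3, rays_per_image=128)
        model = train_model("lfn", "multi_view", one, cfg)
        h, w = one.resolution
        mses = []
        for v in range(one.n_views):
            _, weights = model.forward(one.images[:1, v])
            img = model.render(weights, one.poses[0][(v + 1) % one.n_views])
            target = one.images[0, (v + 1) % one.n_views]
            mses.append(float(((img.mean(axis=2) - target) ** 2).mean()))
        assert np.mean(mses) < 5e-3


class TestExtractFeatures:
    def test_layer_validation(self, tiny_dataset, tiny_corpus):
        stimuli, _, _ = tiny_corpus
        model = train_model("contrastive", "multi_view", tiny_dataset, small_config(epochs=1))
        with pytest.raises(ValueError, match="invalid"):
            extract_features(model, stimuli[:4], "field_weights")

    def test_lfn_latents_dimension(self, tiny_dataset, tiny_corpus):
        stimuli, _, _ = tiny_corpus
        cfg = small_config(epochs=1)
        model = train_model("lfn", "single_view", tiny_dataset, cfg)
        fs = extract_features(model, stimuli[:6], "latents")
        assert fs.dim == cfg.latent_dim
        assert len(fs) == 6

    def test_identical_stimuli_identical_features(self, tiny_dataset, tiny_corpus):
        stimuli, _, _ = tiny_corpus
        model = train_model("classifier", "single_view", tiny_dataset, small_config(epochs=2))
        a = extract_features(model, stimuli[:3], "penultimate")
        b = extract_features(model, stimuli[:3], "penultimate")
        for key in a.vectors:
            np.testing.assert_array_equal(a[key], b[key])

    def test_contrastive_training_builds_view_invariance(self, tiny_dataset, tiny_corpus):
        stimuli, _, _ = tiny_corpus
        model = train_model("contrastive", "multi_view", tiny_dataset,
                            small_config(epochs=40, batch_size=8))
        fs = extract_features(model, stimuli, "embedding")
        mat, keys = fs.matrix()
        mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
        objs = np.array([k[0] for k in keys])
        sims = mat @ mat.T
        same = np.array([[a == b for b in objs] for a in objs])
        np.fill_diagonal(sims, np.nan)
        np.fill_diagonal(same, False)
        within = np.nanmean(sims[same])
        between = np.nanmean(sims[~same & ~np.isnan(sims)])
        assert within > between


class TestPCA:
    def test_full_rank_projection_preserves_distances(self):
        fs = make_invariant_features([f"o{i}" for i in range(10)], ["v0", "v1"],
                                     dim=6, noise_sd=0.5, seed=0)
        red = reduce_weights_pca(fs, 6)
        mat, keys = fs.matrix()
        red_mat, _ = red.matrix()
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(mat), pdist(red_mat), atol=1e-8)

    def test_low_rank_data_fully_explained(self, rng):
        base = rng.normal(size=(2, 12))
        coeffs = rng.normal(size=(30, 2))
        data = coeffs @ base
        fs_vectors = {(f"o{i}", "v0"): data[i] for i in range(30)}
        from viewmatch.observers import FeatureSet
        fs = FeatureSet(fs_vectors)
        red = reduce_weights_pca(fs, 2)
        explained = red.projection.explained_variance_ratio_.sum()
        assert explained > 0.9999

    def test_component_bound_enforced(self):
        fs = make_invariant_features(["a", "b"], ["v0"], dim=4, seed=1)
        with pytest.raises(ValueError):
            reduce_weights_pca(fs, 5)
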