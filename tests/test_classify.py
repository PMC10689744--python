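"""Spectral-spatial residual network and spectral angle mapper."""

import numpy as np
import pytest

from reefspectra import classify as cl
from reefspectra import nn
from reefspectra import preprocess as pp
from reefspectra import scene as sc
from reefspectra import taxonomy as tx
from reefspectra.cube import HyperspectralCube

from conftest import identity_optics


def tiny_config(**kw):
    base = dict(
        patch_size=3, reduced_channels=4, n_spectral_blocks=1,
        n_spatial_blocks=1, filters=4, epochs=4, batch_size=64, seed=0,
    )
    base.update(kw)
    return cl.SSRNConfig(**base)


class TestModelContracts:
    def test_forward_outputs_probability_simplex(self):
        model = cl.build_model(tiny_config(), n_bands=20, n_classes=4)
        rng = np.random.default_rng(0)
        probs = model.predict_proba_patches(rng.standard_normal((10, 3, 3, 20)))
        assert probs.shape == (10, 4)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_initialization(self):
        a = cl.build_model(tiny_config(seed=9), 20, 3)
        b = cl.build_model(tiny_config(seed=9), 20, 3)
        assert a.checksum() == b.checksum()
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_constant_input_finite_probabilities(self):
        model = cl.build_model(tiny_config(), 8, 2)
        probs = model.predict_proba_patches(np.ones((3, 3, 3, 8), np.float32))
        assert np.all(np.isfinite(probs))
        assert np.all(probs > 0)

    @pytest.mark.parametrize("patch", [2, 1])
    def test_invalid_patch_size(self, patch):
        with pytest.raises(ValueError):
            tiny_config(patch_size=patch)

    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences (float64).

        Biases are nudged off zero so no ReLU pre-activation sits exactly
        at the kink, where the subgradient and the symmetric difference
        quotient legitimately disagree.
        """
        model = cl.build_model(tiny_config(seed=3), n_bands=6, n_classes=3)
        rng = np.random.default_rng(1)
        for k in model.params:
            p = model.params[k].astype(np.float64)
            if k.endswith("_b"):
                p = p + 0.05 * rng.standard_normal(p.shape)
            model.params[k] = p
        x = rng.standard_normal((5, 3, 3, 6))
        y = np.array([0, 1, 2, 0, 1])

        def loss():
            return nn.cross_entropy(nn.softmax(model.forward(x)), y)[0]

        logits, cache = model.forward(x, need_cache=True)
        _, dlogits = nn.cross_entropy(nn.softmax(logits), y)
        grads = model.backward(dlogits.astype(np.float64), cache)
        eps = 1e-6
        for k, p in model.params.items():
            flat = rng.choice(p.size, size=min(5, p.size), replace=False)
            for f in flat:
                idx = np.unravel_index(f, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, abs=1e-4, rel=1e-3), k


class TestTraining:
    def test_separable_classes_reach_high_validation_accuracy(self, trained_setup):
        assert trained_setup["model"].history["val_accuracy"][-1] >= 0.95

    def test_loss_decreases_or_early_stop(self, trained_setup):
        hist = trained_setup["model"].history["train_loss"]
        assert hist[-1] <= hist[0]

    def test_shuffled_labels_give_chance_accuracy(self, trained_setup):
        ann = trained_setup["annotations"]
        cube = trained_setup["cube"]
        rng = np.random.default_rng(0)
        shuffled_rois = []
        cats = [r.category for r in ann.rois]
        perm = rng.permutation(len(cats))
        for roi, j in zip(ann.rois, perm):
            shuffled_rois.append(tx.Roi(roi.transect_id, roi.pixels, cats[j]))
        shuffled = tx.AnnotationSet(rois=shuffled_rois, train_flag=ann.train_flag)
        cfg = cl.SSRNConfig(epochs=6, batch_size=128, seed=1)
        model = cl.build_model(cfg, cube.n_bands, 3)
        model = cl.train(model, cube, shuffled, cfg)
        acc = model.history["val_accuracy"][-1]
        assert abs(acc - 1 / 3) <= 0.15

    def test_class_absent_from_train_rejected(self, trained_setup):
        cube = trained_setup["cube"]
        rois = [
            tx.Roi("T1", np.array([[r, c] for r in range(10, 14) for c in range(4)]), 1),
            tx.Roi("T1", np.array([[r, c] for r in range(20, 24) for c in range(4)]), 2),
        ]
        flag = np.ones(32, dtype=bool)
        flag[16:] = False  # all of category 2 in validation
        ann = tx.AnnotationSet(rois=rois, train_flag=flag)
        cfg = tiny_config()
        model = cl.build_model(cfg, cube.n_bands, 2)
        with pytest.raises(ValueError, match="absent"):
            cl.train(model, cube, ann, cfg)


class TestPredictMap:
    def test_certainty_within_softmax_bounds(self, trained_setup):
        pm = cl.predict_map(trained_setup["model"], trained_setup["cube"])
        off = trained_setup["cube"].plate_mask == False  # noqa: E712
        cert = pm.certainty[off]
        assert np.all(cert >= 1.0 / 3 - 1e-6)
        assert np.all(cert <= 1.0 + 1e-6)

    def test_high_accuracy_on_training_scene(self, trained_setup):
        pm = cl.predict_map(trained_setup["model"], trained_setup["cube"])
        scene = trained_setup["scene"]
        off = ~scene.plate_mask
        acc = (pm.labels[off] == scene.class_map[off]).mean()
        assert acc >= 0.95

    def test_inference_deterministic(self, trained_setup):
        a = cl.predict_map(trained_setup["model"], trained_setup["cube"])
        b = cl.predict_map(trained_setup["model"], trained_setup["cube"])
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.certainty, b.certainty)

    def test_label_is_argmax_of_probabilities(self, trained_setup):
        pm = cl.predict_map(
            trained_setup["model"], trained_setup["cube"], store_probabilities=True
        )
        off = ~trained_setup["cube"].plate_mask
        probs = pm.class_probabilities[off]
        class_arr = np.asarray(pm.class_ids)
        assert np.array_equal(class_arr[probs.argmax(axis=1)], pm.labels[off])
        assert np.allclose(probs.max(axis=1), pm.certainty[off], atol=1e-6)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_band_mismatch_rejected(self, trained_setup, lib3):
        model = trained_setup["model"]
        bad = HyperspectralCube(
            np.ones((10, 10, model.n_bands + 3), np.float32),
            400 + np.arange(model.n_bands + 3),
            np.zeros((10, 10), bool),
        )
        with pytest.raises(ValueError, match=str(model.n_bands)):
            cl.predict_map(model, bad)

    def test_plate_pixels_labeled_plate(self, trained_setup):
        pm = cl.predict_map(trained_setup["model"], trained_setup["cube"])
        plate = trained_setup["cube"].plate_mask
        assert np.all(pm.labels[plate] == cl.PLATE)

    def test_model_save_load_round_trip(self, trained_setup, tmp_path):
        model = trained_setup["model"]
        path = tmp_path / "m.npz"
        cl.save_model(model, path)
        back = cl.load_model(path)
        a = cl.predict_map(model, trained_setup["cube"])
        b = cl.predict_map(back, trained_setup["cube"])
        assert np.array_equal(a.labels, b.labels)


class TestSam:
    def test_endmember_pixel_zero_angle(self, lib3):
        wl = lib3.wavelengths_nm
        px = np.stack([lib3.endmembers[1], lib3.endmembers[2]])[None]
        cube = HyperspectralCube(px, wl, np.zeros((1, 2), bool))
        pm = cl.sam_classify(cube, lib3)
        assert pm.labels[0, 0] == 1
        assert pm.labels[0, 1] == 2

    def test_orthogonal_endmembers(self):
        wl = np.array([400.0, 450, 500, 550, 600])
        e1 = np.array([1.0, 1, 0, 0, 0]) * 0.5
        e2 = np.array([0.0, 0, 0, 1, 1]) * 0.5
        lib = sc.SpectralLibrary(wl, {1: e1, 2: e2}, np.full(5, 0.3))
        cube = HyperspectralCube(e1[None, None], wl, np.zeros((1, 1), bool))
        pm = cl.sam_classify(cube, lib)
        assert pm.labels[0, 0] == 1
        assert pm.certainty[0, 0] == pytest.approx(1.0)  # angle 0 vs pi/2

    def test_zero_norm_pixel_unclassified(self, lib3):
        wl = lib3.wavelengths_nm
        cube = HyperspectralCube(
            np.zeros((1, 1, len(wl)), np.float32), wl, np.zeros((1, 1), bool)
        )
        pm = cl.sam_classify(cube, lib3)
        assert pm.labels[0, 0] == cl.UNCLASSIFIED
        assert pm.certainty[0, 0] == 0.0

    def test_identity_optics_recovers_ground_truth(self, lib3, scene3):
        cube = sc.render_cube(scene3, lib3, identity_optics(121))
        pm = cl.sam_classify(cube, lib3)
        off = ~scene3.plate_mask
        assert np.array_equal(pm.labels[off], scene3.class_map[off])

    def test_ssrn_beats_sam_on_default_benchmark(self):
        """The network must not lose to the spectral-angle baseline on the
        default library, whose last two categories share a spectral shape
        and differ only in albedo (angle-degenerate, like turf vs. bare
        pavement). Both classifiers see the same training information: SAM
        endmembers are the per-category mean training spectra.
        """
        lib = sc.demo_library([1, 2, 3, 4])
        scene = sc.generate_scene(
            [1, 2, 3, 4], [0.3, 0.25, 0.25, 0.2], 0.3, (200, 50), 0.02, seed=12
        )
        optics = sc.default_optics(
            lib.wavelengths_nm, noise_sd_additive=0.002,
            noise_sd_multiplicative=0.01, seed=13,
        )
        pre = pp.preprocess_cube(
            sc.render_cube(scene, lib, optics), lib.plate_reflectance
        )
        ann = tx.split_train_validation(
            tx.sample_rois(scene, 60, 5, seed=14), 0.9, seed=15
        )
        table = ann.subset(train=True)
        endmembers = {
            int(cat): np.clip(
                pre.radiance[sub["row"].to_numpy(), sub["col"].to_numpy()].mean(0),
                0, 1,
            )
            for cat, sub in table.groupby("category")
        }
        sam_lib = sc.SpectralLibrary(
            pre.wavelengths_nm, endmembers, np.full(pre.n_bands, 0.3)
        )
        sam = cl.sam_classify(pre, sam_lib)
        cfg = cl.SSRNConfig(epochs=10, batch_size=128, seed=16)
        model = cl.train(cl.build_model(cfg, pre.n_bands, 4), pre, ann, cfg)
        ssrn = cl.predict_map(model, pre)
        off = ~scene.plate_mask
        acc_sam = (sam.labels[off] == scene.class_map[off]).mean()
        acc_ssrn = (ssrn.labels[off] == scene.class_map[off]).mean()
        assert acc_ssrn >= acc_sam - 1e-9, (acc_ssrn, acc_sam)
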