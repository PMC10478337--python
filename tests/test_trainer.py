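"""Dual-branch training loop: determinism, bookkeeping, gating, reduction."""

import numpy as np
import pytest

from atstseg.ema import EMASchedule, adaptive_coef
from atstseg.io import HUVolume, LabelMask
from atstseg.synthetic import PhantomSpec, make_slice_dataset
from atstseg.trainer import (ATSTSegmenter, TrainConfig, augment, binarize,
                             extract_training_slices, predict_volume, train)

SIDE = 32


@pytest.fixture(scope="module")
def small_data():
    """Small slice dataset at 32x32 so training smoke tests stay fast."""
    spec = PhantomSpec(shape=(32, 32, 4), lesion_radius=(3.0, 6.0))
    data = make_slice_dataset(4, 6, 2, spec=spec, side=SIDE, seed=5)
    xl, yl = data["labeled"]
    xp, yp = data["pseudo"]
    X = np.concatenate([xl, xp])
    y = np.concatenate([yl, yp])
    is_pseudo = np.zeros(len(X), dtype=bool)
    is_pseudo[len(xl):] = True
    return {"X": X, "y": y, "is_pseudo": is_pseudo, "test": data["test"]}


def small_model(**kw):
    base = dict(side=SIDE, base_width=4, depth=2, iters=10, window_len=4,
                random_state=0)
    base.update(kw)
    return ATSTSegmenter(**base)


class TestBinarize:
    def test_inclusive_boundary_and_idempotence(self, rng):
        assert binarize(np.array([0.5]), 0.5)[0] == 1
        p = rng.random((5, 5))
        m = binarize(p)
        np.testing.assert_array_equal(binarize(m.astype(float), 0.5), m)

    def test_monotone_in_threshold(self, rng):
        p = rng.random((8, 8))
        counts = [binarize(p, t).sum() for t in (0.2, 0.5, 0.8)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_threshold_contract(self):
        with pytest.raises(ValueError):
            binarize(np.array([0.5]), 0.0)
        with pytest.raises(ValueError):
            binarize(np.array([1.5]), 0.5)


class TestAugment:
    def test_deterministic_under_seed(self, rng):
        imgs = rng.random((3, 16, 16)).astype(np.float32)
        masks = (rng.random((3, 16, 16)) < 0.4).astype(np.uint8)
        a1 = augment(imgs, masks, np.random.default_rng(9))
        a2 = augment(imgs, masks, np.random.default_rng(9))
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[1], a2[1])

    def test_masks_stay_binary_and_shapes_preserved(self, rng):
        imgs = rng.random((4, 16, 16)).astype(np.float32)
        masks = (rng.random((4, 16, 16)) < 0.4).astype(np.uint8)
        ai, am = augment(imgs, masks, np.random.default_rng(0))
        assert ai.shape == imgs.shape and am.shape == masks.shape
        assert set(np.unique(am)) <= {0, 1}

    def test_flip_is_involution(self, rng):
        img = rng.random((8, 8))
        np.testing.assert_array_equal(img[:, ::-1][:, ::-1], img)


class TestFit:
    def test_bookkeeping_and_eps_log(self, small_data):
        m = small_model().fit(small_data["X"], small_data["y"],
                              is_pseudo=small_data["is_pseudo"])
        h = m.history_
        assert len(h) == 10
        assert m.n_iter_ == 10
        sched = EMASchedule(iters=10)
        assert h.eps.iloc[-1] == pytest.approx(adaptive_coef(10, sched))
        assert h.eps.iloc[0] == pytest.approx(adaptive_coef(1, sched))

    def test_full_run_determinism(self, small_data):
        args = (small_data["X"], small_data["y"])
        kw = {"is_pseudo": small_data["is_pseudo"]}
        m1 = small_model().fit(*args, **kw)
        m2 = small_model().fit(*args, **kw)
        for a, b in zip(m1.clean_weights_, m2.clean_weights_):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(m1.noisy_weights_, m2.noisy_weights_):
            np.testing.assert_array_equal(a, b)
        assert m1.history_.equals(m2.history_)

    def test_warm_up_targets_are_pseudo(self, small_data):
        m = small_model(iters=6, window_len=100).fit(
            small_data["X"], small_data["y"], is_pseudo=small_data["is_pseudo"])
        assert (m.history_.switch_fraction == 0).all()
        assert m.history_.tau.isna().all()

    def test_requires_labeled_samples(self, small_data):
        m = small_model()
        with pytest.raises(ValueError):
            m.fit(small_data["X"], small_data["y"],
                  is_pseudo=np.ones(len(small_data["X"]), dtype=bool))

    def test_branches_start_identical_and_diverge(self, small_data):
        m = small_model(iters=5, use_ema=False).fit(
            small_data["X"], small_data["y"], is_pseudo=small_data["is_pseudo"])
        diffs = [np.abs(a - b).max()
                 for a, b in zip(m.clean_weights_, m.noisy_weights_)]
        assert max(diffs) > 0  # separate gradients after a few steps

    def test_sklearn_protocol(self):
        from sklearn.base import clone
        m = small_model(lambda_max=0.3)
        m2 = clone(m)
        assert m2.get_params()["lambda_max"] == 0.3
        m2.set_params(lambda_max=0.7)
        assert m2.lambda_max == 0.7


class TestReduction:
    def test_lambda0_no_ema_equals_supervised_unet(self, small_data):
        """With every coupling off, fit is bitwise a plain supervised loop.

        The reference loop below re-implements single-branch training
        directly from the nn/losses/augment primitives with the same spawned
        RNG streams; weights must agree exactly after 20 iterations.
        """
        from atstseg.losses import batch_seg_losses_and_logit_grad
        from atstseg.nn import SGD, BackboneConfig, build_backbone

        X, y = small_data["X"], small_data["y"]
        is_pseudo = small_data["is_pseudo"]
        iters = 20
        m = small_model(iters=iters, lambda_max=0.0, use_ema=False,
                        use_atst=False, noisy_grad=False).fit(
                            X, y, is_pseudo=is_pseudo)

        # ---- independent single-branch reference ----
        labeled_idx = np.flatnonzero(~is_pseudo)
        ss = np.random.SeedSequence(0)
        s_init, s_lab, _s_pse, s_aug_lab, _s_aug_pse = ss.spawn(5)
        cfg = BackboneConfig(side=SIDE, base_width=4, depth=2)
        net = build_backbone(cfg, s_init)
        opt = SGD(net.params, 0.05, 0.9)
        rng_lab = np.random.default_rng(s_lab)
        rng_aug = np.random.default_rng(s_aug_lab)
        Xf = np.asarray(X, dtype=np.float32)
        yb_all = (np.asarray(y) > 0.5).astype(np.uint8)
        for it in range(iters):
            opt.lr = 0.05 * 0.1 ** (it / iters)
            bi = rng_lab.choice(labeled_idx, size=4, replace=True)
            xb, yb = augment(Xf[bi], yb_all[bi], rng_aug)
            probs, cache = net.forward(xb, want_grad=True)
            _, dz = batch_seg_losses_and_logit_grad(probs, yb)
            opt.step(net.backward(cache, dz, wrt="logits"))
        for a, b in zip(m.clean_weights_, net.get_weights()):
            np.testing.assert_array_equal(a, b)


class TestPredict:
    def test_predict_proba_range_and_shape(self, small_data):
        m = small_model().fit(small_data["X"], small_data["y"],
                              is_pseudo=small_data["is_pseudo"])
        p = m.predict_proba(small_data["X"][:3])
        assert p.shape == (3, SIDE, SIDE)
        assert p.min() >= 0 and p.max() <= 1
        assert set(np.unique(m.predict(small_data["X"][:3]))) <= {0, 1}

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            small_model().predict_proba(np.zeros((1, SIDE, SIDE)))

    def test_volume_prediction_gated_by_lung(self, small_data):
        m = small_model().fit(small_data["X"], small_data["y"],
                              is_pseudo=small_data["is_pseudo"])
        case = small_data["test"][0]
        probs = predict_volume(m, case["volume"], case["lung"])
        assert probs.shape == case["volume"].shape
        outside = ~case["lung"].voxels.astype(bool)
        assert np.all(probs[outside] == 0)
        ungated = predict_volume(m, case["volume"], None)
        assert ungated.min() >= 0 and ungated.max() <= 1


class TestTrainWrapper:
    def test_train_function_and_config_profiles(self, small_data):
        cfg = TrainConfig(side=SIDE, base_width=4, depth=2, iters=4,
                          window_len=4, seed=1)
        X, y = small_data["X"], small_data["y"]
        lab = ~small_data["is_pseudo"]
        model = train(cfg, (X[lab], y[lab]), (X[~lab], y[~lab]))
        assert model.n_iter_ == 4
        pub = TrainConfig.published_profile()
        assert (pub.iters, pub.side, pub.lr) == (40000, 256, 0.01)
        assert pub.batch_labeled == pub.batch_pseudo == 64

    def test_empty_labeled_set_rejected(self):
        cfg = TrainConfig(side=SIDE, iters=2)
        with pytest.raises(ValueError):
            train(cfg, (np.empty((0, SIDE, SIDE)), np.empty((0, SIDE, SIDE))),
                  None)


class TestExtractSlices:
    def test_empty_lung_slices_dropped(self):
        vox = np.full((16, 16, 3), 40.0, dtype=np.float32)
        vox[4:12, 4:12, 1] = -850.0
        vol = HUVolume(vox, spacing=(1, 1, 1))
        lung = np.zeros((16, 16, 3), dtype=np.uint8)
        lung[4:12, 4:12, 1] = 1
        lesion = np.zeros_like(lung)
        x, y = extract_training_slices(vol, LabelMask(lesion),
                                       LabelMask(lung, role="lung"), 16)
        assert x.shape == (1, 16, 16)  # only the slice with lung kept
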