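import itertools

import numpy as np
import pytest

from seedhsi import synthetic_data as sd
from seedhsi._nn import Adam, Conv3dLayer, DenseLayer, MaxPool3dLayer, Sequential, softmax
from seedhsi.cnn3d import (
    Cnn3dConfig,
    LabeledSeedSet,
    augment,
    conv3d_forward,
    maxpool3d,
    predict_cnn3d,
    split_dataset,
    train_cnn3d,
)


def conv3d_oracle(x, k, bias):
    """Five-nested-loop reference for the valid 3-D convolution."""
    C, D, H, W = x.shape
    Co, Ci, kd, kh, kw = k.shape
    out = np.zeros((Co, D - kd + 1, H - kh + 1, W - kw + 1))
    for co in range(Co):
        for i in range(out.shape[1]):
            for j in range(out.shape[2]):
                for l in range(out.shape[3]):
                    s = 0.0
                    for c, d, h, w in itertools.product(
                        range(Ci), range(kd), range(kh), range(kw)
                    ):
                        s += x[c, i + d, j + h, l + w] * k[co, c, d, h, w]
                    out[co, i, j, l] = s + bias[co]
    return out


def maxpool_oracle(x, pool):
    """Window-scan reference with edge replication for ragged dims."""
    pd, ph, pw = pool
    C, D, H, W = x.shape
    do, ho, wo = -(-D // pd), -(-H // ph), -(-W // pw)
    out = np.empty((C, do, ho, wo))
    for c in range(C):
        for i in range(do):
            for j in range(ho):
                for l in range(wo):
                    win = x[c, i * pd : min((i + 1) * pd, D),
                            j * ph : min((j + 1) * ph, H),
                            l * pw : min((l + 1) * pw, W)]
                    out[c, i, j, l] = win.max()
    return out


class TestConv3dForward:
    def test_all_ones_cube_sums_to_eight(self):
        out = conv3d_forward(np.ones((1, 2, 2, 2)), np.ones((1, 1, 2, 2, 2)), np.zeros(1))
        assert out.shape == (1, 1, 1, 1)
        assert out[0, 0, 0, 0] == 8.0

    def test_identity_kernel_crops_input(self):
        rng = np.random.default_rng(0)
        x = rng.random((1, 4, 5, 6))
        k = np.zeros((1, 1, 2, 2, 2))
        k[0, 0, 0, 0, 0] = 1.0
        out = conv3d_forward(x, k, np.zeros(1))
        np.testing.assert_allclose(out[0], x[0, :3, :4, :5])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        C, Co = rng.integers(1, 3), rng.integers(1, 4)
        D, H, W = rng.integers(3, 6, size=3)
        kd, kh, kw = (rng.integers(1, s + 1) for s in (D, H, W))
        x = rng.normal(size=(C, D, H, W))
        k = rng.normal(size=(Co, C, kd, kh, kw))
        b = rng.normal(size=Co)
        np.testing.assert_allclose(
            conv3d_forward(x, k, b), conv3d_oracle(x, k, b), atol=1e-5
        )

    def test_oversize_kernel_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            conv3d_forward(np.ones((1, 2, 2, 2)), np.ones((1, 1, 3, 2, 2)), np.zeros(1))


class TestMaxPool3d:
    def test_constant_cube_stays_constant(self):
        out = maxpool3d(np.full((2, 4, 4, 4), 0.3), (2, 2, 2))
        np.testing.assert_allclose(out, 0.3)

    def test_single_window_takes_max(self):
        x = np.arange(8, dtype=float).reshape(1, 2, 2, 2)
        x[0, 1, 1, 1] = 7.0
        assert maxpool3d(x, (2, 2, 2))[0, 0, 0, 0] == 7.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_window_scan_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        C = rng.integers(1, 3)
        D, H, W = rng.integers(2, 8, size=3)
        pool = tuple(rng.integers(1, 4, size=3))
        x = rng.normal(size=(C, D, H, W))
        np.testing.assert_allclose(maxpool3d(x, pool), maxpool_oracle(x, pool))

    def test_ragged_dims_use_edge_replication(self):
        x = np.arange(3, dtype=float).reshape(1, 3, 1, 1)
        out = maxpool3d(x, (2, 1, 1))
        np.testing.assert_allclose(out[0, :, 0, 0], [1.0, 2.0])


class TestBackprop:
    """Finite-difference checks of the hand-written gradients."""

    @staticmethod
    def _numeric_grad(f, p, eps=1e-6):
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            old = p[idx]
            p[idx] = old + eps
            hi = f()
            p[idx] = old - eps
            lo = f()
            p[idx] = old
            g[idx] = (hi - lo) / (2 * eps)
        return g

    def test_conv_dense_pool_gradients(self):
        rng = np.random.default_rng(0)
        net = Sequential([
            Conv3dLayer(1, 2, (2, 2, 2), rng),
            MaxPool3dLayer((2, 2, 2)),
        ])
        x = rng.normal(size=(2, 1, 4, 4, 4))
        w = rng.normal(size=2 * 2 * 2 * 2)  # random linear readout

        def loss():
            out = net.forward(x, train=True).reshape(2, -1)
            return float((out @ w).sum())

        base = loss()  # populate caches
        dout = np.broadcast_to(w.reshape(1, 2, 2, 2, 2), (2, 2, 2, 2, 2)).copy()
        grads = net.backward(dout)
        for p, g in zip(net.params, grads):
            np.testing.assert_allclose(g, self._numeric_grad(loss, p), atol=1e-4)

    def test_dense_layer_gradient(self):
        rng = np.random.default_rng(1)
        layer = DenseLayer(3, 2, rng)
        x = rng.normal(size=(4, 3))

        def loss():
            return float(layer.forward(x, train=True).sum())

        loss()
        _, (dW, db) = layer.backward(np.ones((4, 2)))
        np.testing.assert_allclose(dW, self._numeric_grad(loss, layer.W), atol=1e-5)
        np.testing.assert_allclose(db, self._numeric_grad(loss, layer.b), atol=1e-5)


class TestSplitDataset:
    def _set_of(self, counts):
        labels = [cls for cls, n in counts.items() for _ in range(n)]
        # minimal stand-in cubes: split logic only needs labels
        from seedhsi.segmentation import SeedCube

        cubes = [
            SeedCube(data=np.zeros((2, 2, 2), dtype=np.float32),
                     mask=np.ones((2, 2), dtype=bool), class_label=lab)
            for lab in labels
        ]
        return LabeledSeedSet(cubes=cubes, labels=labels)

    def test_forty_items_split_32_4_4(self):
        ds = split_dataset(self._set_of({"A": 40, "B": 40}), (0.8, 0.1, 0.1), rng_seed=0)
        for cls in ("A", "B"):
            counts = {
                s: sum(1 for lab, sp in zip(ds.labels, ds.split) if lab == cls and sp == s)
                for s in ("train", "val", "test")
            }
            assert counts == {"train": 32, "val": 4, "test": 4}

    def test_five_classes_of_40_overall_160_20_20(self):
        ds = split_dataset(self._set_of({c: 40 for c in "ABCDE"}), rng_seed=1)
        from collections import Counter

        totals = Counter(ds.split)
        assert totals == {"train": 160, "val": 20, "test": 20}

    def test_deterministic_for_fixed_seed(self):
        base = self._set_of({"A": 17, "B": 23})
        s1 = split_dataset(base, rng_seed=5).split
        s2 = split_dataset(base, rng_seed=5).split
        assert s1 == s2
        assert split_dataset(base, rng_seed=6).split != s1

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            split_dataset(self._set_of({"A": 40, "B": 2}))

    def test_every_item_in_exactly_one_split(self):
        ds = split_dataset(self._set_of({"A": 13, "B": 29}), rng_seed=2)
        assert all(s in ("train", "val", "test") for s in ds.split)


class TestAugment:
    def _training_set(self, n, chip=8, bands=4):
        rng = np.random.default_rng(0)
        from seedhsi.segmentation import SeedCube

        cubes = []
        for k in range(n):
            mask = np.zeros((chip, chip), dtype=bool)
            mask[2:6, 2:6] = True  # 2-px margin so +/-2 px shifts stay in frame
            data = np.zeros((chip, chip, bands), dtype=np.float32)
            data[mask] = rng.random((mask.sum(), bands))
            cubes.append(SeedCube(data=data, mask=mask, class_label="A", source=f"s{k}"))
        return LabeledSeedSet(cubes=cubes, labels=["A"] * n,
                              split=["train"] * n)

    def test_thirty_originals_grow_to_forty_untouched(self):
        ds = self._training_set(30)
        originals = [c.data.copy() for c in ds.cubes]
        out = augment(ds, per_class_total=40, rng_seed=0)
        assert len(out.cubes) == 40
        for before, after in zip(originals, out.cubes[:30]):
            np.testing.assert_array_equal(before, after.data)
        assert all(lab == "A" for lab in out.labels)
        assert all(s == "train" for s in out.split)

    def test_augmented_spectra_are_spatial_transforms_only(self):
        ds = self._training_set(5)
        out = augment(ds, per_class_total=10, rng_seed=1)
        source_values = {tuple(np.sort(c.data[c.mask], axis=None)) for c in ds.cubes}
        for c in out.cubes[5:]:
            # every augmented cube's masked spectra multiset matches a source
            assert tuple(np.sort(c.data[c.mask], axis=None)) in source_values

    def test_flip_is_involution(self):
        from seedhsi.cnn3d import _apply_transform

        rng = np.random.default_rng(2)
        data = rng.random((6, 6, 3))
        mask = rng.random((6, 6)) > 0.5
        for name in ("hflip", "vflip", "rot180"):
            d1, m1 = _apply_transform(data, mask, name)
            d2, m2 = _apply_transform(d1, m1, name)
            np.testing.assert_array_equal(d2, data)
            np.testing.assert_array_equal(m2, mask)

    def test_target_below_current_rejected(self):
        with pytest.raises(ValueError):
            augment(self._training_set(30), per_class_total=20)


@pytest.fixture(scope="module")
def tiny_trained(models3):
    """3-class, 15 cubes/class, 12x12x16 chips; a few epochs."""
    seed_set, _, _ = sd.generate_dataset(15, models3, chip_hw=(12, 12),
                                         grid=sd.reduced_grid(16), rng_seed=0)
    ds = split_dataset(seed_set, (0.8, 0.1, 0.1), rng_seed=0)
    cfg = Cnn3dConfig(conv_blocks=[(4, (5, 3, 3), (2, 2, 2)), (8, (3, 2, 2), (2, 2, 2))],
                      epochs=4, rng_seed=0)
    model, history = train_cnn3d(ds, cfg)
    return ds, cfg, model, history


class TestTraining:
    def test_loss_decreases_on_separable_fixture(self, tiny_trained):
        _, _, _, history = tiny_trained
        losses = history["train_loss"][:3]
        assert losses[1] <= losses[0] and losses[2] <= losses[1]

    def test_probabilities_normalised_and_deterministic(self, tiny_trained):
        ds, _, model, _ = tiny_trained
        test = ds.subset("test")
        labels1, probs1 = predict_cnn3d(model, test.cubes)
        labels2, probs2 = predict_cnn3d(model, test.cubes)
        np.testing.assert_allclose(probs1.sum(axis=1), 1.0, atol=1e-6)
        assert labels1 == labels2
        np.testing.assert_array_equal(probs1, probs2)

    def test_duplicate_cube_gets_same_prediction(self, tiny_trained):
        ds, _, model, _ = tiny_trained
        cube = ds.cubes[0]
        labels, probs = predict_cnn3d(model, [cube, cube])
        assert labels[0] == labels[1]
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_dim_mismatch_rejected(self, tiny_trained, models3):
        _, _, model, _ = tiny_trained
        other, _, _ = sd.generate_dataset(1, models3, chip_hw=(10, 10),
                                          grid=sd.reduced_grid(16), rng_seed=1)
        with pytest.raises(ValueError, match="shape"):
            predict_cnn3d(model, other.cubes)

    def test_single_class_rejected(self, models3):
        seed_set, _, _ = sd.generate_dataset(4, models3[:1], chip_hw=(8, 8),
                                             grid=sd.reduced_grid(8), rng_seed=0)
        ds = LabeledSeedSet(cubes=seed_set.cubes, labels=seed_set.labels)
        with pytest.raises(ValueError, match="2 classes"):
            train_cnn3d(ds, Cnn3dConfig(epochs=1))

    def test_zero_epoch_training_predicts_without_error(self, models3):
        seed_set, _, _ = sd.generate_dataset(3, models3, chip_hw=(10, 10),
                                             grid=sd.reduced_grid(12), rng_seed=0)
        cfg = Cnn3dConfig(conv_blocks=[(2, (3, 3, 3), (2, 2, 2)),
                                       (4, (3, 2, 2), (2, 2, 2))],
                          epochs=0, rng_seed=0)
        model, history = train_cnn3d(seed_set, cfg)
        assert history["train_loss"] == []
        labels, probs = predict_cnn3d(model, seed_set.cubes)
        assert len(labels) == len(seed_set.cubes)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_training_is_bit_reproducible(self, models3):
        seed_set, _, _ = sd.generate_dataset(10, models3, chip_hw=(10, 10),
                                             grid=sd.reduced_grid(12), rng_seed=0)
        ds = split_dataset(seed_set, (0.8, 0.1, 0.1), rng_seed=0)
        cfg = Cnn3dConfig(conv_blocks=[(2, (3, 3, 3), (2, 2, 2)),
                                       (4, (3, 2, 2), (2, 2, 2))],
                          epochs=2, rng_seed=7)
        m1, h1 = train_cnn3d(ds, cfg)
        m2, h2 = train_cnn3d(ds, cfg)
        assert h1 == h2
        for p1, p2 in zip(m1.net.params, m2.net.params):
            np.testing.assert_array_equal(p1, p2)

    def test_tied_logits_resolve_to_first_class(self):
        probs = softmax(np.zeros((3, 4)))
        assert (probs.argmax(axis=1) == 0).all()


def test_accuracy_monotone_in_class_separation():
    """Held-out accuracy does not decrease as class separation grows."""
    accs = []
    for sep in (0.05, 0.4, 1.2):
        models = sd.make_class_models(3, separation=sep, rng_seed=0, noise_sigma=0.04)
        seed_set, _, _ = sd.generate_dataset(20, models, chip_hw=(12, 12),
                                             grid=sd.reduced_grid(16), rng_seed=0)
        ds = split_dataset(seed_set, (0.8, 0.1, 0.1), rng_seed=0)
        cfg = Cnn3dConfig(conv_blocks=[(4, (5, 3, 3), (2, 2, 2)),
                                       (8, (3, 2, 2), (2, 2, 2))],
                          epochs=10, rng_seed=0)
        model, _ = train_cnn3d(ds, cfg)
        holdout = LabeledSeedSet(
            cubes=[c for c, s in zip(ds.cubes, ds.split) if s != "train"],
            labels=[l for l, s in zip(ds.labels, ds.split) if s != "train"],
        )
        pred, _ = predict_cnn3d(model, holdout.cubes)
        accs.append(np.mean([p == t for p, t in zip(pred, holdout.labels)]))
    assert accs[0] <= accs[1] + 0.15 and accs[1] <= accs[2] + 0.15
    assert accs[2] >= 0.8
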