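"""Augmentation strategies: SDA transforms, Mixup, manifold mixing, set composition."""

import numpy as np
import pytest

from dreamon import (
    MixupConfig,
    SDAConfig,
    build_training_dataset,
    manifold_mixup_step,
    pixel_mixup,
    sample_lambda,
    standard_augment,
)
from dreamon.data import ImageSample, is_one_hot, is_two_sparse, one_hot
from dreamon.nn import Conv2d, Dense, GlobalAvgPool, Sequential, softmax_cross_entropy
from dreamon.nn.models import ResNetClassifier


def _img(seed=0, size=32):
    rng = np.random.default_rng(seed)
    return ImageSample(rng.random((size, size)), one_hot(1))


class TestSDA:
    def test_identity_config(self):
        cfg = SDAConfig(rotation_range=0, hflip_prob=0, brightness_range=0, contrast_range=0)
        img = _img()
        out = standard_augment(img, cfg, seed=3)
        assert np.allclose(out.pixels, img.pixels)
        assert np.allclose(out.label, img.label)

    def test_forced_hflip_is_involution(self):
        cfg = SDAConfig(rotation_range=0, hflip_prob=1.0, brightness_range=0, contrast_range=0)
        img = _img(1)
        twice = standard_augment(standard_augment(img, cfg, seed=5), cfg, seed=6)
        assert np.allclose(twice.pixels, img.pixels)

    def test_rotation_against_coordinate_oracle(self):
        """An off-center dot lands where the plane rotation matrix predicts (<1 px)."""
        size = 33
        img = np.zeros((size, size))
        row0, col0 = 10, 22
        img[row0, col0] = 1.0
        sample = ImageSample(img, one_hot(0))
        cfg = SDAConfig(rotation_range=15, hflip_prob=0, brightness_range=0, contrast_range=0)
        # find a seed whose rotation draw is close to +15 degrees
        for seed in range(400):
            angle = np.random.default_rng(seed).uniform(-15, 15)
            if angle > 14.5:
                break
        out = standard_augment(sample, cfg, seed=seed)
        r, c = np.nonzero(out.pixels)
        w = out.pixels[r, c]
        centroid = np.array([(r * w).sum(), (c * w).sum()]) / w.sum()
        th = np.deg2rad(angle)
        center = (size - 1) / 2
        dy, dx = row0 - center, col0 - center
        expected = np.array(
            [center + dy * np.cos(th) - dx * np.sin(th), center + dy * np.sin(th) + dx * np.cos(th)]
        )
        assert np.linalg.norm(centroid - expected) < 1.0

    def test_label_never_changes(self):
        img = _img(7)
        out = standard_augment(img, SDAConfig(), seed=11)
        assert np.array_equal(out.label, img.label)
        assert 0 <= out.pixels.min() and out.pixels.max() <= 1


class TestLambda:
    def test_beta_symmetry_mean_half(self):
        rng = np.random.default_rng(0)
        cfg = MixupConfig(alpha=0.8)
        draws = np.array([sample_lambda(cfg, rng) for _ in range(100_000)])
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se
        assert draws.min() >= 0 and draws.max() <= 1

    def test_concentration_limit(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_lambda(MixupConfig(alpha=1e4), rng) for _ in range(2000)])
        assert draws.var() < 1e-4


class TestPixelMixup:
    def test_lambda_one_is_identity(self):
        x, y = _img(0), _img(1)
        out = pixel_mixup(x, y, 1.0)
        assert np.array_equal(out.pixels, x.pixels)
        assert np.array_equal(out.label, x.label)

    def test_label_interpolation(self):
        x = ImageSample(np.zeros((8, 8)), one_hot(0))
        y = ImageSample(np.ones((8, 8)), one_hot(1))
        out = pixel_mixup(x, y, 0.2)
        assert np.allclose(out.label, (0.2, 0.8, 0.0))

    def test_half_lambda_symmetry_and_errors(self):
        x, y = _img(2), _img(3)
        assert np.allclose(pixel_mixup(x, y, 0.5).pixels, pixel_mixup(y, x, 0.5).pixels)
        with pytest.raises(ValueError):
            pixel_mixup(x, ImageSample(np.zeros((8, 8)), one_hot(0)), 0.5)


def _stub_model(seed=0):
    rng = np.random.default_rng(seed)
    stage = Sequential([Conv2d(1, 2, 3, 1, 1, rng)])
    head = Sequential([GlobalAvgPool(), Dense(2, 3, rng)])
    return ResNetClassifier([stage], head)


class TestManifoldMixup:
    def test_input_layer_equals_pixel_mixup(self):
        model = _stub_model()
        rng = np.random.default_rng(4)
        xa, xb = rng.random((4, 1, 16, 16)), rng.random((4, 1, 16, 16))
        ya = np.tile([1.0, 0, 0], (4, 1))
        yb = np.tile([0, 1.0, 0], (4, 1))
        lam = 0.3
        loss = manifold_mixup_step(model, (xa, ya), (xb, yb), lam, layer_index=0, train=False)
        logits = model.forward(lam * xa + (1 - lam) * xb, train=False)
        expected, _ = softmax_cross_entropy(logits, lam * ya + (1 - lam) * yb)
        assert loss == pytest.approx(expected, rel=1e-10)

    def test_lambda_one_equals_unmixed_loss(self):
        model = _stub_model(1)
        rng = np.random.default_rng(5)
        xa, xb = rng.random((3, 1, 16, 16)), rng.random((3, 1, 16, 16))
        ya = np.tile([0, 0, 1.0], (3, 1))
        yb = np.tile([0, 1.0, 0], (3, 1))
        loss = manifold_mixup_step(model, (xa, ya), (xb, yb), 1.0, layer_index=1, train=False)
        expected, _ = softmax_cross_entropy(model.forward(xa, train=False), ya)
        assert loss == pytest.approx(expected, rel=1e-10)

    def test_hand_traced_forward_oracle(self):
        """Loss matches an independent numpy re-computation of the stub's forward pass."""
        model = _stub_model(2)
        rng = np.random.default_rng(6)
        xa, xb = rng.random((2, 1, 8, 8)), rng.random((2, 1, 8, 8))
        ya = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        yb = np.array([[0, 0, 1.0], [0, 1.0, 0]])
        lam = 0.6
        loss = manifold_mixup_step(model, (xa, ya), (xb, yb), lam, layer_index=1, train=False)

        conv = model.stages[0].layers[0]
        dense = model.head.layers[1]

        def conv_by_hand(x):
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            out = np.zeros((x.shape[0], 2, 8, 8))
            w = conv.W.value.reshape(2, 1, 3, 3)
            for n in range(x.shape[0]):
                for f in range(2):
                    for i in range(8):
                        for j in range(8):
                            out[n, f, i, j] = (
                                np.sum(xp[n, 0, i : i + 3, j : j + 3] * w[f, 0]) + conv.b.value[f]
                            )
            return out

        h = lam * conv_by_hand(xa) + (1 - lam) * conv_by_hand(xb)
        logits = h.mean(axis=(2, 3)) @ dense.W.value.T + dense.b.value
        p = np.exp(logits - logits.max(1, keepdims=True))
        p /= p.sum(1, keepdims=True)
        t = lam * ya + (1 - lam) * yb
        expected = float(-(t * np.log(p + 1e-12)).sum() / 2)
        assert loss == pytest.approx(expected, rel=1e-9)

    def test_invalid_layer_index(self):
        model = _stub_model()
        x = np.zeros((1, 1, 8, 8))
        y = np.tile([1.0, 0, 0], (1, 1))
        with pytest.raises(ValueError):
            manifold_mixup_step(model, (x, y), (x, y), 0.5, layer_index=2)


@pytest.fixture(scope="module")
def train90(splits130):
    return splits130[0]


class TestComposition:
    def test_vanilla_is_identity(self, train90):
        out = build_training_dataset("vanilla", train90)
        assert len(out) == len(train90)
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(out, train90))

    @pytest.mark.parametrize("strategy", ["sda", "pixel_mixup", "manifold_mixup"])
    def test_doubling_composition(self, train90, strategy):
        out = build_training_dataset(strategy, train90, seed=1)
        assert len(out) == 2 * len(train90)
        labels = out.labels()
        assert np.allclose(labels.sum(axis=1), 1.0)  # simplex closure

    def test_pixel_mixup_records(self, train90):
        out = build_training_dataset("pixel_mixup", train90, seed=2)
        mixed = [s for s in out if s.source == "pixel_mixup"]
        assert len(mixed) == len(train90)
        for s in mixed:
            assert is_one_hot(s.label) or is_two_sparse(s.label)  # <= 2 parent classes
            assert s.parents is not None and len(s.parents) == 2

    def test_manifold_flagging(self, train90):
        out = build_training_dataset("manifold_mixup", train90)
        flagged = [s for s in out if s.source == "manifold_flag"]
        assert len(flagged) == len(train90)
        for s, orig in zip(flagged, train90):
            assert np.array_equal(s.pixels, orig.pixels)

    def test_dream_strategies_need_generated_set(self, train90):
        with pytest.raises(ValueError):
            build_training_dataset("dreamon", train90, generated=None)
        generated = build_training_dataset("vanilla", train90)
        out = build_training_dataset("dreamon", train90, generated=generated)
        assert len(out) == 2 * len(train90)

    def test_dreamon_sda_keeps_generated_labels(self, train90):
        donors = build_training_dataset("vanilla", train90)
        out = build_training_dataset("dreamon_sda", train90, generated=donors, seed=3)
        aug = out[len(train90):]
        assert np.allclose(aug.labels(), donors.labels())
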