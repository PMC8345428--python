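"""Loss function, initialization schemes, and the SGD loop."""

import numpy as np
import pytest

from ptcscreen import (NetworkConfig, TrainingConfig, TrainingSample,
                       init_weights, pixelwise_cross_entropy, train)
from ptcscreen.nn.layers import bilinear_upsample_kernel
from ptcscreen.nn.model import FCNModel


class TestCrossEntropy:
    def test_saturated_logits_near_zero_loss(self):
        labels = np.random.default_rng(0).integers(0, 3, (8, 8))
        scores = np.full((3, 8, 8), -20.0)
        np.put_along_axis(scores, labels[None], 20.0, axis=0)
        loss = pixelwise_cross_entropy(scores, labels, "mean")
        assert loss < 1e-6

    def test_uniform_logits_closed_form(self):
        """All-zero logits with 3 classes: summed loss is N·ln 3."""
        labels = np.random.default_rng(1).integers(0, 3, (16, 16))
        scores = np.zeros((3, 16, 16))
        loss = pixelwise_cross_entropy(scores, labels, "sum")
        assert loss == pytest.approx(16 * 16 * np.log(3), rel=1e-12)

    def test_ignore_label_excluded(self):
        labels = np.full((4, 4), 255)
        labels[0, 0] = 1
        scores = np.zeros((3, 4, 4))
        loss = pixelwise_cross_entropy(scores, labels, "mean")
        assert loss == pytest.approx(np.log(3))

    def test_all_ignored_zero_loss_and_grad(self):
        labels = np.full((4, 4), 255)
        loss, grad = pixelwise_cross_entropy(
            np.random.default_rng(2).normal(size=(3, 4, 4)), labels, "sum",
            return_grad=True)
        assert loss == 0.0
        assert not grad.any()

    def test_invalid_label_rejected(self):
        labels = np.zeros((2, 2), dtype=int)
        labels[0, 0] = 7
        with pytest.raises(ValueError):
            pixelwise_cross_entropy(np.zeros((3, 2, 2)), labels)

    def test_gradient_matches_finite_differences(self):
        """Analytic grad of the 2x2x3 toy agrees with central differences."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(3, 2, 2))
        labels = rng.integers(0, 3, (2, 2))
        for reduction in ("sum", "mean"):
            _, grad = pixelwise_cross_entropy(scores, labels, reduction,
                                              return_grad=True)
            eps = 1e-6
            for idx in np.ndindex(scores.shape):
                sp, sm = scores.copy(), scores.copy()
                sp[idx] += eps
                sm[idx] -= eps
                num = (pixelwise_cross_entropy(sp, labels, reduction)
                       - pixelwise_cross_entropy(sm, labels, reduction)) / (2 * eps)
                assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestInitWeights:
    def test_bilinear_deconv_kernel_closed_form(self, tiny_net_factory):
        """The deconv init equals the factor-32 separable bilinear kernel."""
        model = tiny_net_factory()
        w = model.layer("deconv9").params["W"]
        k = 64
        center = k / 2 - 0.5
        w1d = 1.0 - np.abs(np.arange(k) - center) / (k / 2)
        expected = np.outer(w1d, w1d)
        for c in range(3):
            np.testing.assert_allclose(w[c, c], expected, atol=1e-6)
        # off-diagonal channel pairs carry nothing
        assert not w[0, 1].any()

    def test_same_seed_identical(self, tiny_net_factory):
        m1 = tiny_net_factory(seed=7, scheme="random")
        m2 = tiny_net_factory(seed=7, scheme="random")
        for (l1, p1), (l2, p2) in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(l1.params[p1], l2.params[p2])

    def test_pretrained_fallback_zero_conv8_and_warns(self):
        cfg = NetworkConfig(width_multiplier=1 / 64, input_px=128)
        model = FCNModel(cfg, seed=0)
        with pytest.warns(UserWarning, match="falling back"):
            init_weights(model, scheme="pretrained_backbone", seed=0)
        conv8 = model.layer("conv8")
        assert not conv8.params["W"].any()
        assert not conv8.params["b"].any()
        # backbone convs are not zero
        assert model.layer("conv1_1").params["W"].any()

    def test_unknown_scheme(self, tiny_net_factory):
        model = tiny_net_factory()
        with pytest.raises(ValueError):
            init_weights(model, scheme="imagenet21k")


def _toy_samples(n=2, px=128, seed=0):
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        img = np.full((px, px, 3), 245, dtype=np.uint8)
        lab = np.zeros((px, px), dtype=np.int64)
        cx, cy = rng.integers(30, px - 30, 2)
        yy, xx = np.mgrid[:px, :px]
        blob = (xx - cx) ** 2 + (yy - cy) ** 2 < 24**2
        img[blob] = (110, 50, 140)
        lab[blob] = 2
        samples.append(TrainingSample(image=img, label_map=lab))
    return samples


class TestTrainLoop:
    def test_defaults_are_published_recipe(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 1e-10
        assert cfg.dropout == 0.5
        assert cfg.weight_decay == 0.0005
        assert cfg.loss_reduction == "sum"

    def test_zero_lr_leaves_weights_unchanged(self, tiny_net_factory):
        model = tiny_net_factory(input_px=128)
        before = {(l.name, p): l.params[p].copy()
                  for l, p in model.parameters()}
        cfg = TrainingConfig(learning_rate=0.0, epochs=2, seed=0,
                             loss_reduction="mean", dropout=0.0)
        train(model, _toy_samples(), cfg)
        for lyr, p in model.parameters():
            np.testing.assert_array_equal(lyr.params[p],
                                          before[(lyr.name, p)])

    def test_weight_decay_shrinks_without_data_gradient(self, tiny_net_factory):
        """All-ignore labels: one step multiplies weights by (1 − lr·decay)."""
        model = tiny_net_factory(input_px=128)
        sample = _toy_samples(1)[0]
        sample.label_map[:] = 255
        before = {(l.name, p): l.params[p].copy()
                  for l, p in model.parameters()}
        lr, wd = 0.1, 0.01
        cfg = TrainingConfig(learning_rate=lr, weight_decay=wd, momentum=0.9,
                             epochs=1, seed=0, loss_reduction="mean",
                             dropout=0.0)
        train(model, [sample], cfg)
        for lyr, p in model.parameters():
            np.testing.assert_allclose(
                lyr.params[p], before[(lyr.name, p)] * (1 - lr * wd),
                rtol=1e-5)

    def test_determinism_same_seed(self, tiny_net_factory):
        traces = []
        for _ in range(2):
            model = tiny_net_factory(input_px=128, seed=5, dropout=0.5)
            cfg = TrainingConfig(learning_rate=0.01, epochs=2, seed=9,
                                 loss_reduction="mean", dropout=0.5)
            _, trace = train(model, _toy_samples(), cfg)
            traces.append(trace)
        assert traces[0] == traces[1]

    def test_empty_sample_list_rejected(self, tiny_net_factory):
        with pytest.raises(ValueError):
            train(tiny_net_factory(), [], TrainingConfig(epochs=1))

    def test_loss_decreases_on_learnable_toy(self, tiny_net_factory):
        """A short run on blob tiles cuts the mean loss by half."""
        model = tiny_net_factory(input_px=128, seed=2,
                                 scheme="pretrained_backbone", dropout=0.5)
        cfg = TrainingConfig(learning_rate=0.05, momentum=0.9, epochs=15,
                             seed=4, loss_reduction="mean", dropout=0.5)
        _, trace = train(model, _toy_samples(4, seed=8), cfg)
        assert trace[-1] < 0.5 * trace[0]

    def test_csv_log(self, tiny_net_factory, tmp_path):
        model = tiny_net_factory(input_px=128)
        cfg = TrainingConfig(learning_rate=0.0, epochs=2, seed=0,
                             loss_reduction="mean", dropout=0.0)
        log = tmp_path / "loss.csv"
        train(model, _toy_samples(1), cfg, log_csv=log)
        lines = log.read_text().strip().splitlines()
        assert lines[0] == "epoch,loss"
        assert len(lines) == 3


class TestLayerGradients:
    """Finite-difference checks of the layer backward passes."""

    @pytest.mark.parametrize("layer_name",
                             ["conv1_1", "conv2_1", "conv6", "deconv9"])
    def test_weight_gradients(self, tiny_net_factory, layer_name):
        model = tiny_net_factory(input_px=128, seed=1)
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (128, 128, 3)).astype(np.uint8)
        lab = rng.integers(0, 3, (128, 128)).astype(np.int64)
        x = (img.astype(np.float32) / 255.0).transpose(2, 0, 1)

        scores = model.forward(x, train=True)
        _, g = pixelwise_cross_entropy(scores, lab, "mean", return_grad=True)
        model.backward(g)
        lyr = model.layer(layer_name)
        grad = lyr.grads["W"]
        idx = np.unravel_index(np.abs(grad).argmax(), grad.shape)
        eps = 1e-3
        w = lyr.params["W"]
        old = w[idx]

        def loss_at(val):
            w[idx] = val
            s = model.forward(x, train=False)
            return pixelwise_cross_entropy(s, lab, "mean")

        num = (loss_at(old + eps) - loss_at(old - eps)) / (2 * eps)
        w[idx] = old
        assert grad[idx] == pytest.approx(num, rel=0.05, abs=1e-7)
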