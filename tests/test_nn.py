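"""Network construction, autodiff correctness and the HMM layer gradients."""

import numpy as np
import pytest

import locusnet.alphabet as ab
from locusnet.hmm import build_transitions
from locusnet.losses import cce_f1_loss
from locusnet.nn import autodiff as ad
from locusnet.nn.autodiff import Tensor
from locusnet.nn.hmm_layer import hmm_posteriors, masked_likelihoods
from locusnet.nn.layers import Adam, BiLSTM, Conv1d
from locusnet.nn.network import (
    NetworkConfig,
    SequenceClassifier,
    build_network,
    predict_class_probabilities,
)
from locusnet.nn.training import RandomCropSampler, TrainingConfig, train_pre_hmm


class TestNetworkContract:
    def test_output_shape_and_simplex(self, rng):
        net = build_network(NetworkConfig(preset="tiny", seed=0))
        x = rng.random((2, 99, 6))
        out = net.forward(Tensor(x))
        assert out.shape == (2, 99, 15)
        assert np.allclose(out.data.sum(axis=-1), 1.0, atol=1e-9)

    def test_variable_length_without_rebuild(self, rng):
        net = build_network(NetworkConfig(preset="tiny", seed=0))
        for T in (99, 999):
            out = net.forward(Tensor(rng.random((1, T, 6))))
            assert out.shape == (1, T, 15)

    def test_indivisible_length_rejected(self, rng):
        net = build_network(NetworkConfig(preset="tiny", seed=0))
        with pytest.raises(ValueError):
            net.forward(Tensor(rng.random((1, 100, 6))))

    def test_parameter_budget_presets(self):
        """Halving CNN filter and LSTM unit sizes takes the ~8M full model
        to ~2M (the quadratic LSTM terms quarter)."""
        n_small = build_network(NetworkConfig(preset="small", seed=0)).n_parameters()
        n_full = build_network(NetworkConfig(preset="full", seed=0)).n_parameters()
        assert 6.5e6 <= n_full <= 9.5e6
        assert 1.6e6 <= n_small <= 2.4e6
        assert n_small / n_full == pytest.approx(0.25, rel=0.2)

    def test_prediction_deterministic_and_pads(self, rng):
        net = build_network(NetworkConfig(preset="tiny", seed=0))
        enc = rng.random((100, 6)).astype(np.float32)  # not divisible by 9
        a = predict_class_probabilities(net, enc).probabilities
        b = predict_class_probabilities(net, enc).probabilities
        assert a.shape == (100, 15)
        assert np.array_equal(a, b)

    def test_no_softmask_ignores_repeat_channel(self, rng):
        net = build_network(NetworkConfig(preset="tiny", seed=0, use_softmask=False))
        x = rng.random((1, 99, 6))
        x2 = x.copy()
        x2[:, :, 5] = 1 - x2[:, :, 5]
        a = net.forward(Tensor(x)).data
        b = net.forward(Tensor(x2)).data
        assert np.allclose(a, b)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = build_network(NetworkConfig(preset="tiny", seed=1))
        path = str(tmp_path / "m.npz")
        net.save(path)
        back = SequenceClassifier.load(path)
        x = rng.random((1, 99, 6))
        assert np.allclose(net.forward(Tensor(x)).data, back.forward(Tensor(x)).data)


def _fd_check(param, loss_fn, grad, rng, n=5, eps=1e-6, tol=1e-4):
    worst = 0.0
    for _ in range(n):
        idx = tuple(int(rng.integers(0, s)) for s in param.data.shape)
        old = param.data[idx]
        param.data[idx] = old + eps
        fp = loss_fn()
        param.data[idx] = old - eps
        fm = loss_fn()
        param.data[idx] = old
        fd = (fp - fm) / (2 * eps)
        worst = max(worst, abs(fd - grad[idx]) / max(1.0, abs(fd)))
    assert worst < tol, worst


class TestGradients:
    def test_conv_and_lstm_against_finite_differences(self, rng):
        conv = Conv1d(4, 6, 9, rng)
        lstm = BiLSTM(6, 5, rng)
        x = rng.random((2, 27, 4))

        def loss_fn():
            with ad.no_grad():
                h = lstm(ad.relu(conv(Tensor(x))))
                return float((h.data ** 2).sum())

        h = lstm(ad.relu(conv(Tensor(x, requires_grad=True))))
        (h * h).sum().backward()
        for p in [conv.W, conv.b, *lstm.parameters()]:
            _fd_check(p, loss_fn, p.grad, rng)

    def test_full_network_loss_gradient(self, rng):
        net = build_network(NetworkConfig(preset="tiny", seed=0))
        x = rng.random((2, 54, 6))
        y = rng.integers(0, 15, (2, 54))

        def loss_fn():
            with ad.no_grad():
                return float(cce_f1_loss(y, net.forward(Tensor(x)).data))

        loss = cce_f1_loss(y, net.forward(Tensor(x)))
        loss.backward()
        for p in (net.convs[0].W, net.lstms[0].params[0], net.head.W):
            _fd_check(p, loss_fn, p.grad, rng)

    def test_hmm_layer_posteriors_and_gradient(self, rng, toy_params):
        B, T = 2, 12
        X = rng.dirichlet(np.ones(15), size=(B, T))
        mask = np.ones((B, T, 15))
        Xt = Tensor(X, requires_grad=True)
        post = hmm_posteriors(masked_likelihoods(Xt, mask, 0.05), toy_params, "free")
        assert np.allclose(post.data.sum(axis=-1), 1.0, atol=1e-9)
        W = rng.random((B, T, 15))
        (post * Tensor(W)).sum().backward()
        g = Xt.grad

        def f(Xv):
            with ad.no_grad():
                p = hmm_posteriors(
                    masked_likelihoods(Tensor(Xv), mask, 0.05), toy_params, "free"
                )
            return float((p.data * W).sum())

        eps, worst = 1e-6, 0.0
        for _ in range(30):
            b, i, j = (int(rng.integers(0, m)) for m in (B, T, 15))
            Xp, Xm = X.copy(), X.copy()
            Xp[b, i, j] += eps
            Xm[b, i, j] -= eps
            fd = (f(Xp) - f(Xm)) / (2 * eps)
            worst = max(worst, abs(fd - g[b, i, j]) / max(1.0, abs(fd)))
        assert worst < 1e-3

    def test_end_to_end_gradient_through_hmm(self, rng, toy_params):
        """Gradient of the posterior loss with respect to a network weight
        is nonzero, finite, and matches finite differences (T<=30 toy)."""
        net = build_network(NetworkConfig(preset="tiny", seed=3))
        x = rng.random((1, 27, 6))
        y = rng.integers(0, 15, (1, 27))
        mask = np.ones((1, 27, 15))

        def full_loss(grad_mode):
            probs = net.forward(Tensor(x))
            lik = masked_likelihoods(probs, mask, 0.05)
            post = hmm_posteriors(lik, toy_params, "free")
            return cce_f1_loss(y, post)

        loss = full_loss(True)
        loss.backward()
        p = net.convs[0].W
        assert np.isfinite(p.grad).all()
        assert np.abs(p.grad).max() > 0

        def loss_fn():
            with ad.no_grad():
                return float(full_loss(False).item())

        _fd_check(p, loss_fn, p.grad, rng, n=5, tol=1e-3)


class TestTrainingLoop:
    def _tiny_setup(self, rng):
        cfg = NetworkConfig(preset="tiny", seed=0)
        net = build_network(cfg)
        X = [(rng.random((198, 6)), rng.integers(0, 15, 198)) for _ in range(6)]
        return net, X

    def test_two_runs_same_seed_identical(self, rng):
        tc = TrainingConfig(window_length=198, batch_size=2, max_steps=5,
                            learning_rate=1e-3, seed=7)
        net1, data = self._tiny_setup(np.random.default_rng(1))
        h1 = train_pre_hmm(net1, data, config=tc)
        net2 = build_network(NetworkConfig(preset="tiny", seed=0))
        h2 = train_pre_hmm(net2, data, config=tc)
        assert h1.losses == h2.losses

    def test_loss_beats_all_ir_baseline(self, small_sim):
        """A briefly trained tiny model beats the constant all-IR predictor
        on genic windows (baseline computed analytically from the labels)."""
        from locusnet.io_formats import encode_input

        _, record, annotation, labels = small_sim
        strand_data = [(encode_input(record, s).matrix, labels[s].labels) for s in "+-"]
        sampler = RandomCropSampler(strand_data, 999)
        net = build_network(NetworkConfig(preset="tiny", seed=0))
        tc = TrainingConfig(window_length=999, batch_size=4, max_steps=60,
                            learning_rate=3e-3, genic_fraction=0.5, seed=0)
        hist = train_pre_hmm(net, sampler, config=tc)
        # baseline: all-IR one-hot prediction on the same sampling mix
        rng = np.random.default_rng(0)
        base_losses = []
        for _ in range(30):
            _, y = sampler.sample(tc, rng)
            P = np.zeros((*y.shape, 15))
            P[..., ab.IR] = 1.0
            base_losses.append(cce_f1_loss(y, P))
        assert np.mean(hist.losses[-10:]) < np.mean(base_losses)
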