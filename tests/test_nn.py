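"""CNN engine contracts: architecture shapes, seeded init, gradient
correctness against finite differences, optimizer behaviour, and the
capacity/phenotype-separability properties."""

import numpy as np
import pytest

import netquant as nq
from netquant.nn import (Conv2D, Dense, DenseBlock, Flatten, MaxPool2, ReLU,
                         Sequential, TrainConfig, build_ol_classifier,
                         build_phenotype, build_pl_stage1,
                         build_pl_stage2_counter, load_model, save_model,
                         train)
from netquant.nn.network import _ce_loss_grad, _mae_loss_grad


class TestBuildContracts:
    def test_stage1_softmax_normalised(self, rng):
        net = build_pl_stage1(width=8, seed=0)
        p = net.predict_proba(rng.random((4, 32, 32, 1)).astype(np.float32))
        assert p.shape == (4, 3)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_counter_outputs_nonnegative(self, rng):
        net = build_pl_stage2_counter((32, 64), width=8, seed=0)
        out = net.predict(rng.standard_normal((2, 32, 64, 3)).astype(
            np.float32))
        assert out.shape == (2, 2)
        assert (out >= 0).all()

    def test_phenotype_and_ol_heads(self, rng):
        ph = build_phenotype((100, 100), width=4, seed=0)
        p = ph.predict_proba(rng.random((2, 100, 100, 1)).astype(np.float32))
        assert p.shape == (2, 2)
        ol = build_ol_classifier(seed=0)
        q = ol.predict_proba(rng.random((2, 56, 56, 1)).astype(np.float32))
        assert q.shape == (2, 3)
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-5)

    def test_seeded_init_reproducible_and_seed_sensitive(self):
        a = build_pl_stage1(width=8, seed=5)
        b = build_pl_stage1(width=8, seed=5)
        c = build_pl_stage1(width=8, seed=6)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa, pb)
        assert any(not np.array_equal(pa, pc)
                   for pa, pc in zip(a.params(), c.params()))

    def test_undersized_input_raises_shape_error(self):
        with pytest.raises(ValueError, match="too small"):
            build_phenotype((20, 20), width=4, seed=0)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients of a mixed conv/pool/dense-block stack agree
        with central differences. Individual entries can disagree where
        the perturbation crosses a rectifier/pooling kink, so agreement is
        asserted in aggregate: high correlation and a small median error.
        """
        rng = np.random.default_rng(0)
        net = Sequential([
            Conv2D(2, 3, rng=rng), ReLU(), MaxPool2(),
            DenseBlock(3, 2, 2, rng=rng), Flatten(),
            Dense(7 * 5 * 5, 4, rng=rng), ReLU(), Dense(4, 3, rng=rng)])
        x = rng.standard_normal((3, 12, 12, 2)).astype(np.float32)
        y = np.array([0, 2, 1])
        out = net.forward(x, train=True)
        _, d = _ce_loss_grad(out, y)
        dx = net.backward(d)
        eps = 5e-3

        def loss_at():
            return _ce_loss_grad(net.forward(x), y)[0]

        def compare(analytic, fd):
            analytic, fd = np.asarray(analytic), np.asarray(fd)
            assert np.corrcoef(analytic, fd)[0, 1] > 0.995
            scale = np.abs(fd).max() + 1e-8
            assert np.median(np.abs(analytic - fd)) < 0.02 * scale

        idxs = [tuple(q) for q in np.stack([
            rng.integers(0, 3, 30), rng.integers(0, 12, 30),
            rng.integers(0, 12, 30), rng.integers(0, 2, 30)]).T]
        fds, ans = [], []
        for idx in idxs:
            orig = x[idx]
            x[idx] = orig + eps
            lp = loss_at()
            x[idx] = orig - eps
            lm = loss_at()
            x[idx] = orig
            fds.append((lp - lm) / (2 * eps))
            ans.append(dx[idx])
        compare(ans, fds)

        _, d = _ce_loss_grad(net.forward(x, train=True), y)
        net.backward(d)
        conv = net.layers[0]
        dW = conv.dW.copy()
        fds, ans = [], []
        for idx in np.ndindex(3, 3, 2, 3):
            orig = conv.W[idx]
            conv.W[idx] = orig + eps
            lp = loss_at()
            conv.W[idx] = orig - eps
            lm = loss_at()
            conv.W[idx] = orig
            fds.append((lp - lm) / (2 * eps))
            ans.append(dW[idx])
        compare(ans, fds)

    def test_mae_loss_gradient_sign(self):
        pred = np.array([[2.0, -1.0]], dtype=np.float32)
        y = np.array([[1.0, 1.0]], dtype=np.float32)
        loss, d = _mae_loss_grad(pred, y)
        assert loss == pytest.approx(1.5)
        assert np.sign(d).tolist() == [[1.0, -1.0]]


class TestTraining:
    def test_single_batch_overfit_and_loss_decrease(self):
        """Capacity sanity: a single easy batch is memorised within 200
        epochs and the final training loss undercuts the initial one."""
        patches, labels = nq.make_patch_arrays(
            ["background", "non_netotic", "netotic"], 10, 32, 0.0, seed=3)
        x = patches.astype(np.float32)[..., None] / 65535.0
        net = build_pl_stage1(width=8, seed=1)
        hist = train(net, x, labels, TrainConfig(epochs=200, seed=1))
        assert (net.predict(x) == labels).mean() == 1.0
        assert hist.train_loss.iloc[-1] < hist.train_loss.iloc[0]

    def test_zero_learning_rate_freezes_weights(self, rng):
        net = build_pl_stage1(width=8, seed=2)
        before = [p.copy() for p in net.params()]
        x = rng.random((8, 32, 32, 1)).astype(np.float32)
        y = rng.integers(0, 3, 8)
        train(net, x, y, TrainConfig(learning_rate=0.0, epochs=1, seed=0))
        for p, b in zip(net.params(), before):
            assert np.array_equal(p, b)

    def test_empty_training_set_rejected(self):
        net = build_pl_stage1(width=8, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(net, np.empty((0, 32, 32, 1), dtype=np.float32),
                  np.empty(0, dtype=int), TrainConfig())

    def test_fixed_seed_reproduces_trajectory(self, rng):
        x = rng.random((24, 32, 32, 1)).astype(np.float32)
        y = rng.integers(0, 3, 24)
        hists = []
        for _ in range(2):
            net = build_pl_stage1(width=8, seed=3)
            hists.append(train(net, x, y, TrainConfig(epochs=2, seed=3)))
        assert np.allclose(hists[0].train_loss, hists[1].train_loss, rtol=0)

    def test_lr_step_schedule_applies(self, rng):
        x = rng.random((8, 32, 32, 1)).astype(np.float32)
        y = rng.integers(0, 3, 8)
        net = build_pl_stage1(width=8, seed=0)
        hist = train(net, x, y,
                     TrainConfig(learning_rate=1e-3, epochs=4,
                                 lr_step=(1e-4, 2), seed=0))
        assert hist.lr.iloc[0] == pytest.approx(1e-3)
        assert hist.lr.iloc[3] == pytest.approx(9e-4)

    def test_save_load_roundtrip(self, tmp_path, rng):
        for net in (build_pl_stage1(width=8, seed=4),
                    build_ol_classifier(seed=4)):
            path = tmp_path / f"{net.name}.npz"
            save_model(net, str(path))
            back = load_model(str(path))
            x = rng.random((2, 40, 40, 1)).astype(np.float32) \
                if net.name == "ol_classifier" \
                else rng.random((2, 32, 32, 1)).astype(np.float32)
            assert np.allclose(net.predict_proba(x), back.predict_proba(x))


class TestPhenotypeSeparabilityBracket:
    """The treatment-subtype dial must bracket an intermediate-accuracy
    regime: indistinguishable subtypes score near chance, fully separated
    ones score high."""

    def _subtype_patchset(self, separation, seed, n=120, size=100):
        rng = np.random.default_rng(seed)
        xs, ys = [], []
        for ci, sub in enumerate(["pma_like", "a23187_like"]):
            for _ in range(n):
                nuc = nq.sample_nucleus("netotic", 0.0, rng, subtype=sub,
                                        subtype_separation=separation)
                xs.append(nq.render_patch(nuc, size,
                                          seed=int(rng.integers(2**31))))
                ys.append(ci)
        x = np.stack(xs).astype(np.float32)[..., None] / 65535.0
        y = np.asarray(ys)
        order = rng.permutation(len(y))
        x, y = x[order], y[order]
        n_tr = int(0.75 * len(y))
        return x[:n_tr], y[:n_tr], x[n_tr:], y[n_tr:]

    def test_separated_subtypes_learnable_overlapping_at_chance(self):
        accs = {}
        for sep in (1.0, 0.0):
            xtr, ytr, xte, yte = self._subtype_patchset(sep, seed=9)
            net = build_phenotype((100, 100), width=16, seed=0)
            train(net, xtr, ytr, TrainConfig(learning_rate=3e-3, epochs=16,
                                             seed=0))
            accs[sep] = (net.predict(xte) == yte).mean()
        assert accs[1.0] >= 0.95
        assert 0.35 <= accs[0.0] <= 0.65
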