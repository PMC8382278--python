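"""Training loop: gradient separation between the two generator losses,
deterministic histories, and end-to-end prediction plumbing."""

import numpy as np
import pytest

from r1hic.autodiff import Tensor
from r1hic.hicdata import ContactMap, SubmatrixPair, scn_normalize
from r1hic.losses import LossWeights, loss_g1, loss_g2
from r1hic.network import HiCGan, NetworkConfig
from r1hic.train import Adam, TrainConfig, fit, make_optimizers, predict, train_step

from conftest import random_symmetric


def toy_pairs(n_pairs=4, m=8, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_pairs):
        lr = rng.random((m, m))
        lr = 0.5 * (lr + lr.T) / m
        hr = rng.random((4 * m, 4 * m))
        hr = 0.5 * (hr + hr.T) / (4 * m)
        out.append(SubmatrixPair(block_pair=(k, k + 1), hr_target=hr, lr_input=lr))
    return out


@pytest.fixture(scope="module")
def tiny_model():
    return HiCGan(NetworkConfig(m=8, c_out=4, gen_channels=4, disc_widths=(4, 8, 8), seed=0))


class TestGradientSeparation:
    def test_g1_loss_touches_no_g2_parameter(self, tiny_model):
        G = tiny_model.generator
        pairs = toy_pairs()
        out = G.forward(np.stack([p.lr_input for p in pairs]), detach_features=True)
        lg1 = loss_g1(
            [out.approx2, out.approx4],
            [Tensor(np.stack([p.lr_down2 for p in pairs])),
             Tensor(np.stack([p.lr_down4 for p in pairs]))],
            window=3,
        )
        for p in G.params() + tiny_model.discriminator.params():
            p.grad = None
        lg1.backward()
        assert all(p.grad is not None for p in G.g1_params())
        assert all(p.grad is None for p in G.g2_params())
        assert all(p.grad is None for p in tiny_model.discriminator.params())

    def test_g2_loss_blocked_from_g1_parameters(self, tiny_model):
        G, D = tiny_model.generator, tiny_model.discriminator
        pairs = toy_pairs(seed=1)
        out = G.forward(np.stack([p.lr_input for p in pairs]), detach_features=True)
        lg2 = loss_g2(
            out.sr, Tensor(np.stack([p.hr_target for p in pairs])),
            D.forward(out.sr), LossWeights(),
        )
        for p in G.params() + D.params():
            p.grad = None
        lg2.backward()
        assert all(p.grad is None for p in G.g1_params())
        assert all(p.grad is not None for p in G.g2_params())

    def test_joint_flow_reaches_g1_when_unblocked(self, tiny_model):
        G = tiny_model.generator
        # the correction head is zero-initialized; give it weight so the
        # feature path carries gradient at all
        G.head.kernel.data[:] = 0.5
        pairs = toy_pairs(seed=2)
        out = G.forward(np.stack([p.lr_input for p in pairs]), detach_features=False)
        for p in G.params():
            p.grad = None
        ((out.sr - 0.01) ** 2.0).mean().backward()
        assert any(p.grad is not None and np.abs(p.grad).max() > 0 for p in G.g1_params())

    def test_finite_difference_confirms_g1_loss_ignores_g2(self):
        # numerically: perturbing a G2 parameter leaves l_G1 unchanged,
        # while perturbing a G1 kernel entry changes it
        model = HiCGan(NetworkConfig(m=8, c_out=2, gen_channels=2, disc_widths=(2, 2, 2), seed=4))
        G = model.generator
        pairs = toy_pairs(n_pairs=1, seed=3)
        lr_in = np.stack([p.lr_input for p in pairs])
        truths = [Tensor(np.stack([p.lr_down2 for p in pairs])),
                  Tensor(np.stack([p.lr_down4 for p in pairs]))]

        def lg1_value():
            out = G.forward(lr_in, detach_features=True)
            return loss_g1([out.approx2, out.approx4], truths, window=3).item()

        base = lg1_value()
        h = G.head.kernel
        h.data[0, 0, 0, 0] += 1e-3
        assert lg1_value() == pytest.approx(base, abs=1e-15)
        h.data[0, 0, 0, 0] -= 1e-3
        k = G.rank1_blocks[0].kernel
        k.data[0, 0] += 1e-3
        assert abs(lg1_value() - base) > 1e-12

    def test_block_changes_analytic_gradient(self):
        # with the block on, l_G2's gradient on G1 kernels is exactly zero;
        # with joint flow it is not
        model = HiCGan(NetworkConfig(m=8, c_out=2, gen_channels=2, disc_widths=(2, 2, 2), seed=5))
        G, D = model.generator, model.discriminator
        G.head.kernel.data[:] = 0.5  # un-zero the head so joint flow is live
        pairs = toy_pairs(n_pairs=1, seed=6)
        lr_in = np.stack([p.lr_input for p in pairs])
        hr = Tensor(np.stack([p.hr_target for p in pairs]))
        grads = {}
        for blocked in (True, False):
            for p in G.params() + D.params():
                p.grad = None
            out = G.forward(lr_in, detach_features=blocked)
            loss_g2(out.sr, hr, D.forward(out.sr), LossWeights()).backward()
            g = G.rank1_blocks[0].kernel.grad
            grads[blocked] = None if g is None else g.copy()
        assert grads[True] is None
        assert grads[False] is not None and np.abs(grads[False]).max() > 0


class TestTrainStep:
    def test_returns_finite_record_and_updates(self, tiny_model):
        pairs = toy_pairs(seed=5)
        opts = make_optimizers(tiny_model, TrainConfig(epochs=1))
        before = tiny_model.generator.rank1_blocks[0].kernel.data.copy()
        rec = train_step(pairs, tiny_model, opts, LossWeights(), dssim_window=3)
        assert set(rec) >= {"loss_g1", "loss_g2", "loss_d", "p_real", "p_fake"}
        assert all(np.isfinite(v) for v in rec.values())
        assert not np.allclose(before, tiny_model.generator.rank1_blocks[0].kernel.data)

    def test_repeated_stepping_halves_g1_loss(self):
        # overfitting one fixed batch: l_G1 drops by >= 50% within 200 steps
        model = HiCGan(NetworkConfig(m=8, c_out=4, gen_channels=4, disc_widths=(4, 4, 4), seed=6))
        pairs = toy_pairs(n_pairs=2, seed=7)
        opts = make_optimizers(model, TrainConfig(epochs=1))
        first = None
        for step in range(200):
            rec = train_step(pairs, model, opts, LossWeights(), dssim_window=3)
            if first is None:
                first = rec["loss_g1"]
            if rec["loss_g1"] <= 0.5 * first:
                break
        assert rec["loss_g1"] <= 0.5 * first


class TestFit:
    def test_history_length_and_determinism(self):
        pairs = toy_pairs(n_pairs=5, seed=8)
        cfg = TrainConfig(epochs=3, batch_size=2, seed=11, dssim_window=3)
        nc = NetworkConfig(m=8, c_out=2, gen_channels=2, disc_widths=(2, 2, 2), seed=11)
        _, h1 = fit(pairs, cfg, nc)
        _, h2 = fit(pairs, cfg, nc)
        assert len(h1) == 3 * int(np.ceil(5 / 2))
        assert [r["loss_g1"] for r in h1.records] == [r["loss_g1"] for r in h2.records]
        assert [r["step"] for r in h1.records] == list(range(len(h1)))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit([], TrainConfig(epochs=1))

    def test_checkpoints_and_history_written(self, tmp_path):
        pairs = toy_pairs(n_pairs=2, seed=9)
        cfg = TrainConfig(epochs=2, batch_size=2, seed=0, dssim_window=3,
                          checkpoint_every=1, run_dir=str(tmp_path))
        nc = NetworkConfig(m=8, c_out=2, gen_channels=2, disc_widths=(2, 2, 2), seed=0)
        fit(pairs, cfg, nc)
        assert (tmp_path / "checkpoint_0001.npz").exists()
        assert (tmp_path / "model_final.npz").exists()
        assert (tmp_path / "history.jsonl").exists()


class TestPredict:
    def _model_and_map(self, m=8, nblocks=4, seed=12):
        model = HiCGan(NetworkConfig(m=m, c_out=2, gen_channels=2, disc_widths=(2, 2, 2), seed=seed))
        N = nblocks * m // 2
        counts = np.rint(random_symmetric(N, seed=seed) * 20 + 1)
        return model, ContactMap("chrP", 40_000, counts)

    def test_output_scale_symmetry_nonnegativity(self):
        model, lr_map = self._model_and_map()
        # 200 kb cutoff keeps only adjacent block pairs: far corners uncovered
        pred, mask = predict(model, lr_map, max_distance_bp=200_000)
        assert pred.N == 4 * lr_map.N
        assert pred.bin_size == lr_map.bin_size // 4
        np.testing.assert_allclose(pred.counts, pred.counts.T)
        assert pred.counts.min() >= 0
        assert mask.shape == pred.counts.shape
        assert mask.any() and not mask.all()

    def test_normalized_input_skips_renormalization(self):
        model, lr_map = self._model_and_map(seed=13)
        norm, _ = scn_normalize(lr_map)
        pred, _ = predict(model, norm, normalized=True, max_distance_bp=10_000_000)
        assert pred.N == 4 * lr_map.N

    def test_supplied_bias_denormalizes(self):
        from r1hic.hicdata import BiasVector

        model, lr_map = self._model_and_map(seed=14)
        pred_raw, _ = predict(model, lr_map, max_distance_bp=10_000_000,
                              hr_bias=BiasVector(np.ones(4 * lr_map.N), True, 1))
        pred_b, _ = predict(model, lr_map, max_distance_bp=10_000_000,
                            hr_bias=BiasVector(np.full(4 * lr_map.N, 2.0), True, 1))
        np.testing.assert_allclose(pred_b.counts, 4.0 * pred_raw.counts, rtol=1e-10)

    def test_too_small_map_rejected(self):
        model, _ = self._model_and_map()
        tiny = ContactMap("c", 40_000, np.ones((4, 4)))
        with pytest.raises(ValueError):
            predict(model, tiny)


def test_adam_converges_on_quadratic():
    from r1hic.autodiff import Parameter

    p = Parameter(np.array([5.0, -3.0]))
    opt = Adam([p], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        ((p - 1.0) ** 2.0).sum().backward()
        opt.step()
    np.testing.assert_allclose(p.data, [1.0, 1.0], atol=1e-3)
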