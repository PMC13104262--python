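"""Losses, gradients, the paired sign test, and the training loop."""

import math

import numpy as np
import pytest

from dockselect.data import make_kfold
from dockselect.objectives import (
    TrainConfig,
    bce_loss,
    exact_ndcg3,
    mixed_loss,
    mse_loss,
    ndcg3_loss,
    paired_test,
    pairwise_logistic_loss,
    train,
    _mse_on_logits,
)
from dockselect.selector import SelectorConfig


def numeric_grad(fn, x, eps=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


class TestBce:
    def test_uniform_soft_labels_closed_form(self):
        # each of the 8 elements contributes exactly ln 2 at logit 0, target 1/2
        val = bce_loss(np.zeros(8), np.full(8, 0.5))
        assert val == pytest.approx(8 * math.log(2), rel=1e-12)

    def test_saturated_correct_is_near_zero(self):
        logits = np.array([50.0, -50.0, 50.0])
        targets = np.array([1.0, 0.0, 1.0])
        assert bce_loss(logits, targets) < 1e-15

    def test_matches_naive_two_term_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = rng.normal(scale=3.0, size=6)
            t = rng.random(6)
            s = 1.0 / (1.0 + np.exp(-z))
            naive = -np.sum(t * np.log(s) + (1 - t) * np.log(1 - s))
            assert bce_loss(z, t) == pytest.approx(naive, abs=1e-6)

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros(2), np.array([0.5, 1.2]))


class TestMse:
    def test_equal_vectors_zero(self):
        assert mse_loss(np.array([0.2, 0.8]), np.array([0.2, 0.8])) == 0.0

    def test_opposite_unit_vectors(self):
        assert mse_loss(np.array([0.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(1.0)

    def test_matches_naive_formula(self):
        rng = np.random.default_rng(1)
        p, t = rng.random(7), rng.random(7)
        assert mse_loss(p, t) == pytest.approx(float(np.mean((p - t) ** 2)), abs=1e-12)


class TestPairwiseLogistic:
    def test_single_pair_zero_gap_is_log2(self):
        assert pairwise_logistic_loss(np.zeros(2), np.array([1.0, 0.0])) == \
            pytest.approx(math.log(2), rel=1e-12)

    def test_all_ties_no_pairs(self):
        assert pairwise_logistic_loss(np.array([3.0, -1.0, 0.0]),
                                      np.full(3, 0.7)) == 0.0

    def test_confident_correct_saturates(self):
        assert pairwise_logistic_loss(np.array([30.0, 0.0]), np.array([1.0, 0.0])) < 1e-12


class TestNdcg3:
    def test_ideal_order_loss_vanishes_at_low_temperature(self):
        logits = np.array([3.0, 2.0, 1.0, 0.0])
        targets = np.array([1.0, 0.7, 0.3, 0.1])
        assert exact_ndcg3(logits, targets) == pytest.approx(1.0)
        assert ndcg3_loss(logits, targets, temperature=0.05) == pytest.approx(0.0, abs=1e-3)

    def test_reversed_order_hand_computed_dcg(self):
        targets = np.array([0.9, 0.5, 0.1])
        logits = np.array([0.0, 1.0, 2.0])      # worst-first ranking
        discounts = 1.0 / np.log2(np.arange(2, 5))
        dcg = float(np.sum(np.array([0.1, 0.5, 0.9]) * discounts))
        idcg = float(np.sum(np.array([0.9, 0.5, 0.1]) * discounts))
        assert exact_ndcg3(logits, targets) == pytest.approx(dcg / idcg)
        assert exact_ndcg3(logits, targets) < 1.0

    def test_uniform_targets_loss_zero(self):
        assert ndcg3_loss(np.array([2.0, -1.0, 0.5]), np.full(3, 0.4)) == 0.0


class TestGradients:
    """Numeric-vs-analytic agreement for every objective."""

    @pytest.mark.parametrize("name", ["bce", "mse_logits", "pairwise", "ndcg3"])
    def test_loss_gradients(self, name):
        rng = np.random.default_rng(42)
        fns = {
            "bce": lambda z, t: bce_loss(z, t, return_grad=True),
            "mse_logits": lambda z, t: _mse_on_logits(z, t, return_grad=True),
            "pairwise": lambda z, t: pairwise_logistic_loss(z, t, return_grad=True),
            "ndcg3": lambda z, t: ndcg3_loss(z, t, return_grad=True),
        }
        plain = {
            "bce": bce_loss,
            "mse_logits": _mse_on_logits,
            "pairwise": pairwise_logistic_loss,
            "ndcg3": ndcg3_loss,
        }
        for _ in range(5):
            z = rng.normal(scale=1.5, size=5)
            t = rng.random(5)
            _, analytic = fns[name](z, t)
            numeric = numeric_grad(lambda zz: plain[name](zz, t), z)
            np.testing.assert_allclose(analytic, numeric, atol=1e-4)

    def test_mse_prob_gradient(self):
        rng = np.random.default_rng(7)
        p, t = rng.random(6), rng.random(6)
        _, g = mse_loss(p, t, return_grad=True)
        np.testing.assert_allclose(g, numeric_grad(lambda pp: mse_loss(pp, t), p),
                                   atol=1e-6)

    def test_network_gradient_full_backprop(self):
        """End-to-end check: analytic parameter gradients vs finite differences."""
        from dockselect.selector import backward_batch, forward_batch, init_params

        cfg = SelectorConfig(d_protein=6, d_ligand=4, attn_dim=3, joint_dim=5,
                             n_resblocks=2, resblock_width=7, m_out=3, seed=3)
        rng = np.random.default_rng(11)
        prot = [rng.normal(size=(k, cfg.d_protein)) for k in (4, 2, 6)]
        lig = rng.normal(size=(3, cfg.d_ligand))
        targets = rng.random((3, cfg.m_out))

        def loss_at(params):
            logits = forward_batch(prot, lig, params, cfg, training=False)
            return sum(bce_loss(logits[r], targets[r]) for r in range(3)) / 3.0

        params = init_params(cfg)
        cache = {}
        logits = forward_batch(prot, lig, params, cfg, training=False, cache=cache)
        dlogits = np.stack([bce_loss(logits[r], targets[r], return_grad=True)[1]
                            for r in range(3)]) / 3.0
        grads = backward_batch(dlogits, params, cfg, cache)

        eps = 1e-6
        arrays = params.trainable()
        for arr, grad in zip(arrays, grads):
            flat = arr.ravel()
            for idx in np.random.default_rng(0).choice(flat.size,
                                                       size=min(4, flat.size),
                                                       replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at(params)
                flat[idx] = orig - eps
                down = loss_at(params)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grad.ravel()[idx] == pytest.approx(numeric, abs=1e-5)


class TestMixedLoss:
    def test_pure_bce_weight_reproduces_bce(self):
        rng = np.random.default_rng(2)
        z, t = rng.normal(size=5), rng.random(5)
        assert mixed_loss(z, t, {"bce": 1.0}) == pytest.approx(bce_loss(z, t))
        v1, g1 = mixed_loss(z, t, {"bce": 1.0}, return_grad=True)
        v2, g2 = bce_loss(z, t, return_grad=True)
        assert v1 == pytest.approx(v2)
        np.testing.assert_allclose(g1, g2)

    def test_weights_combine_linearly(self):
        rng = np.random.default_rng(3)
        z, t = rng.normal(size=5), rng.random(5)
        combo = mixed_loss(z, t, {"bce": 0.5, "mse": 2.0})
        assert combo == pytest.approx(0.5 * bce_loss(z, t) + 2.0 * _mse_on_logits(z, t))


class TestPairedTest:
    def test_identical_vectors_p_one(self):
        v = np.array([1, 0, 1, 1, 0])
        assert paired_test(v, v) == 1.0

    def test_twenty_discordant_one_sided(self):
        a = np.ones(20, dtype=int)
        b = np.zeros(20, dtype=int)
        assert paired_test(a, b) == pytest.approx(2 * 0.5 ** 20, rel=1e-9)

    def test_balanced_discordance_p_one(self):
        a = np.array([1] * 5 + [0] * 5)
        b = np.array([0] * 5 + [1] * 5)
        assert paired_test(a, b) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_test(np.ones(3), np.ones(4))


class TestTrainingLoop:
    def test_smoke_two_epochs(self, small_bench):
        table = small_bench.table
        split = make_kfold(table.instance_ids, k=5, seed=0)
        cfg = SelectorConfig(d_protein=64, d_ligand=32, m_out=table.m, seed=0)
        tc = TrainConfig(max_epochs=2, patience=1, batch_size=64, seed=0)
        report = train(table, small_bench.embeddings, split, 0, cfg, tc)
        assert len(report.epoch_losses) <= 2
        assert all(math.isfinite(x) for x in report.epoch_losses)
        assert 0 <= report.best_epoch < len(report.epoch_losses)

    def test_same_seed_identical_trajectory(self, small_bench):
        table = small_bench.table
        split = make_kfold(table.instance_ids, k=5, seed=0)
        cfg = SelectorConfig(d_protein=64, d_ligand=32, m_out=table.m, seed=0)
        tc = TrainConfig(max_epochs=3, patience=2, batch_size=64, seed=1)
        r1 = train(table, small_bench.embeddings, split, 0, cfg, tc)
        r2 = train(table, small_bench.embeddings, split, 0, cfg, tc)
        assert r1.epoch_losses == r2.epoch_losses
        assert r1.val_metrics == r2.val_metrics

    def test_learns_planted_structure_beyond_sbs(self, small_bench):
        """On a highly separable benchmark the selector must beat the SBS."""
        from dockselect.evaluation import sbs
        from dockselect.selector import forward

        table = small_bench.table
        split = make_kfold(table.instance_ids, k=5, seed=0)
        cfg = SelectorConfig(d_protein=64, d_ligand=32, m_out=table.m, seed=0)
        tc = TrainConfig(max_epochs=30, patience=8, batch_size=64, seed=0)
        report = train(table, small_bench.embeddings, split, 0, cfg, tc)

        row_of = {iid: i for i, iid in enumerate(table.instance_ids)}
        test_idx = [row_of[i] for i in split.test_ids(0)]
        sub = table.subset(test_idx)
        sels = np.array([forward(small_bench.embeddings[iid], report.params, cfg).selected
                         for iid in sub.instance_ids])
        sel_rate = sub.success_relaxed[np.arange(sub.n), sels].mean()
        sbs_rate = sub.success_relaxed[:, sbs(table, "relaxed")].mean()
        assert sel_rate > sbs_rate
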