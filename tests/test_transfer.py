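"""Transfer methods: fine-tuning, autoencoder transfer and CCSA alignment."""

import numpy as np
import pytest

from equibench.benchmark import auroc
from equibench.neural import NetSpec, SDASpec, TrainConfig, glorot_init, predict_proba, sda_pretrain
from equibench.preprocess import l2_normalize_rows
from equibench.transfer import (
    CCSAConfig,
    DomainPair,
    LabeledData,
    ccsa_loss_and_grads,
    ccsa_pair_losses,
    ccsa_train,
    finetune_transfer,
    sda_transfer,
    transfer_best,
)


def _make_pair(rng, p=8, n_source=60, n_target=24, normalize=False):
    def block(n):
        X = rng.normal(size=(n, p))
        y = np.where(X[:, 0] + X[:, 1] + 0.3 * rng.normal(size=n) > 0, 1, -1)
        if normalize:
            X = l2_normalize_rows(X)
        return LabeledData(X, y)

    return DomainPair(
        source=block(n_source),
        target_train=block(n_target),
        target_test=block(n_target),
    )


def _brute_force_pair_losses(Zs, Zt, ys, yt, m):
    sa, s, n_sa, n_s = 0.0, 0.0, 0, 0
    for i in range(len(ys)):
        for j in range(len(yt)):
            d = np.linalg.norm(Zs[i] - Zt[j])
            if (ys[i] > 0) == (yt[j] > 0):
                sa += 0.5 * d**2
                n_sa += 1
            else:
                s += 0.5 * max(0.0, m - d) ** 2
                n_s += 1
    return (sa / n_sa if n_sa else 0.0), (s / n_s if n_s else 0.0)


class TestPairLosses:
    def test_identical_same_label_embeddings_contribute_zero(self):
        Z = np.array([[1.0, 2.0]])
        l_sa, _ = ccsa_pair_losses(Z, Z, np.array([1]), np.array([1]), 0.3)
        assert l_sa == 0.0

    def test_separation_zero_beyond_margin(self):
        Zs = np.array([[0.0, 0.0]])
        Zt = np.array([[0.5, 0.0]])  # distance 0.5 > m = 0.3
        _, l_s = ccsa_pair_losses(Zs, Zt, np.array([1]), np.array([-1]), 0.3)
        assert l_s == 0.0

    def test_separation_hand_value_inside_margin(self):
        Zs = np.array([[0.0]])
        Zt = np.array([[0.1]])  # distance 0.1, m=0.3 -> 0.5 * 0.2^2 = 0.02
        _, l_s = ccsa_pair_losses(Zs, Zt, np.array([1]), np.array([-1]), 0.3)
        assert l_s == pytest.approx(0.02, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        ns, nt, k = rng.integers(2, 20, size=3)
        Zs, Zt = rng.normal(size=(ns, k)), rng.normal(size=(nt, k))
        ys = rng.choice([-1, 1], ns)
        yt = rng.choice([-1, 1], nt)
        got = ccsa_pair_losses(Zs, Zt, ys, yt, 0.3)
        want = _brute_force_pair_losses(Zs, Zt, ys, yt, 0.3)
        assert got == pytest.approx(want, rel=1e-12)

    def test_losses_are_non_negative(self, rng):
        Zs, Zt = rng.normal(size=(6, 3)), rng.normal(size=(5, 3))
        l_sa, l_s = ccsa_pair_losses(
            Zs, Zt, rng.choice([-1, 1], 6), rng.choice([-1, 1], 5), 0.3
        )
        assert l_sa >= 0 and l_s >= 0


class TestCCSALoss:
    @pytest.mark.parametrize("gamma", [0.0, 0.25, 1.0])
    def test_total_decomposes_into_weighted_terms(self, gamma, rng):
        p, k = 6, 5
        params = glorot_init([p, k, 1], rng)
        Xs, Xt = rng.normal(size=(7, p)), rng.normal(size=(4, p))
        ys = (rng.random(7) > 0.5).astype(float)
        yt = (rng.random(4) > 0.5).astype(float)
        cfg = CCSAConfig(gamma=gamma, seed=0)
        total, _, (l_c, l_sa, l_s) = ccsa_loss_and_grads(params, Xs, ys, Xt, yt, cfg)
        # recompute each term independently
        (We, be), (Wh, bh) = params
        Zs = np.maximum(0, Xs @ We + be)
        Zt = np.maximum(0, Xt @ We + be)
        ps = 1 / (1 + np.exp(-(Zs @ Wh + bh)[:, 0]))
        pt = 1 / (1 + np.exp(-(Zt @ Wh + bh)[:, 0]))
        pc = np.clip(np.r_[ps, pt], 1e-7, 1 - 1e-7)
        yc = np.r_[ys, yt]
        ref_c = -np.mean(yc * np.log(pc) + (1 - yc) * np.log(1 - pc))
        ref_sa, ref_s = ccsa_pair_losses(Zs, Zt, 2 * ys - 1, 2 * yt - 1, cfg.margin_m)
        assert l_c == pytest.approx(ref_c, rel=1e-12)
        assert (l_sa, l_s) == pytest.approx((ref_sa, ref_s), rel=1e-12)
        assert total == pytest.approx((1 - gamma) * ref_c + gamma * (ref_sa + ref_s), rel=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        p, k = 4, 3
        params = glorot_init([p, k, 1], rng)
        Xs, Xt = rng.normal(size=(5, p)), rng.normal(size=(3, p))
        ys = (rng.random(5) > 0.5).astype(float)
        yt = (rng.random(3) > 0.5).astype(float)
        cfg = CCSAConfig(gamma=0.4, seed=0)
        _, grads, _ = ccsa_loss_and_grads(params, Xs, ys, Xt, yt, cfg)
        eps, worst = 1e-6, 0.0
        for li, (W, b) in enumerate(params):
            for arr, g in ((W, grads[li][0]), (b, grads[li][1])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    ix = it.multi_index
                    orig = arr[ix]
                    arr[ix] = orig + eps
                    lp, _, _ = ccsa_loss_and_grads(params, Xs, ys, Xt, yt, cfg)
                    arr[ix] = orig - eps
                    lm, _, _ = ccsa_loss_and_grads(params, Xs, ys, Xt, yt, cfg)
                    arr[ix] = orig
                    fd = (lp - lm) / (2 * eps)
                    worst = max(worst, abs(fd - g[ix]) / max(1e-8, abs(fd) + abs(g[ix])))
        assert worst < 1e-5


class TestCCSATrain:
    def test_requires_row_normalized_inputs(self, rng):
        pair = _make_pair(rng, normalize=False)
        with pytest.raises(ValueError, match="normalized"):
            ccsa_train(pair, CCSAConfig(max_iter=2, seed=0))

    def test_deterministic_under_fixed_seed(self, rng):
        pair = _make_pair(rng, normalize=True)
        cfg = CCSAConfig(max_iter=3, hidden_nodes=16, seed=5)
        a = ccsa_train(pair, cfg)
        b = ccsa_train(pair, cfg)
        for (Wa, _), (Wb, _) in zip(a.params, b.params):
            assert np.array_equal(Wa, Wb)

    def test_trained_model_beats_chance_on_target(self, rng):
        pair = _make_pair(rng, n_source=120, n_target=40, normalize=True)
        model = ccsa_train(pair, CCSAConfig(max_iter=30, hidden_nodes=16, seed=1))
        score = auroc(predict_proba(model, pair.target_test.X), pair.target_test.y)
        assert score > 0.6


class TestFineTuning:
    def test_zero_finetune_epochs_returns_source_model(self, rng):
        pair = _make_pair(rng)
        spec = NetSpec(input_nodes=pair.n_features, hidden=(8, 4))
        pre = TrainConfig(batch_size=16, max_iter=5, seed=2)
        fine0 = TrainConfig(lr=0.002, batch_size=10, max_iter=0, seed=3)
        tuned = finetune_transfer(pair, spec, pre, fine0)
        from equibench.neural import train

        source_only = train(spec, pre, pair.source.X, pair.source.y)
        for (Wa, _), (Wb, _) in zip(tuned.params, source_only.params):
            assert np.array_equal(Wa, Wb)

    def test_same_seed_identical_result(self, rng):
        pair = _make_pair(rng)
        spec = NetSpec(input_nodes=pair.n_features, hidden=(8, 4))
        pre = TrainConfig(batch_size=16, max_iter=4, seed=2)
        fine = TrainConfig(lr=0.002, batch_size=10, max_iter=4, seed=3)
        a = finetune_transfer(pair, spec, pre, fine)
        b = finetune_transfer(pair, spec, pre, fine)
        for (Wa, _), (Wb, _) in zip(a.params, b.params):
            assert np.array_equal(Wa, Wb)


class TestSDATransfer:
    def test_classifier_architecture_mirrors_encoder(self, rng):
        pair = _make_pair(rng)
        spec = SDASpec(input_nodes=pair.n_features, code_nodes=8,
                       bottleneck_nodes=4, max_iter=3, seed=4)
        fine = TrainConfig(lr=0.002, batch_size=10, max_iter=2, seed=5)
        model = sda_transfer(pair, spec, fine)
        assert model.spec.hidden == (8, 4)
        assert model.params[0][0].shape == (pair.n_features, 8)
        assert model.params[-1][0].shape == (4, 1)

    def test_encoder_initializes_classifier(self, rng):
        pair = _make_pair(rng)
        spec = SDASpec(input_nodes=pair.n_features, code_nodes=8,
                       bottleneck_nodes=4, max_iter=3, seed=4)
        fine0 = TrainConfig(lr=0.002, batch_size=10, max_iter=0, seed=5)
        model = sda_transfer(pair, spec, fine0)
        X_unlabeled = np.vstack([pair.source.X, pair.target_train.X])
        encoder, _ = sda_pretrain(spec, X_unlabeled)
        for (Wa, ba), (Wb, bb) in zip(model.params[:2], encoder):
            assert np.allclose(Wa, Wb.astype(np.float32))


class TestTransferBest:
    def test_returns_maximum_of_component_methods(self, rng):
        pair = _make_pair(rng, n_source=40, n_target=16)
        seed = 11
        kwargs = dict(
            net_spec=NetSpec(input_nodes=pair.n_features, hidden=(8, 4)),
            pretrain_cfg=TrainConfig(batch_size=16, max_iter=4, seed=seed),
            finetune_cfg=TrainConfig(lr=0.002, batch_size=10, max_iter=4, seed=seed + 1),
            sda_spec=SDASpec(input_nodes=pair.n_features, code_nodes=8,
                             bottleneck_nodes=4, max_iter=3, seed=seed + 2),
            ccsa_cfg=CCSAConfig(max_iter=4, hidden_nodes=16, seed=seed + 3),
        )
        method, best, _ = transfer_best(pair, **kwargs)
        # recompute the three candidates independently
        ft = finetune_transfer(pair, kwargs["net_spec"], kwargs["pretrain_cfg"],
                               kwargs["finetune_cfg"])
        sd = sda_transfer(pair, kwargs["sda_spec"], kwargs["finetune_cfg"])
        norm = DomainPair(
            source=LabeledData(l2_normalize_rows(pair.source.X), pair.source.y),
            target_train=LabeledData(l2_normalize_rows(pair.target_train.X), pair.target_train.y),
            target_test=LabeledData(l2_normalize_rows(pair.target_test.X), pair.target_test.y),
        )
        cc = ccsa_train(norm, kwargs["ccsa_cfg"])
        scores = {
            "finetune": auroc(predict_proba(ft, pair.target_test.X), pair.target_test.y),
            "sda": auroc(predict_proba(sd, pair.target_test.X), pair.target_test.y),
            "ccsa": auroc(predict_proba(cc, norm.target_test.X), norm.target_test.y),
        }
        assert best == pytest.approx(max(scores.values()))
        assert best >= max(scores.values()) - 1e-12  # selection dominance
        assert scores[method] == pytest.approx(best)

    def test_feature_space_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            DomainPair(
                source=LabeledData(rng.normal(size=(5, 4)), np.array([1, -1, 1, -1, 1])),
                target_train=LabeledData(rng.normal(size=(4, 3)), np.array([1, -1, 1, -1])),
                target_test=LabeledData(rng.normal(size=(4, 3)), np.array([1, -1, 1, -1])),
            )
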