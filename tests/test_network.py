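"""Trainable network: consistency with the functional surface, gradients,
parameter accounting, ablation structure, and the sklearn estimator API."""

import numpy as np
import pytest
from sklearn.base import clone

from tsann import TSANNClassifier, TaskAdjacency
from tsann.encoder import EncoderParams, encode_segment
from tsann.fusion import FusionParams, MLPParams, fuse_and_classify
from tsann.graph import BranchParams, branch_forward
from tsann.network import TSANNNetwork


def tiny_network(variants=("plv",), rng=None, **kw):
    kw.setdefault("kernels_per_scale", 2)
    kw.setdefault("hidden1", 4)
    kw.setdefault("hidden2", 3)
    return TSANNNetwork(2, 64, 16.0, variants, rng=rng or np.random.default_rng(0),
                        dtype=np.float64, **kw)


def tiny_adjacency(rng, c=2):
    out = {}
    for lab in ("0", "1"):
        a = np.abs(rng.standard_normal((c, c)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        out[lab] = a
    return TaskAdjacency(method="plv", labels=("0", "1"), adj=out)


class TestNetworkConsistency:
    def test_forward_equals_functional_pipeline(self, rng):
        """The batched autodiff forward reproduces the composition of the
        module-level encoder, branch and fusion functions."""
        net = tiny_network(variants=("plv", "cor"), rng=np.random.default_rng(3))
        ta = {v: tiny_adjacency(np.random.default_rng(10 + i))
              for i, v in enumerate(net.variants)}
        net.set_adjacency({v: (t.norm["0"], t.norm["1"]) for v, t in ta.items()})
        x = rng.standard_normal((3, 2, 64))
        got = net.forward(x).data

        enc_params = EncoderParams(
            kernels=[net.params[f"conv{r}"].data for r in (1, 2, 3)],
            q=[net.params[f"q{r}"].data for r in (1, 2, 3)],
        )
        fusion = FusionParams(
            mlp1={v: MLPParams(*(net.params[f"{v}.mlp1.{n}"].data
                                 for n in ("W1", "b1", "W2", "b2")))
                  for v in net.variants},
            mlp2=MLPParams(*(net.params[f"mlp2.{n}"].data for n in ("W1", "b1", "W2", "b2"))),
        )
        for b in range(3):
            zj = encode_segment(x[b], net.enc_cfg, enc_params)
            branches = {}
            for v in net.variants:
                bp = BranchParams(
                    W_l1=net.params[f"{v}.W_l1"].data, W_l2=net.params[f"{v}.W_l2"].data,
                    W_as=net.params[f"{v}.W_as"].data,
                    P_l1=net.params[f"{v}.P_l1"].data, P_l2=net.params[f"{v}.P_l2"].data,
                )
                branches[v] = branch_forward(zj, ta[v], bp)
            expected = fuse_and_classify(branches, fusion)
            np.testing.assert_allclose(got[b], expected, atol=1e-7)

    def test_gradients_match_finite_differences(self, rng):
        net = tiny_network(variants=("plv",), rng=np.random.default_rng(1))
        ta = tiny_adjacency(np.random.default_rng(2))
        net.set_adjacency({"plv": (ta.norm["0"], ta.norm["1"])})
        x = rng.standard_normal((3, 2, 64))
        y = np.array([0, 1, 1])
        net.loss(x, y, lam=1e-3).backward()
        check = np.random.default_rng(5)
        for name, p in net.params.items():
            for _ in range(2):
                idx = tuple(check.integers(0, s) for s in p.data.shape)
                eps = 1e-6
                p.data[idx] += eps
                lp = net.loss(x, y, lam=1e-3).data.item()
                p.data[idx] -= 2 * eps
                lm = net.loss(x, y, lam=1e-3).data.item()
                p.data[idx] += eps
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(p.grad[idx], rel=1e-4, abs=1e-7), name


class TestStructure:
    def test_shapes_through_graph_stages(self):
        net = tiny_network(variants=("plv",))
        assert net.SK % 4 == 0
        for v in net.variants:
            assert net.params[f"{v}.W_l1"].shape == (net.SK, net.SK // 2)
            assert net.params[f"{v}.W_l2"].shape == (net.SK, net.SK // 2)
            assert net.params[f"{v}.W_as"].shape == (net.SK // 2, net.SK // 4)

    def test_attention_toggles_strictly_reduce_parameters(self):
        full = tiny_network(variants=("plv", "cor")).parameter_count()
        no_k = tiny_network(variants=("plv", "cor"), use_kernel_attention=False).parameter_count()
        no_a = tiny_network(variants=("plv", "cor"), use_adjacency_attention=False).parameter_count()
        neither = tiny_network(variants=("plv", "cor"), use_kernel_attention=False,
                               use_adjacency_attention=False).parameter_count()
        assert no_k < full and no_a < full and neither < min(no_k, no_a)

    def test_cnn_off_uses_raw_samples_as_node_features(self, rng):
        net = tiny_network(variants=("plv",), use_cnn=False)
        assert net.SK == 64
        ta = tiny_adjacency(np.random.default_rng(2))
        net.set_adjacency({"plv": (ta.norm["0"], ta.norm["1"])})
        out = net.forward(rng.standard_normal((2, 2, 64)))
        assert out.shape == (2, 2)

    def test_gcn_off_flattens_encoder_into_fusion(self, rng):
        net = tiny_network(variants=(), use_gcn=False)
        out = net.forward(rng.standard_normal((2, 2, 64)))
        assert out.shape == (2, 2)
        # no graph parameters exist
        assert not any(".W_l1" in n or ".P_l1" in n for n in net.params)

    def test_gcn_on_requires_variants(self):
        with pytest.raises(ValueError, match="non-empty"):
            tiny_network(variants=())

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_every_variant_subset_forward_is_valid(self, rng, k):
        """Removing variants only changes the fusion MLP's input width."""
        from itertools import combinations

        for variants in combinations(("cor", "coh", "plv", "pli"), k):
            net = tiny_network(variants=variants)
            adj = {v: tiny_adjacency(np.random.default_rng(7)) for v in variants}
            net.set_adjacency({v: (t.norm["0"], t.norm["1"]) for v, t in adj.items()})
            assert net.params["mlp2.W1"].shape[0] == 2 * len(variants)
            out = net.forward(rng.standard_normal((2, 2, 64)))
            assert np.isfinite(out.data).all()

    def test_sk_not_divisible_by_four_rejected(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            TSANNNetwork(2, 63, 16.0, ("plv",), use_cnn=False,
                         rng=np.random.default_rng(0))


class TestEstimatorAPI:
    def _data(self, rng, n=24, c=3, t=256, fs=64.0):
        x = rng.standard_normal((n, c, t))
        y = np.array(["a", "b"] * (n // 2))
        # plant a crude class difference so fitting has signal
        tt = np.arange(t) / fs
        x[y == "a", 0] += 2 * np.sin(2 * np.pi * 10 * tt)
        x[y == "b", 1] += 2 * np.sin(2 * np.pi * 10 * tt)
        return x, y

    def test_fit_predict_proba_and_classes(self, rng):
        x, y = self._data(rng)
        est = TSANNClassifier(fs=64.0, variants=("plv",), band=(4.0, 28.0),
                              max_epochs=3, kernels_per_scale=2, random_state=0)
        est.fit(x, y)
        assert list(est.classes_) == ["a", "b"]
        proba = est.predict_proba(x)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert set(est.predict(x)) <= {"a", "b"}
        assert est.n_parameters_ == est.network_.parameter_count()

    def test_same_seed_reproduces_fit_exactly(self, rng):
        x, y = self._data(rng)
        kw = dict(fs=64.0, variants=("plv",), band=(4.0, 28.0), max_epochs=3,
                  kernels_per_scale=2, random_state=42)
        e1 = TSANNClassifier(**kw).fit(x, y)
        e2 = TSANNClassifier(**kw).fit(x, y)
        for n, p in e1.network_.params.items():
            np.testing.assert_array_equal(p.data, e2.network_.params[n].data)

    def test_sklearn_clone_and_params_roundtrip(self):
        est = TSANNClassifier(fs=64.0, max_epochs=7, variants=("plv", "pli"))
        c = clone(est)
        assert c.get_params()["max_epochs"] == 7
        c.set_params(max_epochs=9)
        assert c.max_epochs == 9 and est.max_epochs == 7

    def test_non_binary_labels_rejected(self, rng):
        x, _ = self._data(rng, n=12)
        est = TSANNClassifier(fs=64.0, variants=("plv",), max_epochs=1)
        with pytest.raises(ValueError, match="binary"):
            est.fit(x, np.array(["a", "b", "c"] * 4))

    def test_training_loss_decreases_on_separable_toy(self, rng):
        """Optimization wiring: loss non-increasing over the first epochs."""
        x, y = self._data(rng, n=32)
        est = TSANNClassifier(fs=64.0, variants=("plv",), band=(4.0, 28.0),
                              max_epochs=5, kernels_per_scale=2, lam=0.0,
                              random_state=1)
        est.fit(x, y)
        losses = [h["train_loss"] for h in est.history_]
        assert all(b <= a + 1e-6 for a, b in zip(losses, losses[1:]))
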