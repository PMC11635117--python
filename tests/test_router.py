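"""Query-router oracles, Gumbel-Softmax law, routing invariances, risk head."""

import math

import numpy as np
import pytest

from deeppath.router import (
    ModalityFeatureSet,
    RouterParams,
    fuse,
    risk_head,
    route_logits,
    routed_attention,
    sample_route,
)


def _mlp_oracle(x, W1, b1, W2, b2):
    def elu(v):
        return v if v > 0 else math.exp(v) - 1

    h = [elu(sum(x[i] * W1[i][j] for i in range(len(x))) + b1[j])
         for j in range(len(b1))]
    return [sum(h[j] * W2[j][k] for j in range(len(h))) + b2[k]
            for k in range(len(b2))]


def _route_oracle(Q, params):
    """Scalar-loop re-evaluation: pool -> MLP -> residual -> MLP -> softmax."""
    L, d = len(Q), len(Q[0])
    pooled = [sum(Q[i][j] for i in range(L)) / L for j in range(d)]
    g = _mlp_oracle(pooled, params.W1.tolist(), params.b1.tolist(),
                    params.W2.tolist(), params.b2.tolist())
    Qout = [[Q[i][j] + Q[i][j] * g[j] for j in range(d)] for i in range(L)]
    r = []
    for i in range(L):
        logits = _mlp_oracle(Qout[i], params.W3.tolist(), params.b3.tolist(),
                             params.W4.tolist(), params.b4.tolist())
        mx = max(logits)
        e = [math.exp(x - mx) for x in logits]
        r.append([x / sum(e) for x in e])
    return np.array(Qout), np.array(r)


class TestRouteLogits:
    def test_zero_mlp_weights_give_residual_identity(self):
        rng = np.random.default_rng(0)
        Q = rng.standard_normal((4, 6))
        params = RouterParams.zeros(6, 8)
        Qout, r = route_logits(Q, np.ones(4), params)
        assert np.allclose(Qout, Q)
        assert np.allclose(r, 0.5)  # zero logits -> uniform keep/drop

    def test_rows_of_r_sum_to_one(self):
        rng = np.random.default_rng(1)
        params = RouterParams.random(5, 7, rng)
        Q = rng.standard_normal((6, 5)) * 3
        _, r = route_logits(Q, np.ones(6), params)
        assert np.allclose(r.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            L, d, h = rng.integers(1, 6), rng.integers(1, 5), rng.integers(1, 6)
            params = RouterParams.random(d, h, rng, keep_bias=0.0)
            Q = rng.standard_normal((L, d))
            Qout, r = route_logits(Q, np.ones(L), params)
            Qo_ref, r_ref = _route_oracle(Q.tolist(), params)
            assert np.allclose(Qout, Qo_ref, atol=1e-6)
            assert np.allclose(r, r_ref, atol=1e-6)

    def test_zero_active_tokens_rejected(self):
        params = RouterParams.zeros(3, 4)
        with pytest.raises(ValueError, match="active"):
            route_logits(np.zeros((2, 3)), np.zeros(2), params)


class TestSampleRoute:
    def test_certain_keep_always_kept(self):
        r = np.array([[1.0, 0.0]] * 5)
        for seed in range(5):
            R = sample_route(r, tau=0.5, rng=np.random.default_rng(seed))
            assert np.allclose(R, 1.0)

    def test_low_temperature_matches_shared_noise_argmax_oracle(self):
        rng = np.random.default_rng(3)
        r = rng.dirichlet([1, 1], size=8)
        g = np.random.default_rng(99).gumbel(size=r.shape)
        R = sample_route(r, tau=1e-6, rng=np.random.default_rng(99))
        oracle = (np.argmax(np.log(r + 1e-20) + g, axis=-1) == 0).astype(float)
        assert np.array_equal(R, oracle)

    def test_empirical_keep_frequency_follows_alpha(self):
        alpha = 0.7
        r = np.tile([alpha, 1 - alpha], (10_000, 1))
        R = sample_route(r, tau=0.5, rng=np.random.default_rng(4))
        assert abs(R.mean() - alpha) < 0.02

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            sample_route(np.array([[0.5, 0.5]]), tau=0.0,
                         rng=np.random.default_rng(0))


class TestRoutedAttention:
    def _params(self, d, rng):
        return {k: rng.standard_normal((d, d)) / np.sqrt(d)
                for k in ("Wq", "Wk", "Wv")}

    def test_all_ones_route_equals_unmasked_attention(self):
        rng = np.random.default_rng(5)
        tok = rng.standard_normal((5, 4))
        p = self._params(4, rng)
        full = routed_attention(tok, np.ones(5), p)
        Q, K, V = tok @ p["Wq"], tok @ p["Wk"], tok @ p["Wv"]
        scores = Q @ K.T / 2.0
        e = np.exp(scores - scores.max(-1, keepdims=True))
        ref = (e / e.sum(-1, keepdims=True)) @ V
        assert np.allclose(full, ref, atol=1e-10)

    def test_dropped_token_query_cannot_influence_output(self):
        rng = np.random.default_rng(6)
        tok = rng.standard_normal((6, 4))
        p = self._params(4, rng)
        R = np.array([1, 1, 0, 1, 1, 1.0])
        q1 = tok.copy()
        q2 = tok.copy()
        q2[2] += rng.standard_normal(4) * 10  # perturb dropped token's query
        out1 = routed_attention(tok, R, p, queries=q1)
        out2 = routed_attention(tok, R, p, queries=q2)
        assert np.allclose(out1, out2)
        assert np.allclose(out1[2], 0.0)

    def test_misaligned_mask_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="shape"):
            routed_attention(rng.standard_normal((4, 3)), np.ones(5),
                             self._params(3, rng))


class TestHierarchicalRouting:
    def test_dropped_tokens_stay_dropped_across_blocks(self):
        from deeppath.router import MultimodalRiskModel, PGMTrainConfig

        cfg = PGMTrainConfig(n_blocks=3, tau=1.0, seed=0)
        dims = {"pathology": 8, "lncrna": 6, "immune": 28, "clinical": 5}
        model = MultimodalRiskModel(dims, cfg, seed=0)
        rng = np.random.default_rng(1)
        X = {m: rng.standard_normal((7, d)) for m, d in dims.items()}
        _, _, states = model.forward(X, rng=np.random.default_rng(2), train=False)
        masks = [s.R for s in states]
        for prev, nxt in zip(masks, masks[1:]):
            assert np.all(nxt <= prev)  # kept set is non-increasing
        assert all(m.any(axis=1).all() for m in masks)

    def test_no_rng_keeps_all_routes_at_ones(self):
        from deeppath.router import MultimodalRiskModel, PGMTrainConfig

        dims = {"pathology": 4, "lncrna": 4, "immune": 28, "clinical": 5}
        model = MultimodalRiskModel(dims, PGMTrainConfig(seed=1), seed=1)
        rng = np.random.default_rng(0)
        X = {m: rng.standard_normal((3, d)) for m, d in dims.items()}
        _, _, states = model.forward(X, rng=None, train=False)
        for s in states:
            assert np.all(s.R == 1)


class TestFuseAndRiskHead:
    def test_concatenation_length_and_order(self):
        lat = {"pathology": np.ones(8), "lncrna": np.full(4, 2.0),
               "immune": np.full(28, 3.0), "clinical": np.full(5, 4.0)}
        fused = fuse(lat)
        assert fused.shape == (45,)
        assert np.all(fused[:8] == 1) and np.all(fused[8:12] == 2)
        assert np.all(fused[12:40] == 3) and np.all(fused[40:] == 4)

    def test_missing_modality_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fuse({"pathology": np.ones(3)})

    def test_risk_score_is_max_prob_times_time_risk(self):
        params = {"Ws": np.zeros((4, 2)), "bs": np.log([0.2, 0.8]),
                  "wt": np.zeros(4), "bt": np.array(0.5)}
        out = risk_head(np.zeros(4), params)
        assert np.allclose(out.status_probs, [0.2, 0.8], atol=1e-9)
        assert np.isclose(out.risk_score, 0.8 * 0.5)

    def test_risk_score_symmetric_in_status_order(self):
        p1 = {"Ws": np.zeros((2, 2)), "bs": np.log([0.3, 0.7]),
              "wt": np.zeros(2), "bt": np.array(2.0)}
        p2 = {"Ws": np.zeros((2, 2)), "bs": np.log([0.7, 0.3]),
              "wt": np.zeros(2), "bt": np.array(2.0)}
        assert np.isclose(risk_head(np.zeros(2), p1).risk_score,
                          risk_head(np.zeros(2), p2).risk_score)

    def test_risk_score_monotone_in_time_risk(self):
        outs = []
        for bt in (0.1, 0.5, 2.0):
            params = {"Ws": np.zeros((2, 2)), "bs": np.log([0.4, 0.6]),
                      "wt": np.zeros(2), "bt": np.array(bt)}
            outs.append(risk_head(np.zeros(2), params).risk_score)
        assert outs[0] < outs[1] < outs[2]


def test_modality_feature_set_validates_finiteness():
    with pytest.raises(ValueError, match="finite"):
        ModalityFeatureSet(pathology=np.array([np.nan]), lncrna=np.ones(2),
                           immune=np.ones(28), clinical=np.ones(5))
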