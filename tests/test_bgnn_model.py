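"""Network forward pass: dimension growth, oracle equivalence, dropout."""

import numpy as np
import pytest

from bgyield import bgnn_model as bm
from bgyield.autograd import Tensor
from conftest import random_graph
from _oracles import oracle_forward


def test_edge_dimension_growth_law(rng):
    # pure concatenation: d_e(l+1) = 2 d_v(l+1) + d_e(l); with d_v=4: 1 -> 9
    g = random_graph(rng, n=3, f=4)
    params = bm.init_model(4, hidden=4, n_layers=3, dropout=0.0, seed=0)
    state = bm.initial_state(g)
    assert state.edge_dim == 1
    for expected in (9, 17, 25):
        state = bm.graph_update_layer(state, params.layers[state.layer])
        assert state.edge_dim == expected
        assert state.materialize_edges().shape == (3, 4, expected)


@pytest.mark.parametrize("aggregate", ["mean", "sum"])
def test_forward_matches_loop_oracle_on_random_graphs(rng, aggregate):
    for trial in range(50):
        n = int(rng.integers(1, 6))
        f = int(rng.integers(2, 6))
        g = random_graph(rng, n=n, f=f)
        params = bm.init_model(f, hidden=int(rng.integers(2, 7)),
                               n_layers=int(rng.integers(1, 4)),
                               head_hidden=3, dropout=0.0, seed=trial,
                               aggregate=aggregate)
        state = bm.run_layers(g, params)
        pred = bm.prediction_matrix(state, params.head).data
        assert np.allclose(pred, oracle_forward(g, params), atol=1e-5)


def test_neighbor_order_invariance(rng):
    # summing explicit per-neighbor messages in a shuffled order reproduces
    # the layer's node update to floating tolerance
    g = random_graph(rng, n=4, f=5)
    params = bm.init_model(5, hidden=6, n_layers=1, dropout=0.0, seed=3)
    lp = params.layers[0]
    state = bm.initial_state(g)
    out = bm.graph_update_layer(state, lp)

    WA, WB = lp.full_wa(), lp.full_wb()
    for i in range(4):
        order = rng.permutation(5)
        agg = np.zeros(6)
        for j in order:
            x = np.concatenate([g.feat_init[j], [g.edge_weights[i, j]]])
            agg += np.maximum(WA.T @ x + lp.b_a.data, 0)
        agg /= 5  # mean aggregation
        v = np.maximum(WB.T @ np.concatenate([agg, g.obs_init[i]]) + lp.b_b.data, 0)
        assert np.allclose(v, out.obs_hist[-1].data[i], atol=1e-6)


def test_observation_permutation_equivariance(rng):
    g = random_graph(rng, n=6, f=4)
    params = bm.init_model(4, hidden=5, n_layers=3, dropout=0.0, seed=7)
    _, yield_pred, _ = bm.forward(g, params)

    perm = rng.permutation(6)
    gp = random_graph(rng, n=6, f=4)
    gp.edge_weights = g.edge_weights[perm]
    gp.supervision_mask = g.supervision_mask[perm]
    gp.obs_init = g.obs_init[perm]
    gp.feat_init = g.feat_init
    _, yield_perm, _ = bm.forward(gp, params)
    assert np.allclose(yield_perm, yield_pred[perm], atol=1e-10)


def test_all_zero_weights_give_zero_embeddings(rng):
    g = random_graph(rng, n=3, f=3)
    params = bm.init_model(3, hidden=4, n_layers=1, dropout=0.0, seed=0)
    for t in params.layers[0].tensors():
        t.data[...] = 0.0
    state = bm.graph_update_layer(bm.initial_state(g), params.layers[0])
    assert np.all(state.obs_hist[-1].data == 0)
    assert np.all(state.feat_hist[-1].data == 0)


def test_zero_head_outputs_bias_for_every_pair(rng):
    g = random_graph(rng, n=3, f=3)
    params = bm.init_model(3, hidden=4, n_layers=1, dropout=0.0, seed=0)
    for t in params.head.tensors():
        t.data[...] = 0.0
    params.head.b2.data[...] = 1.75
    state = bm.run_layers(g, params)
    out = bm.predict_pairs(state, [(0, 0), (2, 1)], params.head)
    assert np.allclose(out, 1.75)


def test_eval_mode_is_deterministic(rng):
    g = random_graph(rng, n=5, f=4)
    params = bm.init_model(4, hidden=8, n_layers=3, dropout=0.1, seed=5)
    a = bm.forward(g, params, training=False)[0]
    b = bm.forward(g, params, training=False)[0]
    assert np.array_equal(a, b)


def test_training_dropout_zeroes_expected_fraction(rng):
    # ~p of units zeroed; survivors scaled by 1/(1-p) (inverted dropout)
    g = random_graph(rng, n=50, f=10)
    params = bm.init_model(10, hidden=40, n_layers=1, dropout=0.1, seed=2)
    state = bm.graph_update_layer(bm.initial_state(g), params.layers[0],
                                  training=True, rng=np.random.default_rng(0))
    ref = bm.graph_update_layer(bm.initial_state(g), params.layers[0])
    active = ref.obs_hist[-1].data > 0
    dropped = (state.obs_hist[-1].data == 0) & active
    frac = dropped.sum() / active.sum()
    # binomial(n~2000, 0.1): 5 sigma band
    assert abs(frac - 0.1) < 5 * np.sqrt(0.1 * 0.9 / active.sum())
    kept = (state.obs_hist[-1].data > 0) & active
    assert np.allclose(state.obs_hist[-1].data[kept],
                       ref.obs_hist[-1].data[kept] / 0.9)


def test_pair_index_out_of_range_rejected(rng):
    g = random_graph(rng, n=3, f=3)
    params = bm.init_model(3, hidden=4, n_layers=1, dropout=0.0, seed=0)
    state = bm.run_layers(g, params)
    with pytest.raises(IndexError):
        bm.predict_pairs(state, [(3, 0)], params.head)


def test_dimension_mismatch_rejected(rng):
    g = random_graph(rng, n=3, f=4)
    params = bm.init_model(5, hidden=4, n_layers=1, dropout=0.0, seed=0)
    with pytest.raises(ValueError):
        bm.graph_update_layer(bm.initial_state(g), params.layers[0])


def test_forward_passes_observed_cells_through(rng):
    g = random_graph(rng, n=4, f=4)
    params = bm.init_model(4, hidden=4, n_layers=2, dropout=0.0, seed=1)
    imputed, _, _ = bm.forward(g, params)
    assert np.allclose(imputed[g.supervision_mask],
                       g.edge_weights[g.supervision_mask])


def test_checkpoint_round_trip(tmp_path, rng):
    g = random_graph(rng, n=4, f=5)
    params = bm.init_model(5, hidden=6, n_layers=3, dropout=0.1, seed=9)
    bm.save_checkpoint(params, tmp_path / "ckpt.npz")
    back = bm.load_checkpoint(tmp_path / "ckpt.npz")
    a = bm.forward(g, params)[0]
    b = bm.forward(g, back)[0]
    assert np.array_equal(a, b)
    assert back.config == params.config


def test_full_model_gradients_match_finite_differences(rng):
    # the fused message/head ops carry analytic backwards; verify the whole
    # chain against central differences on a small graph
    from bgyield.autograd import Tensor
    g = random_graph(rng, n=4, f=3)
    params = bm.init_model(3, hidden=5, n_layers=2, head_hidden=4,
                           dropout=0.0, seed=1)
    target = rng.normal(size=(4, 3))

    def loss():
        state = bm.run_layers(g, params)
        d = bm.prediction_matrix(state, params.head) - Tensor(target)
        return (d.abs() + (d * d + 0.09).sqrt()).mean()

    out = loss()
    out.backward()
    for t in params.tensors():
        flat = t.data.ravel()
        for k in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            eps, old = 1e-6, flat[k]
            flat[k] = old + eps
            up = float(loss().data)
            flat[k] = old - eps
            down = float(loss().data)
            flat[k] = old
            num = (up - down) / (2 * eps)
            assert abs(num - t.grad.ravel()[k]) <= 1e-5 + 1e-4 * abs(num)


def test_categorical_decoding_rounds_to_valid_labels(rng):
    raw = rng.normal(loc=2.5, scale=2.0, size=200)
    out = bm.decode_categorical(raw, n_labels=4)
    assert np.all((out >= 1) & (out <= 4))
    assert np.all(out == np.round(out))
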