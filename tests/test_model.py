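"""Encoder, GRU gate, pooling and head behavior, including symmetry laws."""

import numpy as np
import pytest

from poseqa.autodiff import Tensor
from poseqa.features import build_graph
from poseqa.model import (POOLING_STRATEGIES, EncoderConfig, ModelError,
                          classify_head, egnn_layer, encode, ensemble_combine,
                          forward, forward_batch, gru_gate, init_params,
                          pool_weighted, score_head, select_pool_set)

from conftest import apply_rigid_to_graph, random_rigid_motion


@pytest.fixture(scope="module")
def graph():
    from poseqa.synthetic import FixtureConfig, make_native_complex
    return build_graph(make_native_complex(FixtureConfig(), seed=21))


@pytest.fixture(scope="module")
def config():
    return EncoderConfig()


@pytest.fixture(scope="module")
def params(config):
    return init_params(config, seed=5)


# ---------------------------------------------------------------------------
# EGNN layer

def test_zero_init_coordinate_mlp_leaves_coords_unchanged(graph, params, config):
    src, dst, ef = graph.directed_edges()
    H = Tensor(np.random.default_rng(0).standard_normal((graph.n_nodes, config.hidden_dim)))
    _, P1 = egnn_layer(H, Tensor(graph.node_coords), src, dst, Tensor(ef), params, 0)
    assert np.array_equal(P1.value, graph.node_coords)  # Wx2 is zero-initialized


def test_egnn_equivariance(graph, config):
    params = init_params(config, seed=5)
    params["l0.Wx2"].value = np.random.default_rng(1).standard_normal((config.hidden_dim, 1)) * 0.1
    src, dst, ef = graph.directed_edges()
    H = Tensor(np.random.default_rng(0).standard_normal((graph.n_nodes, config.hidden_dim)))
    H1, P1 = egnn_layer(H, Tensor(graph.node_coords), src, dst, Tensor(ef), params, 0)
    rng = np.random.default_rng(3)
    R, t = random_rigid_motion(rng)
    H2, P2 = egnn_layer(H, Tensor(graph.node_coords @ R.T + t), src, dst, Tensor(ef), params, 0)
    assert np.abs(H1.value - H2.value).max() < 1e-5      # invariant features
    assert np.abs(P2.value - (P1.value @ R.T + t)).max() < 1e-4  # equivariant coords


def test_egnn_two_node_hand_computed():
    cfg = EncoderConfig(n_layers=1, hidden_dim=2, input_dim=2, edge_dim=1)
    p = init_params(cfg, seed=0)
    # overwrite with tiny hand-set weights
    # edge MLP input layout: [h_i (2), h_j (2), 0.01*|p_i-p_j|^2 (1), e_ij (1)]
    We1 = np.array([[0.1, 0.0], [0.0, 0.1], [0.05, 0.0], [0.0, 0.05],
                    [0.025, 0.025], [0.02, -0.02]])
    We2 = np.array([[0.3, 0.0], [0.0, 0.3]])
    Wh1 = np.array([[0.2, 0.0], [0.0, 0.2], [0.1, 0.0], [0.0, 0.1]])
    for key, arr in {"l0.We1": We1, "l0.We2": We2, "l0.Wh1": Wh1,
                     "l0.Wh2": np.eye(2)}.items():
        p[key].value = np.array(arr, dtype=float)
    for key in ("l0.be1", "l0.be2", "l0.bh1", "l0.bh2"):
        p[key].value[:] = 0.0
    H = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
    P = Tensor(np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))
    src, dst = np.array([0, 1]), np.array([1, 0])
    ef = Tensor(np.array([[0.5], [0.5]]))
    H1, P1 = egnn_layer(H, P, src, dst, ef, p, 0)

    def silu(x):
        return x / (1 + np.exp(-x))

    # independent scalar-arithmetic oracle for node 0's incoming message
    z0 = np.concatenate([[1.0, 0.0], [0.0, 1.0], [0.01 * 4.0], [0.5]]) @ We1
    m0 = silu(silu(z0) @ We2)                      # phi_e: Linear-SiLU-Linear-SiLU
    h0 = silu(np.concatenate([[1.0, 0.0], m0]) @ Wh1) @ np.eye(2)  # phi_h: Linear-SiLU-Linear
    assert np.allclose(H1.value[0], h0, atol=1e-12)


def test_isolated_node_keeps_state(config, params):
    from poseqa.features import PoseGraph
    H = Tensor(np.ones((2, config.hidden_dim)))
    P = Tensor(np.array([[0.0, 0, 0], [100.0, 0, 0]]))
    src, dst = np.array([], dtype=int), np.array([], dtype=int)
    H1, P1 = egnn_layer(H, P, src, dst, Tensor(np.zeros((0, 30))), params, 0)
    assert np.array_equal(P1.value, P.value)


# ---------------------------------------------------------------------------
# GRU gate

def test_gru_all_zero_params_halves_previous_state(config):
    p = init_params(config, seed=0)
    for k in list(p):
        if ".Wi" in k or ".Wh" in k and k.endswith("g") or ".bi" in k or ".bh" in k:
            p[k].value[:] = 0.0
    H_prev = Tensor(np.random.default_rng(0).standard_normal((4, config.hidden_dim)))
    H_tilde = Tensor(np.random.default_rng(1).standard_normal((4, config.hidden_dim)))
    out = gru_gate(H_tilde, H_prev, p, 0)
    assert np.allclose(out.value, 0.5 * H_prev.value)


def test_gru_saturated_update_gate_is_identity_path(config):
    p = init_params(config, seed=0)
    p["l0.biz"].value[:] = 50.0  # drive z -> 1
    H_prev = Tensor(np.random.default_rng(0).standard_normal((4, config.hidden_dim)))
    H_tilde = Tensor(np.random.default_rng(1).standard_normal((4, config.hidden_dim)))
    out = gru_gate(H_tilde, H_prev, p, 0)
    assert np.abs(out.value - H_prev.value).max() < 1e-8


def test_gru_scalar_oracle():
    cfg = EncoderConfig(n_layers=1, hidden_dim=1, input_dim=1, edge_dim=1)
    p = init_params(cfg, seed=3)
    ht, hp = 0.7, -0.4
    x = np.array([ht, hp])
    val = {k: p[k].value for k in p}
    sig = lambda v: 1 / (1 + np.exp(-v))
    r = sig(x @ val["l0.Wir"] + val["l0.bir"] + hp * val["l0.Whrg"][0] + val["l0.bhrg"])
    z = sig(x @ val["l0.Wiz"] + val["l0.biz"] + hp * val["l0.Whzg"][0] + val["l0.bhzg"])
    n = np.tanh(x @ val["l0.Win"] + val["l0.bin"] + r * (hp * val["l0.Whng"][0] + val["l0.bhng"]))
    expect = (1 - z) * n + z * hp
    out = gru_gate(Tensor([[ht]]), Tensor([[hp]]), p, 0)
    assert np.allclose(out.value, expect)


# ---------------------------------------------------------------------------
# encode and symmetry

def test_encode_zero_layers_returns_projection(graph):
    cfg = EncoderConfig(n_layers=0)
    p = init_params(cfg, seed=0)
    H, P = encode(graph, p, cfg)
    expect = graph.node_features @ p["Win"].value + p["bin"].value
    expect = expect / (1 + np.exp(-expect))
    assert np.allclose(H.value, expect)
    assert np.array_equal(P.value, graph.node_coords)


def test_encode_dim_mismatch_raises(graph):
    cfg = EncoderConfig(input_dim=64)
    with pytest.raises(ModelError, match="input_dim"):
        encode(graph, init_params(cfg, 0), cfg)


def test_end_to_end_rigid_invariance(graph, params, config):
    base = forward(graph, params, config)
    rng = np.random.default_rng(17)
    for _ in range(10):
        R, t = random_rigid_motion(rng)
        moved = apply_rigid_to_graph(graph, R, t)
        out = forward(moved, params, config)
        assert abs(out.p_pos.item() - base.p_pos.item()) < 1e-5


def test_coordinate_equivariance_through_full_stack(graph, config):
    params = init_params(config, seed=5)
    for t in range(config.n_layers):  # non-trivial coordinate updates
        params[f"l{t}.Wx2"].value = \
            np.random.default_rng(t).standard_normal((config.hidden_dim, 1)) * 0.05
    _, P1 = encode(graph, params, config)
    rng = np.random.default_rng(23)
    R, t = random_rigid_motion(rng)
    _, P2 = encode(apply_rigid_to_graph(graph, R, t), params, config)
    assert np.abs(P2.value - (P1.value @ R.T + t)).max() < 1e-4


def test_node_permutation_invariance(graph, params, config):
    base = forward(graph, params, config).p_pos.item()
    rng = np.random.default_rng(4)
    perm = rng.permutation(graph.n_nodes)
    inv = np.argsort(perm)
    import copy
    g2 = copy.deepcopy(graph)
    g2.node_features = graph.node_features[perm]
    g2.node_coords = graph.node_coords[perm]
    g2.node_side = graph.node_side[perm]
    g2.node_type_label = graph.node_type_label[perm]
    g2.is_cdr = graph.is_cdr[perm]
    g2.is_interface = graph.is_interface[perm]
    g2.is_cdr_epitope = graph.is_cdr_epitope[perm]
    g2.residue_keys = [graph.residue_keys[i] for i in perm]
    g2.edge_index = np.array([[inv[i], inv[j]] for i, j in graph.edge_index])
    assert abs(forward(g2, params, config).p_pos.item() - base) < 1e-6


def test_batched_forward_equals_single(graph, params, config):
    import copy
    g2 = copy.deepcopy(graph)
    g2.node_coords = graph.node_coords + 5.0
    singles = [forward(g, params, config).p_pos.item() for g in (graph, g2)]
    batched = forward_batch([graph, g2], params, config).p_pos.value
    assert np.abs(np.array(singles) - batched).max() < 1e-10


# ---------------------------------------------------------------------------
# pooling

def test_pool_set_strategies_and_complement_laws(graph):
    V = set(range(graph.n_nodes))
    sets = {s: set(select_pool_set(graph, s).tolist()) for s in POOLING_STRATEGIES}
    assert sets["all_nodes"] == V
    assert sets["without_cdr"] == V - sets["cdr_only"]
    assert sets["without_interface"] == V - sets["interface_only"]
    assert sets["without_cdr_epitope"] == V - sets["cdr_epitope_only"]
    assert sets["interface_only"] == {i for i in V if graph.is_interface[i]}


def test_pool_set_empty_selection_raises(graph):
    import copy
    g = copy.deepcopy(graph)
    g.is_cdr[:] = False
    with pytest.raises(ModelError, match="all_nodes"):
        select_pool_set(g, "cdr_only")


def test_pool_weighted_zero_gate_single_node():
    p = {"wp": Tensor(np.zeros((3, 1))), "bp": Tensor(np.zeros(1))}
    H = Tensor(np.array([[2.0, 4.0, -6.0]]))
    g = pool_weighted(H, [0], p)
    assert np.allclose(g.value, [1.0, 2.0, -3.0])  # sigmoid(0) = 0.5


def test_pool_weighted_permutation_invariant_and_oracle():
    rng = np.random.default_rng(8)
    H = rng.standard_normal((3, 4))
    wp, bp = rng.standard_normal((4, 1)), rng.standard_normal(1)
    p = {"wp": Tensor(wp), "bp": Tensor(bp)}
    out = pool_weighted(Tensor(H), [0, 1, 2], p).value
    w = 1 / (1 + np.exp(-(H @ wp + bp)))
    assert np.allclose(out, (w * H).sum(axis=0))
    out_perm = pool_weighted(Tensor(H[[2, 0, 1]]), [0, 1, 2], p).value
    assert np.allclose(out, out_perm)


# ---------------------------------------------------------------------------
# heads and ensembling

def test_classify_head_zero_params_uniform():
    p = {"Wc1": Tensor(np.zeros((4, 4))), "bc1": Tensor(np.zeros(4)),
         "Wc2": Tensor(np.zeros((4, 2))), "bc2": Tensor(np.zeros(2))}
    logp = classify_head(Tensor(np.ones(4)), p)
    assert np.allclose(np.exp(logp.value), [0.5, 0.5])


def test_classify_head_probabilities_normalize():
    rng = np.random.default_rng(0)
    p = {"Wc1": Tensor(rng.standard_normal((4, 4))), "bc1": Tensor(rng.standard_normal(4)),
         "Wc2": Tensor(rng.standard_normal((4, 2))), "bc2": Tensor(rng.standard_normal(2))}
    logp = classify_head(Tensor(rng.standard_normal(4)), p)
    assert abs(np.exp(logp.value).sum() - 1.0) < 1e-7


def test_classify_head_hand_computed_softmax():
    p = {"Wc1": Tensor(np.eye(2)), "bc1": Tensor(np.zeros(2)),
         "Wc2": Tensor(np.array([[1.0, 0.0], [0.0, 1.0]])), "bc2": Tensor(np.zeros(2))}
    g = np.array([1.0, -1.0])
    silu = lambda x: x / (1 + np.exp(-x))
    logits = silu(g)
    expect = np.exp(logits) / np.exp(logits).sum()
    logp = classify_head(Tensor(g), p)
    assert np.allclose(np.exp(logp.value), expect)


def test_score_head_values_and_monotonicity():
    p = {"Wr": Tensor(np.array([[1.0]])), "br": Tensor(np.array([0.0]))}
    out0 = score_head(Tensor(np.array([0.0])), p)
    assert np.allclose(out0.value, 0.5)
    out2 = score_head(Tensor(np.array([2.0])), p)
    assert np.allclose(out2.value, 0.5 * (np.tanh(1.0) + 1))  # ~0.88080
    zs = np.linspace(-10, 10, 41)
    ys = [score_head(Tensor(np.array([z])), p).value[0] for z in zs]
    assert all(a < b for a, b in zip(ys, ys[1:]))
    assert all(0 < y < 1 for y in ys)


def test_ensemble_combine():
    assert ensemble_combine([1.0, 0.0], [0.7, 0.3]) == pytest.approx(0.7)
    assert ensemble_combine([0.42, 0.42, 0.42], [0.2, 0.5, 0.3]) == pytest.approx(0.42)
    assert ensemble_combine([0.1, 0.2, 0.3, 0.4], [0.25] * 4) == pytest.approx(0.25)
    with pytest.raises(ModelError):
        ensemble_combine([0.5, 0.5], [0.8, 0.3])
    with pytest.raises(ModelError):
        ensemble_combine([0.5], [0.5, 0.5])
    with pytest.raises(ModelError):
        ensemble_combine([0.5, 0.5], [1.2, -0.2])
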