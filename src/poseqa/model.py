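"""The pose-scoring network.

An input projection lifts per-residue sequence embeddings into a hidden
space; ``n_layers`` E(n)-equivariant message-passing layers, each followed
by a GRU gate acting as a learnable residual update, refine node states
while updating coordinates equivariantly; a sigmoid-gated weighted-sum
readout over a selectable node subset produces a graph embedding that feeds
either a two-class softmax head (native-like vs non-native pose) or a
scaled-tanh head estimating DockQ in (0,1).  Because scalar features enter
message passing only through squared inter-node distances, all scalar
outputs are invariant under rigid motions of the input coordinates, and the
coordinate track is equivariant.

Parameters are plain autodiff Tensors in a flat dict; checkpoints are an
``.npz`` tensor container next to a JSON config snapshot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .features import PoseGraph

POOLING_STRATEGIES = (
    "all_nodes", "interface_only", "cdr_epitope_only", "cdr_only",
    "without_interface", "without_cdr_epitope", "without_cdr",
)


class ModelError(ValueError):
    pass


@dataclass
class EncoderConfig:
    n_layers: int = 4
    hidden_dim: int = 64
    input_dim: int = 320
    edge_dim: int = 30
    dropout: float = 0.1
    pooling_strategy: str = "all_nodes"

    def __post_init__(self):
        if self.n_layers < 0:
            raise ModelError("n_layers must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ModelError("dropout must lie in [0,1)")
        if self.pooling_strategy not in POOLING_STRATEGIES:
            raise ModelError(f"unknown pooling strategy {self.pooling_strategy!r}")


@dataclass
class ModelOutput:
    graph_probs: tuple            # (p_neg, p_pos) floats
    p_pos: Tensor                 # scalar tensor, kept differentiable
    log_probs: Tensor             # (2,) log softmax
    node_type_logits: Tensor      # N x 3
    pooled: Tensor                # h-vector
    reg_score: Tensor | None = None   # scalar in (0,1) when regressor head present


# ---------------------------------------------------------------------------
# parameters

def _linear(rng, n_in, n_out, zero=False):
    bound = 1.0 / np.sqrt(n_in)
    W = np.zeros((n_in, n_out)) if zero else rng.uniform(-bound, bound, (n_in, n_out))
    b = np.zeros(n_out)
    return Tensor(W, requires_grad=True), Tensor(b, requires_grad=True)


def init_params(config: EncoderConfig, seed: int = 0, regressor: bool = False) -> dict:
    """Fan-in uniform init; the coordinate-MLP output layer starts at zero."""
    rng = np.random.default_rng(seed)
    h, dx, de = config.hidden_dim, config.input_dim, config.edge_dim
    p: dict = {}
    p["Win"], p["bin"] = _linear(rng, dx, h)
    for t in range(config.n_layers):
        p[f"l{t}.We1"], p[f"l{t}.be1"] = _linear(rng, 2 * h + 1 + de, h)
        p[f"l{t}.We2"], p[f"l{t}.be2"] = _linear(rng, h, h)
        p[f"l{t}.Wx1"], p[f"l{t}.bx1"] = _linear(rng, h, h)
        p[f"l{t}.Wx2"], p[f"l{t}.bx2"] = _linear(rng, h, 1, zero=True)
        p[f"l{t}.Wh1"], p[f"l{t}.bh1"] = _linear(rng, 2 * h, h)
        p[f"l{t}.Wh2"], p[f"l{t}.bh2"] = _linear(rng, h, h)
        # GRU gate: input is concat(h_tilde, h_prev) of width 2h, hidden width h
        for gate in ("r", "z", "n"):
            p[f"l{t}.Wi{gate}"], p[f"l{t}.bi{gate}"] = _linear(rng, 2 * h, h)
            p[f"l{t}.Wh{gate}g"], p[f"l{t}.bh{gate}g"] = _linear(rng, h, h)
    p["wp"], p["bp"] = _linear(rng, h, 1)
    p["Wnt"], p["bnt"] = _linear(rng, h, 3)
    if regressor:
        p["Wr"], p["br"] = _linear(rng, h, 1)
    else:
        p["Wc1"], p["bc1"] = _linear(rng, h, h)
        p["Wc2"], p["bc2"] = _linear(rng, h, 2)
    return p


def param_list(params: dict) -> list:
    return [params[k] for k in sorted(params)]


def clone_params(params: dict) -> dict:
    return {k: Tensor(v.value.copy(), requires_grad=True) for k, v in params.items()}


# ---------------------------------------------------------------------------
# layers

def _mlp2(x: Tensor, W1, b1, W2, b2, final_act: bool) -> Tensor:
    y = (x @ W1 + b1).silu() @ W2 + b2
    return y.silu() if final_act else y


def egnn_layer(H: Tensor, P: Tensor, src, dst, efeat, params: dict, t: int):
    """One equivariant message-passing step.

    Per directed edge (i <- j): m_ij = phi_e(h_i, h_j, |p_i - p_j|^2, e_ij);
    p_i' = p_i + (1/deg i) sum_j (p_i - p_j) phi_x(m_ij);
    h~_i = phi_h(h_i, sum_j m_ij).  Isolated nodes receive zero messages and
    keep their coordinates.
    """
    if not np.all(np.isfinite(H.value)) or not np.all(np.isfinite(P.value)):
        raise ModelError("non-finite encoder state")
    n = H.shape[0]
    pre = f"l{t}."
    if len(src) == 0:
        agg = Tensor(np.zeros((n, H.shape[1])))
        Ht = _mlp2(concat([H, agg], axis=1),
                   params[pre + "Wh1"], params[pre + "bh1"],
                   params[pre + "Wh2"], params[pre + "bh2"], final_act=False)
        return Ht, P
    hi, hj = H.gather(src), H.gather(dst)
    pi, pj = P.gather(src), P.gather(dst)
    diff = pi - pj
    # squared distance scaled to O(1) (edges are <= ~10 A apart) so the
    # radial channel does not swamp the feature channels at initialization
    sq = (diff * diff).sum(axis=1, keepdims=True) * 0.01
    m = _mlp2(concat([hi, hj, sq, efeat], axis=1),
              params[pre + "We1"], params[pre + "be1"],
              params[pre + "We2"], params[pre + "be2"], final_act=True)
    x = _mlp2(m, params[pre + "Wx1"], params[pre + "bx1"],
              params[pre + "Wx2"], params[pre + "bx2"], final_act=False)
    deg = np.zeros(n)
    np.add.at(deg, src, 1.0)
    deg = np.maximum(deg, 1.0)[:, None]
    P_new = P + (diff * x).segment_sum(src, n) / deg
    agg = m.segment_sum(src, n)
    Ht = _mlp2(concat([H, agg], axis=1),
               params[pre + "Wh1"], params[pre + "bh1"],
               params[pre + "Wh2"], params[pre + "bh2"], final_act=False)
    return Ht, P_new


def gru_gate(H_tilde: Tensor, H_prev: Tensor, params: dict, t: int) -> Tensor:
    """Gated residual update: input = concat(h~, h_prev), hidden = h_prev.

    r, z = sigmoid(linear(input) + linear(hidden)); the candidate
    n = tanh(linear(input) + r * linear(hidden)); output
    (1 - z) * n + z * h_prev.  The concatenated input gives the candidate
    gate a direct linear path back to the previous state, strengthening the
    self-loop against oversmoothing.
    """
    pre = f"l{t}."
    x = concat([H_tilde, H_prev], axis=1)
    r = (x @ params[pre + "Wir"] + params[pre + "bir"]
         + H_prev @ params[pre + "Whrg"] + params[pre + "bhrg"]).sigmoid()
    z = (x @ params[pre + "Wiz"] + params[pre + "biz"]
         + H_prev @ params[pre + "Whzg"] + params[pre + "bhzg"]).sigmoid()
    n = (x @ params[pre + "Win"] + params[pre + "bin"]
         + r * (H_prev @ params[pre + "Whng"] + params[pre + "bhng"])).tanh()
    one = Tensor(np.ones_like(z.value))
    return (one - z) * n + z * H_prev


def encode(g: PoseGraph, params: dict, config: EncoderConfig):
    """Run input projection and the full message-passing stack."""
    if g.node_features.shape[1] != config.input_dim:
        raise ModelError(
            f"embedder dim {g.node_features.shape[1]} != config input_dim {config.input_dim}")
    src, dst, efeat_np = g.directed_edges()
    efeat = Tensor(efeat_np)
    H = (Tensor(g.node_features) @ params["Win"] + params["bin"]).silu()
    P = Tensor(g.node_coords)
    for t in range(config.n_layers):
        Ht, P = egnn_layer(H, P, src, dst, efeat, params, t)
        H = gru_gate(Ht, H, params, t)
    return H, P


# ---------------------------------------------------------------------------
# pooling and heads

def select_pool_set(g: PoseGraph, strategy: str) -> np.ndarray:
    masks = {
        "all_nodes": np.ones(g.n_nodes, dtype=bool),
        "interface_only": g.is_interface,
        "cdr_epitope_only": g.is_cdr_epitope,
        "cdr_only": g.is_cdr,
        "without_interface": ~g.is_interface,
        "without_cdr_epitope": ~g.is_cdr_epitope,
        "without_cdr": ~g.is_cdr,
    }
    if strategy not in masks:
        raise ModelError(f"unknown pooling strategy {strategy!r}")
    S = np.flatnonzero(masks[strategy])
    if len(S) == 0:
        raise ModelError(
            f"pooling strategy {strategy!r} selected no nodes; "
            "fall back to 'all_nodes' explicitly if intended")
    return S


def pool_weighted(H: Tensor, S, params: dict) -> Tensor:
    """g = sum_{i in S} sigmoid(wp.h_i + bp) h_i  (weighted sum, not mean)."""
    S = np.asarray(S, dtype=int)
    if S.size == 0:
        raise ModelError("empty pooling set")
    Hs = H.gather(S)
    w = (Hs @ params["wp"] + params["bp"]).sigmoid()
    return (w * Hs).sum(axis=0)


def classify_head(gvec: Tensor, params: dict, dropout: float = 0.0, rng=None) -> Tensor:
    """Two-layer SiLU MLP with softmax; returns the (2,) log-probabilities."""
    hidden = (gvec @ params["Wc1"] + params["bc1"]).silu()
    if dropout > 0.0 and rng is not None:
        mask = (rng.random(hidden.shape) >= dropout) / (1.0 - dropout)
        hidden = hidden * Tensor(mask)
    logits = hidden @ params["Wc2"] + params["bc2"]
    return logits.log_softmax(axis=-1)


def score_head(gvec: Tensor, params: dict) -> Tensor:
    """Scaled-tanh DockQ estimate: y = (tanh(0.5 z) + 1) / 2 in (0,1)."""
    z = gvec @ params["Wr"] + params["br"]
    return ((z * 0.5).tanh() + 1.0) * 0.5


def forward(g: PoseGraph, params: dict, config: EncoderConfig,
            training: bool = False, rng=None) -> ModelOutput:
    """Full pass: encode, pool, and apply whichever heads the params carry."""
    H, _ = encode(g, params, config)
    S = select_pool_set(g, config.pooling_strategy)
    gvec = pool_weighted(H, S, params)
    node_logits = H @ params["Wnt"] + params["bnt"]
    if "Wc1" in params:
        logp = classify_head(gvec, params,
                             dropout=config.dropout if training else 0.0, rng=rng)
        probs = np.exp(logp.value)
        p_pos = logp.gather(np.array([1])).exp().reshape(())
        out = ModelOutput(graph_probs=(float(probs[0]), float(probs[1])),
                          p_pos=p_pos, log_probs=logp,
                          node_type_logits=node_logits, pooled=gvec)
    else:
        yr = score_head(gvec, params).reshape(())
        out = ModelOutput(graph_probs=(float("nan"), float("nan")),
                          p_pos=yr, log_probs=Tensor(np.zeros(2)),
                          node_type_logits=node_logits, pooled=gvec, reg_score=yr)
    return out


@dataclass
class BatchedOutput:
    """Forward results for a disjoint-union minibatch of graphs."""

    log_probs: Tensor | None      # B x 2 (classifier)
    p_pos: Tensor                 # (B,) p_pos or DockQ estimate
    node_type_logits: Tensor      # sum(N) x 3
    node_type_labels: np.ndarray  # sum(N)
    reg_score: Tensor | None = None


def forward_batch(graphs, params: dict, config: EncoderConfig,
                  training: bool = False, rng=None) -> BatchedOutput:
    """Forward pass over several graphs merged into one disjoint union.

    Mathematically identical to per-graph `forward` (message passing never
    crosses components and pooling is per-graph), but amortizes the op
    overhead across the minibatch.
    """
    offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
    X = np.concatenate([g.node_features for g in graphs])
    P0 = np.concatenate([g.node_coords for g in graphs])
    src_l, dst_l, ef_l = [], [], []
    for g, off in zip(graphs, offsets):
        s, d, f = g.directed_edges()
        src_l.append(s + off)
        dst_l.append(d + off)
        ef_l.append(f)
    src = np.concatenate(src_l)
    dst = np.concatenate(dst_l)
    efeat = Tensor(np.concatenate(ef_l))
    gid = np.concatenate([np.full(g.n_nodes, i) for i, g in enumerate(graphs)])

    if X.shape[1] != config.input_dim:
        raise ModelError(
            f"embedder dim {X.shape[1]} != config input_dim {config.input_dim}")
    H = (Tensor(X) @ params["Win"] + params["bin"]).silu()
    P = Tensor(P0)
    for t in range(config.n_layers):
        Ht, P = egnn_layer(H, P, src, dst, efeat, params, t)
        H = gru_gate(Ht, H, params, t)

    sel = np.concatenate([select_pool_set(g, config.pooling_strategy) + off
                          for g, off in zip(graphs, offsets)])
    w = (H.gather(sel) @ params["wp"] + params["bp"]).sigmoid()
    G = (w * H.gather(sel)).segment_sum(gid[sel], len(graphs))  # B x h

    node_logits = H @ params["Wnt"] + params["bnt"]
    labels = np.concatenate([g.node_type_label for g in graphs])
    if "Wc1" in params:
        hidden = (G @ params["Wc1"] + params["bc1"]).silu()
        if training and config.dropout > 0.0 and rng is not None:
            mask = (rng.random(hidden.shape) >= config.dropout) / (1.0 - config.dropout)
            hidden = hidden * Tensor(mask)
        logp = (hidden @ params["Wc2"] + params["bc2"]).log_softmax(axis=-1)
        p_pos = (logp @ Tensor(np.array([0.0, 1.0]))).exp()
        return BatchedOutput(log_probs=logp, p_pos=p_pos,
                             node_type_logits=node_logits, node_type_labels=labels)
    z = G @ params["Wr"] + params["br"]
    yr = (((z * 0.5).tanh() + 1.0) * 0.5).reshape(len(graphs))
    return BatchedOutput(log_probs=None, p_pos=yr, node_type_logits=node_logits,
                         node_type_labels=labels, reg_score=yr)


def ensemble_combine(preds, weights) -> float:
    """Convex combination of model predictions (deep-ensemble aggregation)."""
    preds = np.asarray(preds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if preds.shape != weights.shape or preds.ndim != 1 or len(preds) < 1:
        raise ModelError("preds and weights must be equal-length 1-D sequences")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-8:
        raise ModelError("weights must be non-negative and sum to 1")
    return float(weights @ preds)


# ---------------------------------------------------------------------------
# checkpoints

@dataclass
class Checkpoint:
    params: dict
    encoder_config: EncoderConfig
    training_config: dict = field(default_factory=dict)
    epoch: int = 0
    metrics: dict = field(default_factory=dict)
    rng_state: dict | None = None

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **{k: v.value for k, v in self.params.items()})
        meta = {
            "encoder_config": asdict(self.encoder_config),
            "training_config": self.training_config,
            "epoch": self.epoch,
            "metrics": self.metrics,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "Checkpoint":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        params = {k: Tensor(arrays[k], requires_grad=True) for k in arrays.files}
        return cls(params=params,
                   encoder_config=EncoderConfig(**meta["encoder_config"]),
                   training_config=meta.get("training_config", {}),
                   epoch=meta.get("epoch", 0), metrics=meta.get("metrics", {}))
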