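"""Training objectives for pose classification and DockQ regression.

The classifier minimizes L = L_GC + alpha * L_NC + beta * L_MDN: a
graph-level two-class cross-entropy, a node-level three-class cross-entropy
over node types (antigen / heavy / light) as an auxiliary task, and the
negative Pearson correlation between the predicted positive-class
probability and the ground-truth DockQ over the minibatch.  Default
multipliers are alpha = 1e-3, beta = 2e-3.

The regressor minimizes L = -Corr(y, y_hat) + L_rank, where L_rank is a
top-one listwise (ListNet) ranking loss evaluated per group of poses that
share a target complex.  The correlation term is skipped (contributes 0)
whenever it is undefined, e.g. on a batch with constant labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, concat


class LossError(ValueError):
    pass


UNDEFINED = None  # sentinel for statistics with no defined value


@dataclass
class LossWeights:
    alpha: float = 1e-3
    beta: float = 2e-3

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise LossError("loss multipliers must be non-negative")


def _as_vector(x) -> Tensor:
    if isinstance(x, Tensor):
        return x.reshape(-1) if x.ndim != 1 else x
    if isinstance(x, (list, tuple)) and any(isinstance(v, Tensor) for v in x):
        return concat([astensor(v).reshape(1) for v in x], axis=0)
    return Tensor(np.asarray(x, dtype=float).reshape(-1))


def pearson_corr(a, b):
    """Sample Pearson correlation as a differentiable scalar Tensor.

    Returns the UNDEFINED sentinel when either argument is (numerically)
    constant; callers treat the associated loss term as absent.
    """
    a, b = _as_vector(a), _as_vector(b)
    n = a.shape[0]
    if n != b.shape[0]:
        raise LossError("length mismatch")
    if n < 2:
        raise LossError("correlation needs at least 2 samples")
    da = a - a.mean()
    db = b - b.mean()
    va = (da * da).sum()
    vb = (db * db).sum()
    if va.item() < 1e-24 or vb.item() < 1e-24:
        return UNDEFINED
    return (da * db).sum() / (va.sqrt() * vb.sqrt())


def listwise_rank_loss(y_true, y_pred, groups=None):
    """Top-one ListNet loss, averaged over groups of >= 2 items.

    Per group: L = -sum softmax(y_true) * log softmax(y_pred).  Groups of a
    single item carry no ranking information and are skipped with a warning;
    if every group has size 1 the loss is undefined and raises.
    """
    yt, yp = _as_vector(y_true), _as_vector(y_pred)
    n = yt.shape[0]
    if yp.shape[0] != n:
        raise LossError("length mismatch")
    groups = np.zeros(n, dtype=object) if groups is None else np.asarray(groups)
    terms = []
    for gid in sorted(set(groups.tolist()), key=str):
        idx = np.flatnonzero(groups == gid)
        if len(idx) < 2:
            warnings.warn(f"ranking group {gid!r} has a single item; skipped", stacklevel=2)
            continue
        target = yt.gather(idx).softmax()
        logp = yp.gather(idx).log_softmax()
        terms.append(-(target * logp).sum())
    if not terms:
        raise LossError("no ranking group with >= 2 items")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / len(terms)


def classifier_loss(log_probs, node_type_logits, node_type_labels,
                    y, dockq, weights: LossWeights | None = None):
    """Composite classification loss; returns (total, components dict).

    ``log_probs``: list of (2,) log-softmax Tensors, one per graph.
    ``node_type_logits`` / ``node_type_labels``: per-graph N x 3 Tensors and
    int vectors.  ``dockq``: the ground-truth DockQ label of each graph
    (natives 1, non-cognate decoys 0), required for the correlation term.
    """
    weights = weights or LossWeights()
    y = np.asarray(y, dtype=int)
    if dockq is None:
        raise LossError("dockq labels are required for the correlation term")
    dockq = np.asarray(dockq, dtype=float)
    if not (len(log_probs) == len(y) == len(dockq)):
        raise LossError("batch length mismatch")

    # graph-level cross-entropy
    gc_terms = [-(lp.gather(np.array([yi])).sum()) for lp, yi in zip(log_probs, y)]
    l_gc = concat([t.reshape(1) for t in gc_terms], axis=0).mean()

    # node-level cross-entropy over all nodes of the batch
    nc_terms, n_nodes = [], 0
    for logits, labels in zip(node_type_logits, node_type_labels):
        labels = np.asarray(labels, dtype=int)
        onehot = np.zeros((len(labels), 3))
        onehot[np.arange(len(labels)), labels] = 1.0
        nc_terms.append(-(logits.log_softmax(axis=-1) * Tensor(onehot)).sum())
        n_nodes += len(labels)
    l_nc = concat([t.reshape(1) for t in nc_terms], axis=0).sum() / n_nodes

    # negative Pearson correlation of p_pos against DockQ
    p_pos = concat([lp.gather(np.array([1])).exp() for lp in log_probs], axis=0)
    corr = pearson_corr(p_pos, Tensor(dockq))
    l_mdn = -corr if corr is not UNDEFINED else Tensor(0.0)

    total = l_gc + weights.alpha * l_nc + weights.beta * l_mdn
    comps = {"graph_ce": l_gc.item(), "node_ce": l_nc.item(),
             "neg_corr": (l_mdn.item() if corr is not UNDEFINED else UNDEFINED)}
    return total, comps


def classifier_loss_batched(out, y, dockq, weights: LossWeights | None = None):
    """Composite classification loss on a BatchedOutput (matrix form).

    Computes exactly the same quantity as `classifier_loss` on the
    corresponding per-graph outputs; only the arithmetic layout differs.
    """
    weights = weights or LossWeights()
    y = np.asarray(y, dtype=int)
    if dockq is None:
        raise LossError("dockq labels are required for the correlation term")
    dockq = np.asarray(dockq, dtype=float)
    B = out.log_probs.shape[0]
    if not (B == len(y) == len(dockq)):
        raise LossError("batch length mismatch")

    onehot2 = np.zeros((B, 2))
    onehot2[np.arange(B), y] = 1.0
    l_gc = -(out.log_probs * Tensor(onehot2)).sum() / B

    labels = np.asarray(out.node_type_labels, dtype=int)
    onehot3 = np.zeros((len(labels), 3))
    onehot3[np.arange(len(labels)), labels] = 1.0
    l_nc = -(out.node_type_logits.log_softmax(axis=-1) * Tensor(onehot3)).sum() / len(labels)

    corr = pearson_corr(out.p_pos, Tensor(dockq))
    l_mdn = -corr if corr is not UNDEFINED else Tensor(0.0)

    total = l_gc + weights.alpha * l_nc + weights.beta * l_mdn
    comps = {"graph_ce": l_gc.item(), "node_ce": l_nc.item(),
             "neg_corr": (l_mdn.item() if corr is not UNDEFINED else UNDEFINED)}
    return total, comps


def regressor_loss(y_pred, y_true, groups=None):
    """L = -Corr(y, y_hat) + listwise rank loss; returns (total, components)."""
    yp, yt = _as_vector(y_pred), _as_vector(y_true)
    if yp.shape[0] < 2:
        raise LossError("regression batch needs at least 2 samples")
    corr = pearson_corr(yt, yp)
    l_coeff = -corr if corr is not UNDEFINED else Tensor(0.0)
    l_rank = listwise_rank_loss(yt, yp, groups)
    total = l_coeff + l_rank
    comps = {"neg_corr": (l_coeff.item() if corr is not UNDEFINED else UNDEFINED),
             "rank": l_rank.item()}
    return total, comps
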