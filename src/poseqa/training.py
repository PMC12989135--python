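"""Optimization loop for the pose classifier and the DockQ regressor.

Training follows the protocol the network was designed for: Adam from an
initial learning rate of 1e-4 annealed by a cosine schedule down to 1e-5
over the epoch budget (50 by default), minibatches drawn with replacement
by a weighted random sampler (weights 0.8 for negatives, 0.2 for positives,
countering class imbalance), early stopping on the monitored validation
metric -- F1 at threshold 0.5 for the classifier, Pearson r for the
regressor -- and checkpointing every epoch.  The regressor can be
initialized from a trained classifier by copying all encoder and pooling
parameters and replacing the softmax head with a fresh scaled-tanh head
(transfer learning); every parameter stays trainable during fine-tuning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np

from .autodiff import Adam, Tensor
from .losses import LossWeights, classifier_loss_batched, regressor_loss
from .model import (Checkpoint, EncoderConfig, clone_params, forward,
                    forward_batch, init_params, param_list)


class TrainingError(ValueError):
    pass


@dataclass
class TrainingConfig:
    max_epochs: int = 50
    lr_init: float = 1e-4
    lr_min: float = 1e-5
    sampler_weights: tuple = (0.8, 0.2)   # (negative, positive)
    patience: int = 10
    batch_size: int = 2
    seed: int = 0
    grad_clip: float = 5.0
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.lr_min > self.lr_init:
            raise TrainingError("lr_min must not exceed lr_init")
        if self.patience > self.max_epochs:
            raise TrainingError("patience must not exceed max_epochs")


def cosine_lr(epoch: int, config: TrainingConfig) -> float:
    """Cosine annealing from lr_init (epoch 0) to lr_min (final epoch)."""
    if config.max_epochs == 1:
        return config.lr_init
    frac = epoch / (config.max_epochs - 1)
    return config.lr_min + 0.5 * (config.lr_init - config.lr_min) * (1 + np.cos(np.pi * frac))


def sampler_weights(labels, w_neg: float = 0.8, w_pos: float = 0.2) -> np.ndarray:
    """Per-example draw weights for the class-balancing sampler."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        warnings.warn("single-class dataset: falling back to uniform sampling weights",
                      stacklevel=2)
        return np.full(len(labels), 1.0 / len(labels))
    w = np.where(labels == 0, w_neg, w_pos).astype(float)
    return w


def _clip_gradients(params: list, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _f1_at_half(scores, labels) -> float:
    pred = np.asarray(scores) >= 0.5
    labels = np.asarray(labels)
    tp = np.sum(pred & (labels == 1))
    fp = np.sum(pred & (labels == 0))
    fn = np.sum(~pred & (labels == 1))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return float(2 * p * r / (p + r)) if p + r else 0.0


def _rank_auc(scores, labels) -> float:
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        return 0.5
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(labels, np.asarray(scores)))


def _pearson(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def predict_scores(examples, params: dict, config: EncoderConfig,
                   chunk: int = 64) -> np.ndarray:
    """Inference-mode scores (p_pos or DockQ estimate) for graph examples."""
    out = []
    for start in range(0, len(examples), chunk):
        batch = [e.graph for e in examples[start:start + chunk]]
        out.append(forward_batch(batch, params, config).p_pos.value)
    return np.concatenate(out)


def init_from_classifier(checkpoint: Checkpoint, seed: int = 0) -> dict:
    """Regressor parameters transferred from a trained classifier.

    Encoder, GRU, pooling-gate and node-type parameters are copied verbatim;
    the classifier head is discarded and a freshly initialized scaled-tanh
    head attached.
    """
    params = clone_params(checkpoint.params)
    for k in ("Wc1", "bc1", "Wc2", "bc2"):
        params.pop(k, None)
    h = checkpoint.encoder_config.hidden_dim
    rng = np.random.default_rng((seed, 7))
    bound = 1.0 / np.sqrt(h)
    params["Wr"] = Tensor(rng.uniform(-bound, bound, (h, 1)), requires_grad=True)
    params["br"] = Tensor(np.zeros(1), requires_grad=True)
    return params


@dataclass
class TrainingResult:
    checkpoints: list            # every epoch, in order
    best: Checkpoint
    history: list                # per-epoch dicts of losses / metrics

    def top(self, k: int = 5) -> list:
        """The k checkpoints with the best monitored validation metric."""
        ranked = sorted(self.checkpoints,
                        key=lambda c: (-c.metrics["monitored"],
                                       -c.metrics.get("val_rank", 0.0)))
        return ranked[:k]


def train(task: str, train_examples, val_examples,
          encoder_config: EncoderConfig | None = None,
          config: TrainingConfig | None = None,
          init: Checkpoint | None = None,
          log_path=None) -> TrainingResult:
    """Train a classifier or regressor on featurized LabeledExamples.

    ``train_examples`` / ``val_examples`` must carry ``.graph`` (a PoseGraph),
    ``.label``, ``.dockq`` and an ``example_id`` whose complex prefix defines
    the ranking groups of the listwise loss.
    """
    if task not in ("classifier", "regressor"):
        raise TrainingError(f"unknown task {task!r}")
    if not train_examples or not val_examples:
        raise TrainingError("train and validation sets must be non-empty")
    encoder_config = encoder_config or EncoderConfig()
    config = config or TrainingConfig()
    rng = np.random.default_rng((config.seed, 11))

    if task == "classifier":
        val_labels = [e.label for e in val_examples]
        if len(set(val_labels)) < 2:
            raise TrainingError("validation set is single-class")
        if init is not None:
            params = clone_params(init.params)
        else:
            params = init_params(encoder_config, seed=config.seed)
            # start the output bias at the log-odds of drawing a positive
            # under the weighted sampler, so early updates are discriminative
            # instead of re-learning the base rate
            labels = np.asarray([e.label for e in train_examples])
            w_neg, w_pos = config.sampler_weights
            pos_mass = w_pos * labels.sum()
            neg_mass = w_neg * (len(labels) - labels.sum())
            if pos_mass > 0 and neg_mass > 0:
                params["bc2"].value = np.array([0.0, np.log(pos_mass / neg_mass)])
    else:
        if init is not None:
            params = init_from_classifier(init, seed=config.seed)
        else:
            params = init_params(encoder_config, seed=config.seed, regressor=True)

    plist = param_list(params)
    opt = Adam(plist, lr=config.lr_init)
    draw_w = sampler_weights([e.label for e in train_examples], *config.sampler_weights)
    draw_p = draw_w / draw_w.sum()

    result = TrainingResult(checkpoints=[], best=None, history=[])
    best_metric, best_epoch = (-np.inf, -np.inf), -1
    n = len(train_examples)
    for epoch in range(config.max_epochs):
        opt.lr = cosine_lr(epoch, config)
        order = rng.choice(n, size=n, replace=True, p=draw_p)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = [train_examples[i] for i in order[start:start + config.batch_size]]
            if len(batch) < 2:
                continue
            out = forward_batch([e.graph for e in batch], params, encoder_config,
                                training=True, rng=rng)
            if task == "classifier":
                loss, _ = classifier_loss_batched(out, [e.label for e in batch],
                                                  [e.dockq for e in batch],
                                                  config.loss_weights)
            else:
                groups = np.array([e.example_id.split("/")[0] for e in batch])
                if len(set(groups.tolist())) == len(groups):
                    groups = np.zeros(len(batch), dtype=int)  # fall back to whole batch
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    loss, _ = regressor_loss(out.p_pos, [e.dockq for e in batch], groups)
            if not np.isfinite(loss.item()):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            _clip_gradients(plist, config.grad_clip)
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1

        val_scores = predict_scores(val_examples, params, encoder_config)
        if task == "classifier":
            monitored = _f1_at_half(val_scores, [e.label for e in val_examples])
            # rank quality as a secondary criterion: F1 at a fixed threshold
            # is coarse (and degenerate while scores sit below 0.5)
            tiebreak = _rank_auc(val_scores, [e.label for e in val_examples])
        else:
            monitored = _pearson(val_scores, [e.dockq for e in val_examples])
            tiebreak = monitored
        record = {"epoch": epoch, "lr": opt.lr,
                  "train_loss": epoch_loss / max(n_batches, 1),
                  "monitored": monitored, "val_rank": tiebreak}
        result.history.append(record)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")
        ckpt = Checkpoint(params=clone_params(params), encoder_config=encoder_config,
                          training_config=_jsonable(config), epoch=epoch,
                          metrics={"monitored": monitored, "val_rank": tiebreak})
        result.checkpoints.append(ckpt)
        if (monitored, tiebreak) > best_metric:
            best_metric, best_epoch = (monitored, tiebreak), epoch
            result.best = ckpt
        elif epoch - best_epoch >= config.patience:
            break
    return result


def _jsonable(config: TrainingConfig) -> dict:
    d = asdict(config)
    d["loss_weights"] = asdict(config.loss_weights)
    return d
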