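"""End-to-end prediction and evaluation over complex structure files.

``predict_poses`` runs parse -> clean -> role assignment -> featurization ->
interface subgraph sampling -> encoder -> pooling -> heads for each input
structure, ensembling scores across checkpoints with a convex weight vector,
and returns one prediction row per input.  Per-structure failures are
recorded in-row and the run continues.  ``evaluate_run`` joins a prediction
table with labels and produces the full metrics report at both the fixed 0.5
threshold and the F-beta-optimal threshold, plus the filter-then-rank
precision@K table used for candidate selection.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .evaluation import (classification_metrics, select_threshold_fbeta,
                         topk_success)
from .features import FeaturizationConfig, HashedEmbedder, build_graph
from .model import EncoderConfig, ensemble_combine, forward
from .sampling import SamplingConfig, SamplingError, sample_subgraph
from .structure import (assign_roles, clean_structure, parse_structure,
                        read_annotations)


class PipelineError(ValueError):
    pass


def prepare_graph(tc, feat_config=None, sampling_config=None, embedder=None):
    """Featurize and sample one complex; returns (graph, warnings).

    A pose with no interface contacts cannot seed the interface sampler; the
    full graph is used instead and the condition is flagged.
    """
    g = build_graph(tc, feat_config or FeaturizationConfig(), embedder)
    notes = list(g.flags)
    try:
        g = sample_subgraph(g, sampling_config or SamplingConfig())
    except SamplingError:
        notes.append("no_seeds:full_graph_used")
    return g, notes


def featurize_examples(examples, feat_config=None, sampling_config=None, embedder=None):
    """Fill the ``.graph`` slot of LabeledExamples in place; returns them."""
    embedder = embedder or HashedEmbedder()
    for e in examples:
        e.graph, _ = prepare_graph(e.complex, feat_config, sampling_config, embedder)
    return examples


def _ensemble_forward(g, checkpoints, weights):
    scores = [forward(g, c.params, c.encoder_config).p_pos.item() for c in checkpoints]
    return ensemble_combine(scores, weights)


def _uniform(n: int):
    return np.full(n, 1.0 / n)


def predict_poses(paths, annotations, classifier_ckpts, regressor_ckpts=None,
                  clf_weights=None, reg_weights=None, threshold: float = 0.5,
                  feat_config=None, sampling_config=None, embedder=None) -> pd.DataFrame:
    """Score structures with classifier (and optionally regressor) ensembles.

    ``annotations`` is a chain-annotation list, a path to a TSV/JSON file, or
    a per-structure list of either.  Returns a DataFrame with one row per
    input path: clf_score, reg_score, predicted label at the threshold,
    subgraph size and any warnings or per-structure errors.
    """
    if not classifier_ckpts:
        raise PipelineError("at least one classifier checkpoint is required")
    clf_weights = _uniform(len(classifier_ckpts)) if clf_weights is None else np.asarray(clf_weights)
    if regressor_ckpts:
        reg_weights = _uniform(len(regressor_ckpts)) if reg_weights is None else np.asarray(reg_weights)
    embedder = embedder or HashedEmbedder()
    per_structure = isinstance(annotations, (list, tuple)) and len(annotations) == len(paths) \
        and all(isinstance(a, (str,)) or isinstance(a, list) for a in annotations)

    rows = []
    for i, path in enumerate(paths):
        row = {"id": str(path), "clf_score": np.nan, "reg_score": np.nan,
               "predicted_label": -1, "subgraph_size": 0, "warnings": "", "error": ""}
        try:
            ann = annotations[i] if per_structure else annotations
            if isinstance(ann, str):
                ann = read_annotations(ann)
            tc = assign_roles(clean_structure(parse_structure(path)), ann)
            g, notes = prepare_graph(tc, feat_config, sampling_config, embedder)
            row["subgraph_size"] = g.n_nodes
            row["warnings"] = ";".join(notes)
            row["clf_score"] = _ensemble_forward(g, classifier_ckpts, clf_weights)
            row["predicted_label"] = int(row["clf_score"] >= threshold)
            if regressor_ckpts:
                row["reg_score"] = _ensemble_forward(g, regressor_ckpts, reg_weights)
        except (ValueError, OSError) as e:
            row["error"] = f"{type(e).__name__}: {e}"
        rows.append(row)
    table = pd.DataFrame(rows)
    if (table["error"] != "").all():
        raise PipelineError("every input structure failed; first error: "
                            + table["error"].iloc[0])
    return table


def evaluate_run(predictions: pd.DataFrame, labels: pd.DataFrame,
                 beta: float = 1.0, k_list=(10, 20, 50, 100)) -> dict:
    """Metrics + top-K report for a prediction table against labels.

    ``labels`` needs columns id and label, optionally dockq.  The report
    carries metrics at threshold 0.5 and at the F-beta-optimal threshold,
    and the filter-then-rank precision@K table (regressor scores used for
    ranking when present, classifier scores otherwise).
    """
    merged = predictions.merge(labels, on="id", how="inner", validate="one_to_one")
    missing = set(labels["id"]) - set(merged["id"])
    if len(merged) == 0:
        raise PipelineError("no prediction/label ids joined")
    if "error" in merged:
        merged["error"] = merged["error"].fillna("")
        ok = merged[merged["error"] == ""]
    else:
        ok = merged
    scores = ok["clf_score"].to_numpy(dtype=float)
    y = ok["label"].to_numpy(dtype=int)
    dq = ok["dockq"].to_numpy(dtype=float) if "dockq" in ok else None

    report = {"n": int(len(ok)), "unjoined_ids": sorted(missing)}
    report["at_0.5"] = asdict(classification_metrics(scores, y, 0.5, dq))
    single_class = len(set(y.tolist())) < 2
    if single_class:
        report["fbeta_threshold"] = None
        report["at_fbeta"] = None
    else:
        t = select_threshold_fbeta(scores, y, beta)
        report["fbeta_threshold"] = t
        report["at_fbeta"] = asdict(classification_metrics(scores, y, t, dq))
    reg = ok["reg_score"].to_numpy(dtype=float) if "reg_score" in ok else scores
    if np.isnan(reg).all():
        reg = scores
    thr = report["fbeta_threshold"] if report["fbeta_threshold"] is not None else 0.5
    report["top_k"] = {str(k): v for k, v in
                       topk_success(scores, reg, y, thr, k_list).items()}
    if dq is not None and "reg_score" in ok and not np.isnan(reg).all():
        std_ok = np.std(dq) > 0 and np.std(reg) > 0
        report["regressor_pearson_r"] = float(np.corrcoef(dq, reg)[0, 1]) if std_ok else None
    return report
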