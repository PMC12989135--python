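"""DockQ computation, classification/regression metrics and candidate selection.

DockQ combines three interface-quality terms of a model complex against its
native reference -- Fnat (fraction of native cross-side residue contacts,
5 A heavy-atom criterion, recovered by the model), iRMS (backbone RMSD over
the native interface residues, 10 A definition, after superposing on those
residues) and LRMS (ligand backbone RMSD after superposing the receptors) --
into DockQ = (Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3.  The
immunoglobulin side plays the ligand, the antigen side the receptor;
multi-chain sides are merged into one rigid body each.  Scores of at least
0.8 label a pose positive (native-like).

Candidate selection follows filter-then-rank: the classifier discards
predicted negatives, the regressor ranks the survivors, and precision@K is
reported for each K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import BACKBONE_ATOMS
from .structure import TypedComplex

FNAT_CONTACT_CUTOFF = 5.0      # A, heavy-atom native contact
INTERFACE_CUTOFF = 10.0        # A, native interface residue definition
IRMS_SCALE = 1.5               # A
LRMS_SCALE = 8.5               # A

UNDEFINED = None


class EvaluationError(ValueError):
    pass


@dataclass
class DockQResult:
    fnat: float
    irms: float
    lrms: float
    dockq: float


@dataclass
class MetricsReport:
    precision: float | None
    recall: float | None
    f1: float | None
    auc_roc: float | None
    auc_pr: float | None
    pearson_r: float | None
    threshold: float


# ---------------------------------------------------------------------------
# rigid superposition (Kabsch via SVD)

def superpose(moving: np.ndarray, ref: np.ndarray):
    """Least-squares rigid fit of ``moving`` onto ``ref`` (Kabsch, SVD).

    Returns (rmsd, transform) where transform maps arbitrary coordinates
    through the fitted rotation+translation.
    """
    mc, rc = moving.mean(axis=0), ref.mean(axis=0)
    A = (moving - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T

    def transform(X):
        return (X - mc) @ R.T + rc

    diff = transform(moving) - ref
    return float(np.sqrt((diff**2).sum() / len(moving))), transform


def _side_residues(tc: TypedComplex, side: str):
    out = []
    for ann in tc.annotations:
        if ann.side == side:
            for res in tc.structure.chains[ann.chain_id]:
                out.append(((ann.chain_id, res.key), res))
    return out


def _backbone(res_list, keys):
    coords = []
    for key, res in res_list:
        if key not in keys:
            continue
        for name in BACKBONE_ATOMS:
            a = res.atom(name)
            if a is not None:
                coords.append(((key, name), a.coord))
    return coords


def _paired_backbone(model_res, native_res, keys):
    mb = dict(_backbone(model_res, keys))
    nb = _backbone(native_res, keys)
    M, N = [], []
    for k, c in nb:
        if k in mb:
            M.append(mb[k])
            N.append(c)
    return np.asarray(M), np.asarray(N)


def _contacts(ig_res, ag_res, cutoff: float) -> set:
    """Cross-side residue pairs with any heavy-atom pair within cutoff."""
    if not ig_res or not ag_res:
        return set()
    ig_atoms = np.concatenate([r.heavy_coords() for _, r in ig_res])
    ig_idx = np.concatenate([[i] * len(r.heavy_coords()) for i, (_, r) in enumerate(ig_res)])
    ag_atoms = np.concatenate([r.heavy_coords() for _, r in ag_res])
    ag_idx = np.concatenate([[j] * len(r.heavy_coords()) for j, (_, r) in enumerate(ag_res)])
    close = cdist(ig_atoms, ag_atoms) <= cutoff
    pairs = set()
    ii, jj = np.nonzero(close)
    for a, b in zip(ig_idx[ii], ag_idx[jj]):
        pairs.add((ig_res[a][0], ag_res[b][0]))
    return pairs


def dockq(model: TypedComplex, native: TypedComplex) -> DockQResult:
    """DockQ of a model complex against its native reference.

    Residues are matched by (chain id, author residue key); the ig side is
    the ligand, the ag side the receptor, each treated as one rigid body.
    """
    m_ig, m_ag = _side_residues(model, "ig"), _side_residues(model, "ag")
    n_ig, n_ag = _side_residues(native, "ig"), _side_residues(native, "ag")
    m_keys = {k for k, _ in m_ig} | {k for k, _ in m_ag}
    n_keys = {k for k, _ in n_ig} | {k for k, _ in n_ag}
    if not (m_keys & n_keys):
        raise EvaluationError("unresolvable chain/residue correspondence between model and native")

    native_contacts = _contacts(n_ig, n_ag, FNAT_CONTACT_CUTOFF)
    if not native_contacts:
        raise EvaluationError("no native interface: native has no cross-side contacts")
    model_contacts = _contacts(m_ig, m_ag, FNAT_CONTACT_CUTOFF)
    fnat = len(native_contacts & model_contacts) / len(native_contacts)

    # LRMS: superpose receptors (ag side), measure ligand backbone RMSD
    shared_ag = {k for k, _ in n_ag} & {k for k, _ in m_ag}
    shared_ig = {k for k, _ in n_ig} & {k for k, _ in m_ig}
    m_rec, n_rec = _paired_backbone(m_ag, n_ag, shared_ag)
    m_lig, n_lig = _paired_backbone(m_ig, n_ig, shared_ig)
    if len(m_rec) < 3 or len(m_lig) < 1:
        raise EvaluationError("too few shared backbone atoms for superposition")
    _, transform = superpose(m_rec, n_rec)
    diff = transform(m_lig) - n_lig
    lrms = float(np.sqrt((diff**2).sum() / len(m_lig)))

    # iRMS: native interface residues at 10 A, superpose on their backbones
    iface_pairs = _contacts(n_ig, n_ag, INTERFACE_CUTOFF)
    iface_keys = {k for pair in iface_pairs for k in pair} & (m_keys & n_keys)
    m_if, n_if = _paired_backbone(m_ig + m_ag, n_ig + n_ag, iface_keys)
    if len(m_if) < 3:
        raise EvaluationError("too few interface atoms for superposition")
    irms, _ = superpose(m_if, n_if)

    score = (fnat
             + 1.0 / (1.0 + (irms / IRMS_SCALE) ** 2)
             + 1.0 / (1.0 + (lrms / LRMS_SCALE) ** 2)) / 3.0
    return DockQResult(fnat=fnat, irms=irms, lrms=lrms, dockq=float(score))


def label_from_dockq(score: float, threshold: float = 0.8) -> int:
    """Binary pose label: 1 iff DockQ >= threshold (boundary inclusive)."""
    if not 0.0 <= score <= 1.0:
        raise EvaluationError(f"DockQ score {score} outside [0,1]")
    return int(score >= threshold)


# ---------------------------------------------------------------------------
# classification / regression metrics

def _prf(scores, labels, threshold):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def classification_metrics(scores, labels, threshold: float = 0.5,
                           y_true_continuous=None) -> MetricsReport:
    """Precision/recall/F1 at a threshold plus AUC-ROC and AP.

    AUC uses the rank statistic with tied ranks averaged; AP is the
    step-interpolated area under the precision-recall curve.  With a
    single-class label vector both are reported as the undefined sentinel,
    never silently as 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    precision, recall, f1 = _prf(scores, labels, threshold)
    if len(set(labels.tolist())) < 2:
        auc = ap = UNDEFINED
    else:
        auc = float(roc_auc_score(labels, scores))
        ap = float(average_precision_score(labels, scores))
    r = UNDEFINED
    if y_true_continuous is not None:
        y = np.asarray(y_true_continuous, dtype=float)
        if np.std(y) > 0 and np.std(scores) > 0:
            r = float(np.corrcoef(y, scores)[0, 1])
    return MetricsReport(precision=precision, recall=recall, f1=f1,
                         auc_roc=auc, auc_pr=ap, pearson_r=r, threshold=threshold)


def select_threshold_fbeta(scores, labels, beta: float = 1.0) -> float:
    """Threshold from the observed scores maximizing F-beta; ties -> lowest."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise EvaluationError("threshold selection needs both classes")
    best_t, best_f = None, -1.0
    for t in sorted(set(scores.tolist())):
        p, r, _ = _prf(scores, labels, t)
        denom = beta**2 * p + r
        fbeta = (1 + beta**2) * p * r / denom if denom else 0.0
        if fbeta > best_f + 1e-12:
            best_t, best_f = t, fbeta
    return float(best_t)


def topk_success(clf_scores, reg_scores, labels, clf_threshold: float,
                 k_list=(10, 20, 50, 100)):
    """Filter-then-rank precision@K.

    Examples with classifier score below the threshold are discarded; the
    survivors are ranked by regressor score (ties broken by classifier
    score, then input order) and precision@K counts the positives among the
    top K.  When fewer than K survivors exist the denominator stays K
    (missing slots count as failures) and the entry is flagged truncated.
    """
    clf = np.asarray(clf_scores, dtype=float)
    reg = np.asarray(reg_scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if not (len(clf) == len(reg) == len(lab)):
        raise EvaluationError("aligned score/label vectors required")
    surv = np.flatnonzero(clf >= clf_threshold)
    order = sorted(surv, key=lambda i: (-reg[i], -clf[i], i))
    out = {}
    for k in k_list:
        if k <= 0:
            raise EvaluationError("K must be positive")
        top = order[:k]
        out[k] = {"precision": float(sum(lab[i] for i in top)) / k,
                  "truncated": len(order) < k}
    return out
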