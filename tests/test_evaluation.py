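"""DockQ, classification metrics, F-beta thresholds and top-K selection."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from poseqa.evaluation import (EvaluationError, classification_metrics, dockq,
                               label_from_dockq, select_threshold_fbeta,
                               superpose, topk_success)
from poseqa.synthetic import FixtureConfig, make_native_complex, perturb_ig_side


# ---------------------------------------------------------------------------
# independently coded DockQ reference (different code path from the package:
# scipy align_vectors for superposition, pure-python loops for contacts)

def reference_dockq(model, native):
    def residues(tc, side):
        out = []
        for ann in tc.annotations:
            if ann.side == side:
                for r in tc.structure.chains[ann.chain_id]:
                    out.append(((ann.chain_id, r.key), r))
        return out

    def contacts(tc, cutoff):
        pairs = set()
        for ki, ri in residues(tc, "ig"):
            for kj, rj in residues(tc, "ag"):
                hit = False
                for a in ri.atoms:
                    for b in rj.atoms:
                        if a.element != "H" and b.element != "H" and \
                                np.linalg.norm(a.coord - b.coord) <= cutoff:
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    pairs.add((ki, kj))
        return pairs

    def backbone(tc, keys):
        coords = {}
        for side in ("ig", "ag"):
            for k, r in residues(tc, side):
                if k in keys:
                    for name in ("N", "CA", "C", "O"):
                        a = r.atom(name)
                        if a is not None:
                            coords[(k, name)] = a.coord
        return coords

    nat_contacts = contacts(native, 5.0)
    fnat = len(nat_contacts & contacts(model, 5.0)) / len(nat_contacts)

    def fit_rmsd(fit_keys, rms_keys):
        mb, nb = backbone(model, fit_keys | rms_keys), backbone(native, fit_keys | rms_keys)
        fit_ids = [k for k in nb if k[0] in fit_keys and k in mb]
        M = np.array([mb[k] for k in fit_ids])
        N = np.array([nb[k] for k in fit_ids])
        rot, rssd = Rotation.align_vectors(N - N.mean(0), M - M.mean(0))
        rms_ids = [k for k in nb if k[0] in rms_keys and k in mb]
        Mv = rot.apply(np.array([mb[k] for k in rms_ids]) - M.mean(0)) + N.mean(0)
        Nv = np.array([nb[k] for k in rms_ids])
        return float(np.sqrt(((Mv - Nv) ** 2).sum() / len(rms_ids)))

    ag_keys = {k for k, _ in residues(native, "ag")}
    ig_keys = {k for k, _ in residues(native, "ig")}
    lrms = fit_rmsd(ag_keys, ig_keys)
    iface = {k for pair in contacts(native, 10.0) for k in pair}
    irms = fit_rmsd(iface, iface)
    score = (fnat + 1 / (1 + (irms / 1.5) ** 2) + 1 / (1 + (lrms / 8.5) ** 2)) / 3
    return fnat, irms, lrms, score


@pytest.fixture(scope="module")
def native():
    return make_native_complex(FixtureConfig(), seed=13)


def test_dockq_self_comparison_is_perfect(native):
    r = dockq(native, native)
    assert r.fnat == 1.0
    assert r.irms == pytest.approx(0.0, abs=1e-9)
    assert r.lrms == pytest.approx(0.0, abs=1e-9)
    assert r.dockq == pytest.approx(1.0, abs=1e-12)


def test_dockq_destroyed_interface_near_zero(native):
    rng = np.random.default_rng(0)
    far = perturb_ig_side(native, 0.0, 100.0, 0.0, rng)
    r = dockq(far, native)
    assert r.fnat == 0.0
    assert r.dockq < 0.05


def test_dockq_matches_independent_reference_on_perturbed_fixtures(native):
    rng = np.random.default_rng(5)
    for rot, trans in [(0, 2.0), (10, 1.0), (30, 5.0)]:
        decoy = perturb_ig_side(native, rot, trans, 0.0, rng)
        r = dockq(decoy, native)
        fnat, irms, lrms, score = reference_dockq(decoy, native)
        assert r.fnat == pytest.approx(fnat, abs=1e-9)
        assert r.irms == pytest.approx(irms, abs=1e-3)
        assert r.lrms == pytest.approx(lrms, abs=1e-3)
        assert r.dockq == pytest.approx(score, abs=1e-3)


def test_dockq_invariant_under_global_rigid_motion(native):
    import copy
    rng = np.random.default_rng(2)
    decoy = perturb_ig_side(native, 15.0, 3.0, 0.0, rng)
    base = dockq(decoy, native)
    R = Rotation.random(random_state=7).as_matrix()
    t = np.array([5.0, -3.0, 12.0])
    moved_decoy, moved_native = copy.deepcopy(decoy), copy.deepcopy(native)
    for tc in (moved_decoy, moved_native):
        for cid in tc.structure.chains:
            for res in tc.structure.chains[cid]:
                for a in res.atoms:
                    a.coord = R @ a.coord + t
    both = dockq(moved_decoy, moved_native)
    assert both.dockq == pytest.approx(base.dockq, abs=1e-6)
    # moving the model alone: superposition-based terms are recomputed
    model_only = dockq(moved_decoy, native)
    assert model_only.lrms == pytest.approx(base.lrms, abs=1e-6)
    assert model_only.irms == pytest.approx(base.irms, abs=1e-6)


def test_dockq_decreases_with_perturbation_magnitude(native):
    from scipy.stats import spearmanr
    rng = np.random.default_rng(3)
    mags = [(0, 0), (2, 0.4), (5, 1), (10, 2), (20, 5), (45, 12), (90, 30)]
    scores = [dockq(perturb_ig_side(native, r, t, 0.0, rng), native).dockq
              for r, t in mags]
    rho = spearmanr(np.arange(len(mags)), scores).statistic
    assert rho <= -0.9


def test_superpose_recovers_exact_rigid_motion():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((10, 3))
    R = Rotation.random(random_state=3).as_matrix()
    rmsd, _ = superpose(X @ R.T + [1, 2, 3], X)
    assert rmsd < 1e-10


# ---------------------------------------------------------------------------
# labeling

def test_label_threshold_boundary_inclusive():
    assert label_from_dockq(0.8) == 1
    assert label_from_dockq(0.7999) == 0
    assert label_from_dockq(1.0) == 1
    with pytest.raises(EvaluationError):
        label_from_dockq(1.2)


# ---------------------------------------------------------------------------
# classification metrics vs brute-force oracles

def auc_pair_counting(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def ap_step_sum(scores, labels):
    """Step-wise PR area with tied scores grouped at one threshold."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    tp, fp, ap, prev_recall = 0, 0, 0.0, 0.0
    n_pos = labels.sum()
    for t in sorted(set(scores.tolist()), reverse=True):
        at_t = scores == t
        tp += labels[at_t].sum()
        fp += (1 - labels[at_t]).sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * (tp / (tp + fp))
        prev_recall = recall
    return ap


def test_perfect_separation_all_metrics_one():
    m = classification_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5)
    assert (m.precision, m.recall, m.f1, m.auc_roc, m.auc_pr) == (1, 1, 1, 1, 1)


def test_random_scores_auc_near_half():
    rng = np.random.default_rng(0)
    aucs = []
    for _ in range(200):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            continue
        aucs.append(classification_metrics(scores, labels, 0.5).auc_roc)
    assert abs(np.mean(aucs) - 0.5) < 0.03


def test_auc_ap_match_brute_force_oracles():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = int(rng.integers(6, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        m = classification_metrics(scores, labels, 0.5)
        assert m.auc_roc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)
        assert m.auc_pr == pytest.approx(ap_step_sum(scores, labels), abs=1e-12)


def test_single_class_metrics_are_undefined_sentinels():
    m = classification_metrics([0.2, 0.8], [1, 1], 0.5)
    assert m.auc_roc is None and m.auc_pr is None


def test_six_point_set_with_inversion():
    scores = [0.9, 0.8, 0.55, 0.6, 0.3, 0.1]
    labels = [1, 1, 1, 0, 0, 0]
    m = classification_metrics(scores, labels, 0.5)
    assert m.auc_roc == pytest.approx(auc_pair_counting(scores, labels))
    assert m.auc_pr == pytest.approx(ap_step_sum(scores, labels))


# ---------------------------------------------------------------------------
# F-beta threshold selection

def fbeta_scan_oracle(scores, labels, beta):
    best_t, best_f = None, -1.0
    for t in sorted(set(scores)):
        pred = np.asarray(scores) >= t
        labels_arr = np.asarray(labels)
        tp = np.sum(pred & (labels_arr == 1))
        fp = np.sum(pred & (labels_arr == 0))
        fn = np.sum(~pred & (labels_arr == 1))
        p = tp / (tp + fp) if tp + fp else 0
        r = tp / (tp + fn) if tp + fn else 0
        f = (1 + beta**2) * p * r / (beta**2 * p + r) if p + r else 0
        if f > best_f + 1e-12:
            best_t, best_f = t, f
    return best_t


def test_fbeta_threshold_matches_scan_oracle():
    rng = np.random.default_rng(11)
    for beta in (0.5, 1.0, 2.0):
        scores = np.round(rng.random(40), 2)
        labels = (scores + rng.normal(0, 0.3, 40) > 0.5).astype(int)
        if labels.min() == labels.max():
            continue
        assert select_threshold_fbeta(scores, labels, beta) == \
            fbeta_scan_oracle(scores, labels, beta)


def test_fbeta_separated_set_returns_lowest_gap_candidate():
    scores = [0.9, 0.8, 0.2, 0.1]
    labels = [1, 1, 0, 0]
    assert select_threshold_fbeta(scores, labels, 1.0) == 0.8


def test_small_beta_favors_precision():
    scores = np.array([0.95, 0.9, 0.85, 0.6, 0.55, 0.5, 0.45, 0.2])
    labels = np.array([1, 1, 1, 0, 1, 0, 0, 0])
    t_prec = select_threshold_fbeta(scores, labels, 0.1)
    t_rec = select_threshold_fbeta(scores, labels, 2.0)
    assert t_prec >= t_rec


# ---------------------------------------------------------------------------
# top-K candidate selection

def test_topk_saturated_and_alternating():
    n = 12
    clf = np.full(n, 0.9)
    reg = np.linspace(1, 0, n)
    out = topk_success(clf, reg, np.ones(n, dtype=int), 0.5, [10])
    assert out[10]["precision"] == 1.0 and not out[10]["truncated"]
    labels = np.array([1, 0] * 6)
    out = topk_success(clf, reg, labels, 0.5, [4])
    assert out[4]["precision"] == 0.5


def test_topk_filtering_and_truncation():
    clf = np.array([0.9, 0.4, 0.8, 0.3])   # two survive
    reg = np.array([0.5, 0.99, 0.7, 0.98])
    labels = np.array([1, 1, 1, 1])
    out = topk_success(clf, reg, labels, 0.5, [2, 10])
    assert out[2]["precision"] == 1.0
    assert out[10]["precision"] == pytest.approx(2 / 10)
    assert out[10]["truncated"]


def test_topk_invariant_to_order_of_discarded():
    rng = np.random.default_rng(0)
    clf = rng.random(30)
    reg = rng.random(30)
    labels = rng.integers(0, 2, 30)
    base = topk_success(clf, reg, labels, 0.6, [5, 10])
    # shuffle only the discarded examples
    disc = np.flatnonzero(clf < 0.6)
    perm = np.arange(30)
    perm[disc] = rng.permutation(disc)
    out = topk_success(clf[perm], reg[perm], labels[perm], 0.6, [5, 10])
    assert all(base[k]["precision"] == out[k]["precision"] for k in (5, 10))


def test_topk_default_report_ks():
    out = topk_success([0.9], [0.9], [1], 0.5)
    assert sorted(out) == [10, 20, 50, 100]
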