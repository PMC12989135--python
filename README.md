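# poseqa

Binding-pose quality assessment for immunoglobulin-antigen complexes.

Screening campaigns for therapeutic antibodies generate far more candidate
Ig-Ag poses — docking decoys, generative-model re-predictions — than can be
validated experimentally. `poseqa` is for computational structural biologists
who need to triage such poses: it decides whether a candidate pose of an
antibody, nanobody, scFv or TCR bound to its antigen is native-like, and
estimates how good the pose is on the DockQ scale.

## Method

A cleaned complex (PDB/mmCIF) is represented as a residue graph
G = (V, E, X_v, X_e, P): nodes are residues with 320-d sequence embeddings
and C-alpha coordinates; intra-side edges connect residue pairs with minimum
heavy-atom distance <= 3.5 A and interface edges cross-side pairs within
10 A; each edge carries three distances (minimum-atom, C-alpha, centroid)
expanded over 10 log-spaced Gaussian RBF scales in [0.25, 8] A (30 features).
Message passing runs on the 3-hop neighborhood of the interface (<= 600
nodes): four E(n)-equivariant GNN layers, each gated by a GRU residual
update, so scalar outputs are exactly invariant under rigid motions of the
input. A sigmoid-gated weighted sum over a selectable node subset yields the
graph embedding g, read out either by

- a softmax classifier, `p_pos` = probability the pose is a native-like
  cognate pose (trained with cross-entropy + auxiliary node-type
  cross-entropy + a Pearson term aligning `p_pos` with DockQ), or
- a scaled-tanh regressor, `y = (tanh(0.5 z) + 1)/2`, estimating DockQ
  (trained with negative Pearson correlation + a ListNet ranking loss,
  transfer-initialized from the classifier).

DockQ labeling is built in: Fnat, iRMS and LRMS combine as
DockQ = (Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2))/3, with >= 0.8
(inclusive) defining a positive pose. Candidate selection follows
filter-then-rank: the classifier discards predicted non-binders, the
regressor ranks survivors, and precision@K summarizes the shortlist.

A synthetic complex/decoy generator (see `docs/methods.md`) makes the whole
pipeline trainable and testable on one CPU in minutes, with cluster-aware
6:2:2 splits so held-out antigens are genuinely unseen.

## Worked example

```sh
python examples/03_score_with_dockq.py
```

```
 rot(deg)  trans(A)   Fnat   iRMS    LRMS  DockQ label
        0       0.0   1.00   0.00    0.00  1.000 1
        2       0.4   0.94   0.34    0.88  0.960 1
        8       1.5   0.52   1.22    3.01  0.669 0
       20       5.0   0.33   3.59    8.52  0.327 0
       60      20.0   0.00  12.29   28.16  0.033 0
```

Each row perturbs the immunoglobulin side of a synthetic native complex by
the given rotation/translation: as the pose degrades, fewer native contacts
survive (Fnat), the interface and ligand RMSDs grow, DockQ falls, and the
0.8 threshold flips the label from native-like (1) to non-native (0).

The other example scripts cover fixture generation (`01`), graph
featurization and interface sampling (`02`), classifier training with
held-out AUC (`04`), and filter-then-rank candidate selection (`05`). The
`poseqa` CLI exposes the same stages (`fixtures`, `featurize`, `train`,
`predict`, `evaluate`) for shell pipelines.

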