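# Methods

## Problem and model

`poseqa` scores candidate binding poses of immunoglobulin-antigen (Ig-Ag)
complexes: antibodies, nanobodies, scFvs or T-cell receptors bound to a
monomeric antigen or a peptide-MHC. Given a pose as a 3D structure, it
answers two questions: *is this a native-like pose of a cognate pair?*
(binary classifier, output `p_pos` in (0,1)) and *how good is the pose?*
(regressor estimating DockQ in (0,1)).

A cleaned structure becomes a residue-level graph. Nodes are residues,
carrying a 320-dimensional per-residue sequence embedding, a single 3D
coordinate (C-alpha; centroid when C-alpha is missing), a side tag (ig/ag), a
3-way type label (antigen / heavy-like / light-like) used by an auxiliary
head, and boolean masks (CDR, interface, CDR-epitope). Edges connect

- same-side residue pairs with minimum heavy-atom distance <= 3.5 A
  ("intra"; the ig side may span heavy+light chains, the ag side MHC+peptide),
- opposite-side pairs within 10.0 A ("inter"; the binding interface),

both cutoffs boundary-inclusive. Each edge carries three raw distances
(minimum atomic, C-alpha/C-alpha, centroid/centroid), each expanded through a
Gaussian radial-basis map exp(-d^2 / 2 s_k^2) with 10 length scales s_k
log-spaced inclusively over [0.25, 8] A — 30 features per edge. An
alternative parameterization with log-spaced centers is config-selectable
(`rbf_form="centers"`); the widths reading is the default because it keeps
every component monotone in distance.

Message passing consumes not the whole complex but the 3-hop
breadth-first neighborhood of the interface (seeds: unique endpoints of
inter edges, or CDR residues), capped at 600 nodes; within an overflowing
hop nodes are admitted in ascending index order until the cap is exactly
reached. Sampling is deterministic.

The encoder projects node features to a 64-wide hidden space (SiLU), then
applies four E(n)-equivariant message-passing layers, each followed by a GRU
gate. The EGNN layer is the standard form: per directed edge
m_ij = phi_e(h_i, h_j, ||p_i - p_j||^2, e_ij); coordinates update along
difference vectors with a degree-normalized sum; features update as
h~_i = phi_h(h_i, sum_j m_ij). All MLPs are two layers wide h with SiLU.
The GRU gate takes concat(h~, h_prev) as input and h_prev as hidden state,
output (1-z)*n + z*h_prev — a learnable gated residual that counteracts
oversmoothing and keeps a direct gradient path to earlier layers. Scalar
features touch geometry only through squared distances, so every scalar
output is invariant to rigid motions and node relabelings, while the
coordinate track is equivariant; the test suite asserts all three
numerically.

Readout is a sigmoid-gated weighted **sum** over a selected node subset
(seven strategies: all nodes, interface only, CDR-epitope only, CDR only,
and the three complements; default all nodes). The classifier head is a
two-layer SiLU MLP with softmax and dropout 0.1 between its layers; the
regressor head is a scaled tanh, y = (tanh(0.5 z) + 1)/2. A weighted convex
ensemble combines multiple models' scores; checkpoint averaging uses uniform
weights over the five best validation checkpoints.

## Objectives and training

Classifier loss: L = L_GC + alpha L_NC + beta L_MDN with alpha = 1e-3,
beta = 2e-3. L_GC is the two-class cross-entropy on the graph label, L_NC a
3-class cross-entropy on node types (auxiliary), and L_MDN the negative
Pearson correlation between p_pos and the ground-truth DockQ over the
minibatch — computed per minibatch because that is the only well-defined
online pool; batches with constant DockQ contribute 0 (sentinel, never a
silent zero elsewhere).

Regressor loss: L = -Corr(y, y^) + L_rank, with L_rank the top-one ListNet
listwise loss, grouped by source complex (falling back to the whole batch
when every group is a singleton); single-item groups are skipped with a
warning.

Training uses Adam from lr 1e-4 with cosine annealing to exactly 1e-5 at the
final epoch (up to 50 epochs; endpoints are asserted in tests), a weighted
random sampler drawing negatives/positives with weights 0.8/0.2, early
stopping on validation F1 at threshold 0.5 (classifier) or validation
Pearson r (regressor) with patience 10, and gradient clipping at global norm
5. The default batch size is 2 graphs: under the fixed learning-rate
schedule and the short desk-scale epoch budget, the step count — not the
per-step noise — limits how sharply the classifier resolves pose quality,
so small batches win. Two further classifier details: the output bias is
initialized to the log-odds of drawing a positive under the weighted
sampler (the standard imbalance trick, skipping the base-rate transient
that otherwise consumes much of a short budget), and when validation F1
ties across epochs — it is exactly 0 while all scores sit below 0.5 —
checkpoint selection falls back to validation AUC. The early-stopping
metric itself remains F1. The regressor is initialized from a trained
classifier by copying every encoder/pooling parameter and replacing the
softmax head with a fresh scaled-tanh head; everything stays trainable.

The network and training loop run on a small reverse-mode autodiff engine
over numpy (`poseqa.autodiff`): float64, graph-batched by disjoint union so
a minibatch is one forward pass, verified against finite differences.

## DockQ

DockQ is computed natively: Fnat = fraction of native cross-side residue
contacts (any heavy-atom pair <= 5 A) recovered by the model; LRMS = ligand
(ig-side) backbone RMSD after least-squares superposition of the receptor
(ag-side) backbones; iRMS = backbone RMSD over native interface residues
(10 A criterion) after superposing on exactly those residues; backbone =
N, CA, C, O; DockQ = (Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3.
Multi-chain sides are merged into one rigid body each. These constants are
the external standard for the metric; tests cross-check the implementation
against an independently coded reference (different superposition routine
and contact loops) to <= 1e-3. A score >= 0.8 labels a pose positive, with
the boundary inclusive.

## Synthetic benchmark

The generator emulates the statistical shape of a decoy-augmented pose
corpus at desk scale. Each pseudo-residue has N/CA/C/O plus one side-chain
atom (so the three edge distances differ and backbone RMSD is defined);
chains lie along smooth random space curves with ~3.8 A spacing. A 12-residue
window of the ig chain is laid parallel to the antigen curve at a 4.5 A
offset, guaranteeing >= 10 residue contacts at 5 A. Synthetic CDR intervals
are the ig residues within 8 A of the antigen, so all seven pooling masks
are non-trivial. Antigen clusters share a base curve and sequence; defaults:
100 complexes, 10 clusters, chains of 24 (ig) and 30 (ag) residues.

Decoys apply a rigid rotation+translation of the ig side about the interface
centroid plus per-atom Gaussian noise, over an 8-entry magnitude schedule
from identity (DockQ 1.0) to 70 degrees / 25 A (DockQ ~0.03), chosen so the
computed DockQ labels span (0,1) with cases on both sides of the 0.8
boundary, including deliberately ambiguous near-boundary poses. Non-cognate
examples transplant the ig chain of a complex from a different cluster to
the host antigen (centroid-aligned), labeled 0 with DockQ 0 by convention.
Splits assign whole antigen clusters to train/validation/test by seeded
greedy size balancing toward 6:2:2.

What the generator does **not** emulate: real side-chain packing, sterics
and torsional statistics; sequence-dependent binding chemistry (the
non-cognate pairs are distinguishable only geometrically); structure-
predictor error modes. Passing tests therefore demonstrate that the
pipeline, symmetries, losses and optimization behave correctly and that the
architecture can learn genuinely geometric pose-quality signal — not that
the trained toy model transfers to real antibody screening.

## Numerical choices

- Embeddings: the built-in deterministic "hashed" embedder draws each
  residue's 320-vector from a SHA-256-keyed Gaussian (rows normalized to
  ~unit norm), per one-letter code with a configurable sequence window
  (default 1). It is a stand-in interface for protein-language-model
  embeddings with identical shapes and no downloads.
- The squared-distance input to the edge MLP is scaled by 0.01 (edges are
  <= ~10 A) so the radial channel is O(1) against the other inputs at
  initialization.
- RBF components are clamped to the smallest positive normal to keep the
  "(0,1]" feature invariant under floating-point underflow.
- Altloc resolution keeps the label with the highest summed occupancy;
  exact ties keep the first label in file order. Non-standard residues
  (including MSE) are dropped, not converted. Distances use heavy atoms
  only by default (`keep_hydrogens` opts in to file hydrogens).
- Residue centroids are unweighted heavy-atom means; mass weighting is a
  config flag, default off.
- Parameter init is uniform fan-in; the coordinate-MLP output layer starts
  at zero so coordinates are initially untouched (stability).
- Undefined statistics (single-class AUC/AP, constant-vector Pearson) are
  `None` sentinels, never silent zeros.

## Problem sizes

The default benchmark used by the acceptance script and the heavier tests
is 100 complexes x (1 native + 8 decoys + 1 non-cognate) = 1000 graphs of
~50 residues, trained for up to 10 epochs — a few minutes on one CPU.
Unit tests use 6-12 complexes.

## Known limitations

- The classifier's discrimination on the synthetic benchmark is limited by
  deliberately ambiguous near-boundary decoys (DockQ within ~0.1 of the 0.8
  cut); scores track DockQ smoothly, so ranking errors concentrate there.
- No attention pooling, FastEGNN/MACE variants, or learned sampling.
- CDR intervals are consumed from annotations (or synthesized); no automatic
  Chothia/IMGT numbering.
- The CPU autodiff engine is not built for large corpora; it is sized for
  the desk-scale benchmark.
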