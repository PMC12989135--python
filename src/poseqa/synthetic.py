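"""Synthetic Ig-Ag complexes, graded decoys and a cluster-structured benchmark.

Real training corpora for pose scoring pair experimentally solved complexes
with decoys from generative structure predictors.  This module emulates the
essential statistical structure of such a corpus at desk scale:

* native complexes -- two pseudo-protein chains (4 backbone atoms plus one
  pseudo side-chain atom per residue) laid along smooth random space curves,
  posed so that a contact window of the immunoglobulin chain runs alongside
  the antigen chain, guaranteeing a contact-rich interface (>= 10 residue
  pairs within 5 A);
* cognate decoys -- rigid rotation+translation of the ig side about the
  interface centroid plus per-atom Gaussian noise, on a magnitude schedule
  chosen so the resulting DockQ labels span (0, 1) on both sides of the 0.8
  positive/negative boundary;
* non-cognate pairs -- ig chains swapped between complexes of different
  antigen clusters (label 0, DockQ 0 by convention);
* antigen clusters -- complexes in a cluster share a perturbed copy of the
  same base antigen curve and sequence, supporting leakage-free 6:2:2
  cluster-stratified splits.

Everything is bit-reproducible given (config, seed).  No physical realism
(sterics, torsion statistics) is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .evaluation import dockq, label_from_dockq
from .structure import (AA3_TO_1, AtomRecord, ChainAnnotation, ComplexStructure,
                        Residue, TypedComplex)

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA_LETTERS = "".join(sorted(AA1_TO_3))

# default perturbation schedule: (rotation deg, translation A, coordinate
# noise A).  Magnitudes are graded so decoy DockQ spans (0,1) with clear
# cases on both sides of the 0.8 labeling boundary: near-native poses stay
# well above it, perturbed poses fall well below, keeping the benchmark
# separable by construction.
DEFAULT_SCHEDULE = (
    (0.0, 0.0, 0.0),
    (1.0, 0.2, 0.03),
    (2.0, 0.4, 0.05),
    (10.0, 2.5, 0.25),
    (15.0, 3.5, 0.35),
    (25.0, 6.0, 0.45),
    (40.0, 12.0, 0.60),
    (70.0, 25.0, 1.00),
)


class FixtureError(ValueError):
    pass


@dataclass
class FixtureConfig:
    n_complexes: int = 100
    residues_per_chain: tuple = (24, 30)        # (ig, ag)
    decoys_per_complex: int = 8
    schedule: tuple = DEFAULT_SCHEDULE
    n_clusters: int = 10
    contact_window: int = 12                    # residues forced into contact
    contact_offset: float = 4.5                 # A between the paired backbones
    min_contacts: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.n_complexes, self.decoys_per_complex, self.n_clusters,
               *self.residues_per_chain) < 1:
            raise FixtureError("all counts must be >= 1")
        for entry in self.schedule:
            if min(entry) < 0:
                raise FixtureError("schedule magnitudes must be >= 0")


@dataclass
class LabeledExample:
    example_id: str
    complex: TypedComplex
    label: int
    dockq: float
    cluster: int
    kind: str               # native | decoy | non_cognate
    graph: object = None    # PoseGraph cache, filled by the pipeline


# ---------------------------------------------------------------------------
# geometry helpers

def _smooth_curve(rng, n: int, step: float = 3.8, wobble: float = 0.35) -> np.ndarray:
    """Random space curve with ~step spacing and slowly drifting direction."""
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        d = d + wobble * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + step * d)
    return np.asarray(pts)


def _frames(curve: np.ndarray):
    """Per-point tangent and two stable normals."""
    t = np.gradient(curve, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(t, ref)
    bad = np.linalg.norm(u, axis=1) < 1e-6
    u[bad] = np.cross(t[bad], [1.0, 0.0, 0.0])
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(t, u)
    return t, u, v


def _chain_from_curve(curve: np.ndarray, sequence: str) -> list:
    """Place N/CA/C/O plus a pseudo side-chain atom on each curve point."""
    t, u, v = _frames(curve)
    residues = []
    for i, letter in enumerate(sequence):
        c, ti, ui, vi = curve[i], t[i], u[i], v[i]
        atoms = [
            AtomRecord("N", "N", c - 1.2 * ti + 0.3 * ui),
            AtomRecord("CA", "C", c),
            AtomRecord("C", "C", c + 1.2 * ti + 0.3 * ui),
            AtomRecord("O", "O", c + 1.5 * ti + 1.3 * ui),
            AtomRecord("CB", "C", c + 1.5 * vi),
        ]
        residues.append(Residue(name3=AA1_TO_3[letter], seq_id=i + 1, atoms=atoms))
    return residues


def _random_sequence(rng, n: int) -> str:
    return "".join(rng.choice(list(AA_LETTERS), size=n))


def _count_contacts(ig_res, ag_res, cutoff: float = 5.0) -> int:
    ig = np.concatenate([r.heavy_coords() for r in ig_res])
    igi = np.concatenate([[i] * 5 for i in range(len(ig_res))])
    ag = np.concatenate([r.heavy_coords() for r in ag_res])
    agi = np.concatenate([[j] * 5 for j in range(len(ag_res))])
    ii, jj = np.nonzero(cdist(ig, ag) <= cutoff)
    return len({(a, b) for a, b in zip(igi[ii], agi[jj])})


def _ig_side_atoms(tc: TypedComplex):
    for ann in tc.annotations:
        if ann.side == "ig":
            for res in tc.structure.chains[ann.chain_id]:
                for a in res.atoms:
                    yield a


def _copy_complex(tc: TypedComplex) -> TypedComplex:
    chains = {}
    for cid, residues in tc.structure.chains.items():
        chains[cid] = [Residue(r.name3, r.seq_id, r.icode,
                               [AtomRecord(a.name, a.element, a.coord.copy(),
                                           a.occupancy, a.altloc, a.is_hetatm)
                                for a in r.atoms], r.is_hetatm)
                       for r in residues]
    return TypedComplex(
        structure=ComplexStructure(chains=chains, source_id=tc.structure.source_id),
        annotations=[ChainAnnotation(a.chain_id, a.role, list(a.cdr_intervals))
                     for a in tc.annotations])


# ---------------------------------------------------------------------------
# generators

def make_native_complex(config: FixtureConfig | None = None, seed: int = 0,
                        ag_seed: int | None = None, source_id: str = "synthetic",
                        max_retries: int = 20) -> TypedComplex:
    """One synthetic native complex with a guaranteed contact-rich interface.

    ``ag_seed`` pins the antigen curve and sequence (complexes sharing it
    form an antigen cluster); ``seed`` drives everything complex-specific.
    """
    config = config or FixtureConfig()
    n_ig, n_ag = config.residues_per_chain
    m = min(config.contact_window, n_ig, n_ag)
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        ag_rng = np.random.default_rng(ag_seed if ag_seed is not None else (seed, 2))
        ag_curve = _smooth_curve(ag_rng, n_ag)
        ag_curve = ag_curve + 0.15 * rng.standard_normal(ag_curve.shape)  # within-cluster wiggle
        ag_seq = _random_sequence(ag_rng, n_ag)

        # contact window of the ig curve runs parallel to the antigen curve,
        # displaced along the local normal; tails continue as random curve
        _, u, _ = _frames(ag_curve)
        j0 = (n_ag - m) // 2
        i0 = (n_ig - m) // 2
        window = ag_curve[j0:j0 + m] + config.contact_offset * u[j0:j0 + m]
        ig_curve = np.zeros((n_ig, 3))
        ig_curve[i0:i0 + m] = window
        d = window[1] - window[0]
        d /= np.linalg.norm(d)
        back, dirn = window[0], -d
        for i in range(i0 - 1, -1, -1):
            dirn = dirn + 0.4 * rng.standard_normal(3)
            dirn /= np.linalg.norm(dirn)
            back = back + 3.8 * dirn
            ig_curve[i] = back
        fwd, dirn = window[-1], d
        for i in range(i0 + m, n_ig):
            dirn = dirn + 0.4 * rng.standard_normal(3)
            dirn /= np.linalg.norm(dirn)
            fwd = fwd + 3.8 * dirn
            ig_curve[i] = fwd

        ig_res = _chain_from_curve(ig_curve, _random_sequence(rng, n_ig))
        ag_res = _chain_from_curve(ag_curve, ag_seq)
        if _count_contacts(ig_res, ag_res) < config.min_contacts:
            continue

        # synthetic CDR intervals: ig residues within 8 A of the antigen
        ag_atoms = np.concatenate([r.heavy_coords() for r in ag_res])
        near = [i for i, r in enumerate(ig_res)
                if cdist(r.heavy_coords(), ag_atoms).min() <= 8.0]
        intervals, run = [], [near[0]]
        for i in near[1:]:
            if i == run[-1] + 1:
                run.append(i)
            else:
                intervals.append((run[0] + 1, run[-1] + 1))
                run = [i]
        intervals.append((run[0] + 1, run[-1] + 1))

        structure = ComplexStructure(chains={"H": ig_res, "A": ag_res}, source_id=source_id)
        anns = [ChainAnnotation("H", "ig_heavy", intervals),
                ChainAnnotation("A", "antigen", [])]
        return TypedComplex(structure=structure, annotations=anns)
    raise FixtureError(f"could not reach {config.min_contacts} contacts in {max_retries} tries")


def _interface_centroid(tc: TypedComplex) -> np.ndarray:
    ig = [r for ann in tc.annotations if ann.side == "ig"
          for r in tc.structure.chains[ann.chain_id]]
    ag = [r for ann in tc.annotations if ann.side == "ag"
          for r in tc.structure.chains[ann.chain_id]]
    ig_atoms = np.concatenate([r.heavy_coords() for r in ig])
    ag_atoms = np.concatenate([r.heavy_coords() for r in ag])
    d = cdist(ig_atoms, ag_atoms)
    ii, jj = np.nonzero(d <= 5.0)
    if len(ii) == 0:
        return np.concatenate([ig_atoms, ag_atoms]).mean(axis=0)
    return np.concatenate([ig_atoms[np.unique(ii)], ag_atoms[np.unique(jj)]]).mean(axis=0)


def perturb_ig_side(tc: TypedComplex, rot_deg: float, trans: float, noise: float,
                    rng) -> TypedComplex:
    """Rigid-move the ig side about the interface centroid, then add noise."""
    out = _copy_complex(tc)
    center = _interface_centroid(tc)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(rot_deg) * axis).as_matrix()
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    shift = trans * direction
    for a in _ig_side_atoms(out):
        a.coord = R @ (a.coord - center) + center + shift
        if noise > 0:
            a.coord = a.coord + noise * rng.standard_normal(3)
    return out


def make_decoys(native: TypedComplex, config: FixtureConfig | None = None,
                seed: int = 0):
    """Graded decoys of one native, each labeled by its computed DockQ."""
    config = config or FixtureConfig()
    rng = np.random.default_rng((seed, 3))
    out = []
    for k in range(config.decoys_per_complex):
        rot, trans, noise = config.schedule[k % len(config.schedule)]
        decoy = perturb_ig_side(native, rot, trans, noise, rng)
        out.append((decoy, dockq(decoy, native)))
    return out


def _transplant_ig(ag_host: TypedComplex, ig_donor: TypedComplex) -> TypedComplex:
    """Non-cognate pose: the donor's ig chain docked at the host's ig position."""
    host, donor = _copy_complex(ag_host), _copy_complex(ig_donor)
    host_ig = np.asarray([a.coord for a in _ig_side_atoms(host)])
    donor_ig = [a for a in _ig_side_atoms(donor)]
    shift = host_ig.mean(axis=0) - np.asarray([a.coord for a in donor_ig]).mean(axis=0)
    for a in donor_ig:
        a.coord = a.coord + shift
    chains, anns = {}, []
    for ann in donor.annotations:
        if ann.side == "ig":
            chains[ann.chain_id] = donor.structure.chains[ann.chain_id]
            anns.append(ann)
    for ann in host.annotations:
        if ann.side == "ag":
            chains[ann.chain_id] = host.structure.chains[ann.chain_id]
            anns.append(ann)
    sid = f"{donor.structure.source_id}_ig+{host.structure.source_id}_ag"
    return TypedComplex(structure=ComplexStructure(chains=chains, source_id=sid),
                        annotations=anns)


def build_benchmark(config: FixtureConfig | None = None):
    """Full labeled benchmark: natives, cognate decoys and non-cognate pairs."""
    config = config or FixtureConfig()
    if config.n_clusters > config.n_complexes:
        raise FixtureError("n_clusters may not exceed n_complexes")
    rng = np.random.default_rng((config.seed, 4))
    examples, natives, clusters = [], [], []
    for c in range(config.n_complexes):
        cluster = c % config.n_clusters
        if c < config.n_clusters:
            clusters.append(int(rng.integers(2**31)))
        native = make_native_complex(config, seed=config.seed * 100003 + c,
                                     ag_seed=clusters[cluster],
                                     source_id=f"cplx{c:04d}")
        natives.append((c, cluster, native))
        examples.append(LabeledExample(f"cplx{c:04d}/native", native, 1, 1.0, cluster, "native"))
        for d, (decoy, result) in enumerate(
                make_decoys(native, config, seed=config.seed * 100003 + c)):
            examples.append(LabeledExample(
                f"cplx{c:04d}/decoy{d}", decoy, label_from_dockq(result.dockq),
                result.dockq, cluster, "decoy"))
    # one non-cognate pairing per complex, donor drawn from a different cluster
    for c, cluster, native in natives:
        others = [t for t in natives if t[1] != cluster]
        donor = others[int(rng.integers(len(others)))][2]
        nc = _transplant_ig(native, donor)
        examples.append(LabeledExample(
            f"cplx{c:04d}/noncognate", nc, 0, 0.0, cluster, "non_cognate"))
    return examples


def split_by_cluster(examples, ratios=(0.6, 0.2, 0.2), seed: int = 0):
    """Cluster-stratified split: whole clusters go to one of train/val/test.

    Clusters are visited in seeded random order and each is assigned to the
    split with the largest remaining example-count deficit relative to the
    target ratios (greedy size balancing).
    """
    clusters = sorted({e.cluster for e in examples})
    if len(clusters) < 3:
        raise FixtureError("cluster split needs at least 3 clusters")
    by_cluster = {c: [e for e in examples if e.cluster == c] for c in clusters}
    total = len(examples)
    rng = np.random.default_rng((seed, 5))
    order = list(rng.permutation(clusters))
    counts = [0, 0, 0]
    assign = {}
    for c in order:
        deficits = [ratios[s] * total - counts[s] for s in range(3)]
        s = int(np.argmax(deficits))
        assign[c] = s
        counts[s] += len(by_cluster[c])
    splits = ([], [], [])
    for e in examples:
        splits[assign[e.cluster]].append(e)
    return splits
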