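"""Shared fixtures: toy structures on disk and small synthetic benchmarks."""

import numpy as np
import pytest

from poseqa.pipeline import featurize_examples
from poseqa.structure import (AtomRecord, ChainAnnotation, ComplexStructure,
                              Residue, TypedComplex)
from poseqa.synthetic import FixtureConfig, build_benchmark, make_native_complex

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.000   0.500   0.500  1.00  0.00           C
ATOM      5  C   GLY A   2       5.300   1.200   0.300  1.00  0.00           C
ATOM      6  N   SER A   3       7.000   1.000   0.000  1.00  0.00           N
ATOM      7  CA  SER A   3       8.200   1.800   0.400  1.00  0.00           C
ATOM      8  CA  LEU B  10       3.000   4.000   0.000  1.00  0.00           C
ATOM      9  CB  LEU B  10       3.500   5.200   0.500  1.00  0.00           C
ATOM     10  CA  LYS B  11       6.000   4.500   0.200  1.00  0.00           C
ATOM     11  CB  LYS B  11       6.500   5.700   0.100  1.00  0.00           C
ATOM     12  CA  TRP B  12       9.000   5.000   0.000  1.00  0.00           C
ATOM     13  CB  TRP B  12       9.500   6.100   0.300  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def toy_annotations():
    return [ChainAnnotation("A", "ig_heavy", [(1, 2)]),
            ChainAnnotation("B", "antigen", [])]


def make_residue(name3, seq_id, coords, names=None):
    names = names or [f"C{i}" if i else "CA" for i in range(len(coords))]
    atoms = [AtomRecord(n, "C" if n != "N" else "N", c) for n, c in zip(names, coords)]
    return Residue(name3=name3, seq_id=seq_id, atoms=atoms)


@pytest.fixture
def native_complex():
    return make_native_complex(FixtureConfig(), seed=7)


@pytest.fixture(scope="session")
def small_benchmark():
    """12 complexes / 4 clusters, featurized: enough for split + smoke training."""
    cfg = FixtureConfig(n_complexes=12, n_clusters=4, seed=3)
    examples = build_benchmark(cfg)
    featurize_examples(examples)
    return cfg, examples


@pytest.fixture(scope="session")
def smoke_model(small_benchmark):
    """A briefly trained classifier for pipeline/CLI smoke tests."""
    from poseqa.synthetic import split_by_cluster
    from poseqa.training import TrainingConfig, train

    _, examples = small_benchmark
    tr, va, te = split_by_cluster(examples, seed=3)
    result = train("classifier", tr, va,
                   config=TrainingConfig(max_epochs=2, patience=2, seed=3))
    return result, (tr, va, te)


def random_rigid_motion(rng):
    """A uniformly random rotation plus a translation of up to ~20 A."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


def apply_rigid_to_graph(g, R, t):
    import copy
    g2 = copy.deepcopy(g)
    g2.node_coords = g.node_coords @ R.T + t
    return g2
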