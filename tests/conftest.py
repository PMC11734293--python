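import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from gala.network import GalaModel, ModelConfig
from gala.ontology import label_matrix
from gala.synthetic import make_fixture


@pytest.fixture(scope="session")
def fixture():
    """The frozen 8-graph, 15-term synthetic instance (seed 17)."""
    return make_fixture()


@pytest.fixture(scope="session")
def fixture_labels(fixture):
    graphs = fixture["source_graphs"] + fixture["target_graphs"]
    annotations = {**fixture["source_annotations"],
                   **fixture["target_annotations"]}
    Y = label_matrix(annotations, fixture["index"], [g.id for g in graphs])
    return graphs, Y


def tiny_config(**overrides):
    defaults = dict(n_features=25, n_classes=15, gcn_layers=2, hidden_dim=8,
                    meta_nodes=3, heads=2, multilinear_dim=6, dropout=0.0,
                    seed=3)
    defaults.update(overrides)
    return ModelConfig(**defaults)


@pytest.fixture
def tiny_model():
    return GalaModel(tiny_config())


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_obo(tmp_path):
    """Diamond-shaped 5-term MF ontology plus one obsolete term."""
    text = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: left child
namespace: molecular_function
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: right child
namespace: molecular_function
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: diamond grandchild
namespace: molecular_function
is_a: GO:0000002 ! left child
is_a: GO:0000003 ! right child

[Term]
id: GO:0000005
name: leaf
namespace: molecular_function
is_a: GO:0000004 ! diamond grandchild

[Term]
id: GO:0000099
name: gone
namespace: molecular_function
is_obsolete: true
"""
    path = tmp_path / "toy.obo"
    path.write_text(text)
    return path


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.000   0.000   0.000  1.00 10.00           C
ATOM      4  N   GLY A   2       3.000   0.000   0.000  1.00 11.00           N
ATOM      5  CA  GLY A   2       4.000   0.000   0.000  1.00 11.00           C
ATOM      6  CA  TRP A   3       4.000   3.000   0.000  1.00 12.00           C
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path
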