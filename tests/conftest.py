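import numpy as np
import pandas as pd
import pytest

from latentomics.corpus_io import ModalityTable, build_corpus
from latentomics.path_classifier import extract_paths
from latentomics.synthetic_data import (
    GraphSpec,
    generate_pathway_fixture,
    generate_twin_fixture,
)


def make_table(modality: str, pairs) -> ModalityTable:
    return ModalityTable(
        modality, pd.DataFrame(pairs, columns=["disease", "feature"])
    )


@pytest.fixture
def tiny_corpus():
    """Three diseases, two modalities, handmade."""
    ae = make_table("Ae", [("d1", "A"), ("d1", "B"), ("d2", "B"),
                           ("d2", "C"), ("d3", "X")])
    bm = make_table("Bm", [("d1", "P"), ("d2", "Q"), ("d3", "R")])
    return build_corpus([ae, bm])


@pytest.fixture(scope="session")
def twin_fixture():
    return generate_twin_fixture(seed=7)


def paths_and_labels(fixture, label="L00"):
    node_labels = fixture.pathway.node_labels("TI")
    paths, labels = [], []
    for t in sorted(fixture.pathway.targets):
        for p in extract_paths(fixture.pathway.graph, t):
            paths.append(p)
            labels.append(label in node_labels.get(t, set()))
    return paths, np.asarray(labels, dtype=bool)


@pytest.fixture(scope="session")
def pathway_signal():
    return generate_pathway_fixture(GraphSpec(seed=1, noise_rate=0.05))


@pytest.fixture(scope="session")
def pathway_null():
    return generate_pathway_fixture(GraphSpec(seed=1, noise_rate=0.5))
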