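"""Topic-count selection by Louvain community detection.

For each modality an undirected disease-disease graph is built: two
diseases are joined iff they share at least one feature in that modality,
with edge weight equal to the shared-feature count.  Weighted Louvain
modularity optimization is run 20 times with distinct seeds and the mode
of the community counts taken per modality; the number of topics K is the
maximum of these modal counts over the modalities in play.
"""

from __future__ import annotations

import warnings
from collections import Counter
from itertools import combinations

import networkx as nx
from networkx.algorithms.community import louvain_communities

from .corpus_io import DiseaseCorpus

DEFAULT_RUNS = 20
DEFAULT_RESOLUTION = 1.0


def build_shared_feature_graph(corpus: DiseaseCorpus, modality: str) -> nx.Graph:
    """Shared-feature graph of one modality.

    Nodes are all corpus diseases (isolated ones kept at degree 0); an
    edge (d1, d2) exists iff the two diseases share >= 1 feature, weighted
    by the size of the feature-set intersection.
    """
    if modality not in corpus.vocab:
        raise KeyError(f"modality {modality!r} not in corpus")
    g = nx.Graph()
    g.add_nodes_from(corpus.diseases)
    # invert: feature -> carrying diseases, then count co-carriers per pair
    carriers: dict[int, list[str]] = {}
    for d, toks in enumerate(corpus.tokens[modality]):
        name = corpus.diseases[d]
        for v in set(toks.tolist()):
            carriers.setdefault(v, []).append(name)
    weights: Counter[tuple[str, str]] = Counter()
    for names in carriers.values():
        for a, b in combinations(sorted(names), 2):
            weights[(a, b)] += 1
    g.add_weighted_edges_from((a, b, w) for (a, b), w in weights.items())
    return g


def community_count(
    graph: nx.Graph,
    runs: int = DEFAULT_RUNS,
    seed: int = 0,
    resolution: float = DEFAULT_RESOLUTION,
) -> int:
    """Mode of the Louvain community count over `runs` seeded runs.

    Mode ties are broken toward the larger count: overshooting K is benign
    under the sparse topic prior (surplus topics stay empty), while
    undershooting collapses genuinely distinct clusters.  An edgeless
    graph has no modularity structure; its node count is returned with a
    warning (every node its own community).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        warnings.warn(
            "shared-feature graph has no edges; community count equals the "
            "node count",
            stacklevel=2,
        )
        return graph.number_of_nodes()
    counts = Counter(
        len(
            louvain_communities(
                graph, weight="weight", resolution=resolution, seed=seed + r
            )
        )
        for r in range(runs)
    )
    best = max(counts.values())
    return max(k for k, c in counts.items() if c == best)


def select_topic_number(
    corpus: DiseaseCorpus,
    runs: int = DEFAULT_RUNS,
    seed: int = 0,
    resolution: float = DEFAULT_RESOLUTION,
) -> int:
    """K = max over modalities of the modal Louvain community count."""
    return max(
        community_count(
            build_shared_feature_graph(corpus, m),
            runs=runs,
            seed=seed,
            resolution=resolution,
        )
        for m in corpus.modalities
    )


def export_graph(graph: nx.Graph, path) -> None:
    """Write the shared-feature graph as a weighted edge-list TSV."""
    import pandas as pd

    rows = [(a, b, d["weight"]) for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["disease_a", "disease_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )
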