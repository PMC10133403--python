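"""Seeded synthetic-data generators for every pipeline stage.

Three families of fixtures, all text-only and reproducible from a seed:

* corpora drawn from the topic model's own generative process (Dirichlet
  topic weights per disease, per-modality Dirichlet topic-feature
  distributions, categorical tokens), with the ground-truth parameters
  returned for recovery tests;
* directed pathway graphs with planted path-motif/label associations
  emulating the joined KEGG / DrugBank / SIDER structure consumed by the
  path classifier;
* feature -> category annotation tables with a planted enriched category
  for the chi-square enrichment stage.

The corpus generator's ``separation`` knob masks each topic's
distribution toward a dedicated vocabulary block: at 1.0 the per-topic
vocabularies are disjoint, at 0.0 the mask is flat and the corpus
carries no recoverable topic structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .corpus_io import DiseaseCorpus, ModalityTable, build_corpus
from .path_classifier import PathwayGraph

DEFAULT_MODALITIES = {"Ae": 50, "Bm": 50, "Gv": 50}


@dataclass
class CorpusSpec:
    """Generative settings for a synthetic disease corpus.

    Defaults mirror a small but structured multi-omics panel: 60 diseases
    over three modalities of 50 features each, three underlying topics,
    sparse topic weights (alpha 0.1, so most diseases are nearly
    single-topic as real disease-gene profiles are), 5-15 recorded
    features per disease per modality, and separation 0.95 — i.e. ~5% of
    recorded associations are background noise no topic structure can
    explain, roughly the residual unpredictability real association
    databases exhibit.  An ideal scorer knowing the true parameters
    reaches a mean leave-one-modality-out AUC of ~0.93 under these
    defaults; the separation knob trades that ceiling against noise
    (at 0 the corpus is pure noise and AUC is ~0.5).
    """

    D: int = 60
    K_true: int = 3
    modalities: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MODALITIES)
    )
    alpha_gen: float = 0.1
    beta_gen: float = 0.1
    tokens_per_disease_per_modality: tuple[int, int] = (5, 15)
    separation: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")
        if self.separation == 1.0 and any(
            v < self.K_true for v in self.modalities.values()
        ):
            raise ValueError(
                "separation=1 needs every vocabulary at least K_true large"
            )


@dataclass
class CorpusTruth:
    """Ground truth of a generated corpus, for recovery tests."""

    theta: np.ndarray  # D x K_true
    phi: dict[str, np.ndarray]  # modality -> K_true x V
    feature_ids: dict[str, list[str]]
    feature_sets: dict[tuple[str, str], set[str]]  # (disease, modality)
    diseases: list[str]


def _topic_blocks(V: int, K: int) -> np.ndarray:
    """Contiguous block id per vocabulary index (block k belongs to topic k)."""
    return (np.arange(V) * K) // V


def generate_corpus(spec: CorpusSpec) -> tuple[DiseaseCorpus, CorpusTruth]:
    """Draw a corpus from the generative process.

    theta*_d ~ Dirichlet(alpha_gen); each topic's feature distribution
    blends a Dirichlet(beta_gen) draw restricted to the topic's own
    vocabulary block with a uniform background:

        phi*_k = separation * Dir_block_k + (1 - separation) * uniform

    so separation=1 gives disjoint per-topic vocabularies and
    separation=0 collapses every topic to the uniform distribution — a
    corpus with no recoverable structure at all, where imputation can do
    no better than chance.  (A skewed but topic-shared distribution
    would *not* be a chance-level null: globally frequent features are
    trivially predictable.)  Each token draws a topic from theta*_d then
    a feature from phi*_topic.  Drawn duplicates within one
    (disease, modality) collapse to their support, matching the
    association-list semantics of the corpus (a feature is recorded at
    most once per disease per modality).
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.K_true
    diseases = [f"d{i:03d}" for i in range(spec.D)]
    theta = rng.dirichlet(np.full(K, spec.alpha_gen), size=spec.D)

    phi: dict[str, np.ndarray] = {}
    feature_ids: dict[str, list[str]] = {}
    for m in sorted(spec.modalities):
        V = spec.modalities[m]
        raw = rng.dirichlet(np.full(V, spec.beta_gen), size=K)
        blocks = _topic_blocks(V, K)
        in_block = blocks[None, :] == np.arange(K)[:, None]
        block_draw = raw * in_block
        norms = block_draw.sum(axis=1, keepdims=True)
        # a topic whose in-block mass underflowed entirely: flat block
        flat = in_block / in_block.sum(axis=1, keepdims=True)
        block_draw = np.where(norms > 0, block_draw / np.where(norms > 0, norms, 1),
                              flat)
        phi[m] = spec.separation * block_draw + (1.0 - spec.separation) / V
        feature_ids[m] = [f"{m}_f{v:03d}" for v in range(V)]

    lo, hi = spec.tokens_per_disease_per_modality
    feature_sets: dict[tuple[str, str], set[str]] = {}
    tables = []
    for m in sorted(spec.modalities):
        rows = []
        for d, disease in enumerate(diseases):
            n = int(rng.integers(lo, hi + 1))
            z = rng.choice(K, size=n, p=theta[d])
            words = [int(rng.choice(len(phi[m][k]), p=phi[m][k])) for k in z]
            feats = {feature_ids[m][w] for w in words}
            feature_sets[(disease, m)] = feats
            rows.extend((disease, f) for f in sorted(feats))
        tables.append(
            ModalityTable(m, pd.DataFrame(rows, columns=["disease", "feature"]))
        )
    corpus = build_corpus(tables)
    return corpus, CorpusTruth(theta, phi, feature_ids, feature_sets, diseases)


# ---------------------------------------------------------------------------
# hidden-twin corpus (latent-discovery end-to-end fixture)
# ---------------------------------------------------------------------------

@dataclass
class TwinFixture:
    """A corpus with a planted latent disease similarity.

    ``target`` and ``twin`` belong to the same topic block, but in the
    ``held_out`` modality the target records only a small slice of the
    block while the twin records (nearly) all of it — so the block
    features the target is *missing* are overwhelmingly carried by the
    twin, visible only once the held-out modality is imputed.  ``decoy``
    is a disease with a pattern-matching cardiovascular name that is the
    sole carrier of ``decoy_feature``, which the related-disease filter
    must therefore remove.
    """

    corpus: DiseaseCorpus
    target: str
    twin: str
    decoy: str
    decoy_feature: str
    held_out: str
    planted_latent: set[str]  # held-out-block features absent from the target


def generate_twin_fixture(
    D: int = 30,
    V: int = 36,
    n_blocks: int = 3,
    modalities: tuple[str, ...] = ("Ae", "Bm", "Gv"),
    held_out: str = "Ae",
    features_per_disease: int = 6,
    target_observed: int = 4,
    seed: int = 0,
) -> TwinFixture:
    """Build the hidden-twin corpus deterministically from a seed."""
    if held_out not in modalities:
        raise ValueError("held_out must be one of the modalities")
    rng = np.random.default_rng(seed)
    target, twin, decoy = "target syndrome", "silent twin disorder", "heart failure"
    names = [target, twin, decoy] + [f"bystander {i:02d}" for i in range(D - 3)]
    block_of = {name: (0 if i < 3 else i % n_blocks) for i, name in enumerate(names)}
    blocks = _topic_blocks(V, n_blocks)

    ids = {m: [f"{m}_f{v:03d}" for v in range(V)] for m in modalities}
    block_feats = {
        m: {b: [ids[m][v] for v in np.where(blocks == b)[0]] for b in range(n_blocks)}
        for m in modalities
    }
    held_block0 = block_feats[held_out][0]
    target_set = set(held_block0[:target_observed])
    planted_latent = set(held_block0) - target_set
    decoy_feature = sorted(planted_latent)[-1]

    rows: dict[str, list[tuple[str, str]]] = {m: [] for m in modalities}
    for name in names:
        b = block_of[name]
        for m in modalities:
            pool = block_feats[m][b]
            if m == held_out and name == target:
                feats = sorted(target_set)
            elif m == held_out and name == twin:
                # the twin carries the whole block except the decoy feature
                feats = [f for f in held_block0 if f != decoy_feature]
            elif m == held_out and name == decoy:
                # sole carrier of the decoy feature, plus a small alibi set
                feats = [decoy_feature] + sorted(target_set)[:2]
            elif m == held_out and b == 0:
                # block-0 bystanders stay off the planted latent set
                feats = sorted(target_set)[:3]
            else:
                k = min(features_per_disease, len(pool))
                feats = [pool[i] for i in sorted(rng.choice(len(pool), k, False))]
            rows[m].extend((name, f) for f in feats)
    tables = [
        ModalityTable(m, pd.DataFrame(rows[m], columns=["disease", "feature"]))
        for m in modalities
    ]
    return TwinFixture(
        corpus=build_corpus(tables),
        target=target,
        twin=twin,
        decoy=decoy,
        decoy_feature=decoy_feature,
        held_out=held_out,
        planted_latent=planted_latent,
    )


# ---------------------------------------------------------------------------
# pathway fixtures
# ---------------------------------------------------------------------------

@dataclass
class GraphSpec:
    """Settings for a planted-motif pathway fixture.

    Each drug targets one node; drugs carry one of ``n_labels`` labels.
    A path rooted at a drug's target ends in that label's motif chain
    with probability 1 - noise_rate, otherwise in another label's motif
    (so at noise_rate = 0.5 with two labels the motif carries no label
    information).  Fillers between target and motif are unique per path,
    keeping extraction exact; a few within-path back-edges exercise the
    cycle handling.

    The default is one path per target over 200 targets: labels attach
    to targets, so with several paths per shared start the start-node
    identity itself predicts the label regardless of motif content;
    one-path-per-target fixtures keep the planted motif the only
    cross-path label signal, which is what the null (noise 0.5) fixture
    must guarantee.
    """

    n_targets: int = 200
    n_labels: int = 2
    motif_length: int = 4
    n_paths_per_target: int = 1
    filler_range: tuple[int, int] = (2, 5)
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.n_labels < 1:
            raise ValueError("need at least one label")


@dataclass
class PathwayFixture:
    pathway: PathwayGraph
    edges: pd.DataFrame
    drug_targets: pd.DataFrame
    drug_labels: pd.DataFrame
    label_motifs: dict[str, tuple[str, ...]]  # truth
    planted_paths: dict[str, list[tuple[str, ...]]]  # target -> sequences


def generate_pathway_fixture(spec: GraphSpec) -> PathwayFixture:
    """Build the planted-motif pathway graph and its drug tables."""
    rng = np.random.default_rng(spec.seed)
    labels = [f"L{j:02d}" for j in range(spec.n_labels)]
    motifs = {
        lab: tuple(f"mot{j}_{t}" for t in range(spec.motif_length))
        for j, lab in enumerate(labels)
    }
    g = nx.DiGraph()
    for motif in motifs.values():
        for a, b in zip(motif, motif[1:]):
            g.add_edge(a, b)
        g.add_node(motif[-1])  # length-1 motif: still a sink

    edges: list[tuple[str, str]] = list(g.edges)
    targets = [f"hsa:{1000 + i}" for i in range(spec.n_targets)]
    drug_rows, label_rows = [], []
    planted: dict[str, list[tuple[str, ...]]] = {}
    lo, hi = spec.filler_range
    for i, tnode in enumerate(targets):
        drug = f"D{i:04d}"
        own = labels[i % spec.n_labels]
        drug_rows.append((drug, tnode))
        label_rows.append((drug, own))
        planted[tnode] = []
        for j in range(spec.n_paths_per_target):
            if rng.random() < 1.0 - spec.noise_rate or spec.n_labels == 1:
                motif = motifs[own]
            else:
                other = rng.choice([lab for lab in labels if lab != own])
                motif = motifs[str(other)]
            n_fill = int(rng.integers(lo, hi + 1))
            fillers = [f"n{i}_{j}_{t}" for t in range(n_fill)]
            chain = [tnode, *fillers, *motif]
            for a, b in zip(chain, chain[1:]):
                if not g.has_edge(a, b):
                    g.add_edge(a, b)
                    edges.append((a, b))
            planted[tnode].append(tuple(chain))
        # one back-edge among the first path's fillers plants a cycle
        first = planted[tnode][0]
        if len(first) - spec.motif_length >= 3:  # target + >= 2 fillers
            a, b = first[2], first[1]
            if not g.has_edge(a, b):
                g.add_edge(a, b)
                edges.append((a, b))

    drug_targets = pd.DataFrame(drug_rows, columns=["drug", "target"])
    drug_labels = pd.DataFrame(label_rows, columns=["drug", "label"])
    dt_map: dict[str, set[str]] = {}
    for drug, t in drug_rows:
        dt_map.setdefault(drug, set()).add(t)
    lab_map: dict[str, set[str]] = {}
    for drug, lab in label_rows:
        lab_map.setdefault(drug, set()).add(lab)
    pathway = PathwayGraph(g, dt_map, drug_ti=lab_map, drug_se=lab_map)
    return PathwayFixture(
        pathway=pathway,
        edges=pd.DataFrame(edges, columns=["source", "target"]),
        drug_targets=drug_targets,
        drug_labels=drug_labels,
        label_motifs=motifs,
        planted_paths=planted,
    )


def write_pathway_fixture(fixture: PathwayFixture, out_dir) -> None:
    """Write the fixture as the edge-list / drug-table TSV dialects the
    classifier loaders consume (the generators double as format docs)."""
    from pathlib import Path as _P

    out = _P(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture.edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    fixture.drug_targets.to_csv(out / "drug_targets.tsv", sep="\t", index=False)
    fixture.drug_labels.to_csv(out / "drug_labels.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

def generate_annotation_fixture(
    features: list[str],
    categories: list[str],
    enriched: tuple[str, float] | None = None,
    enriched_subset: list[str] | None = None,
    base_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature -> category annotation table with an optional planted
    enrichment: the `enriched` (category, fold) pair boosts membership of
    the designated feature subset to min(1, base_rate * fold).  fold=1 is
    the null table."""
    if enriched is not None and enriched[1] < 1:
        raise ValueError("enrichment fold must be >= 1")
    rng = np.random.default_rng(seed)
    subset = set(enriched_subset or [])
    rows = []
    for f in features:
        for c in categories:
            p = base_rate
            if enriched is not None and c == enriched[0] and f in subset:
                p = min(1.0, base_rate * enriched[1])
            if rng.random() < p:
                rows.append((f, c))
    return pd.DataFrame(rows, columns=["feature", "category"])


def expected_reference_cap(n_pairs: int) -> int:
    """ceil(500 / n) cap used by the Method B reference sampler."""
    return math.ceil(500 / n_pairs)
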