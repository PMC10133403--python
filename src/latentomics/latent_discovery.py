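"""From imputation scores to latent features and latent disease similarity.

Three filters turn an imputation run into "latent omics features" of the
target disease: (1) keep features whose likeliness clears the Youden
cut-off, (2) drop those already recorded for the disease (correctly
predicted, but not latent), (3) drop those derived from diseases whose
names match a pattern list of obviously related conditions (for chronic
kidney disease / myocardial infarction: heart, cardi, athero, arterio,
coronary, kidney, renal, nephro, glomer, diabe, vascul, capil,
hypertens).  Mapping the surviving features back to the training diseases
that carry them — ranked by how many latent features each contributes —
yields the latent disease-similarity table.

A generic chi-square enrichment over any feature -> category annotation
table (e.g. Human Protein Atlas organ/cell assignments) characterizes a
latent feature set against a stated background universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .corpus_io import DiseaseCorpus
from .topic_model import ImputationResult


@dataclass
class NamePatternSet:
    """Case-insensitive substring patterns over disease names.

    Trailing/leading ``**`` wildcards in the source notation (e.g.
    ``nephro**`` "could be any characters") reduce to plain substring
    matching, so patterns are stored as lowercase cores.
    """

    patterns: list[str]

    def __post_init__(self) -> None:
        cores = [p.strip().strip("*").lower() for p in self.patterns]
        self.patterns = [c for c in cores if c]
        if not self.patterns:
            raise ValueError("pattern set is empty")

    def matches(self, disease_name: str) -> bool:
        low = disease_name.lower()
        return any(p in low for p in self.patterns)

    @classmethod
    def from_file(cls, path) -> "NamePatternSet":
        with open(path, encoding="utf-8") as fh:
            lines = [ln.strip() for ln in fh]
        return cls([ln for ln in lines if ln and not ln.startswith("#")])

    @classmethod
    def default(cls) -> "NamePatternSet":
        """The cardiovascular/renal pattern list shipped with the package."""
        from importlib.resources import files

        return cls.from_file(
            files("latentomics.data") / "related_disease_patterns.txt"
        )


@dataclass
class LatentFeatureSet:
    """Ranked latent features of one (disease, modality) with provenance.

    ``provenance[f]`` is the set of training diseases carrying feature f
    (never the target itself); by construction no retained feature sits
    in the target's own recorded set, and every retained feature has at
    least one carrier that fails the related-disease pattern match.
    """

    disease: str
    modality: str
    features: list[tuple[str, float]]  # (feature, likeliness), descending
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.features]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [f for f, _ in self.features],
                "likeliness": [s for _, s in self.features],
                "carriers": [
                    "|".join(sorted(self.provenance.get(f, set())))
                    for f, _ in self.features
                ],
            }
        )


# ---------------------------------------------------------------------------
# the filter pipeline
# ---------------------------------------------------------------------------

def positive_features(
    result: ImputationResult, threshold: float
) -> list[tuple[str, float]]:
    """Features whose likeliness clears the Youden cut-off, descending."""
    order = np.argsort(-result.likeliness, kind="stable")
    return [
        (result.vocab[i], float(result.likeliness[i]))
        for i in order
        if result.likeliness[i] >= threshold
    ]


def filter_known(
    features: list[tuple[str, float]],
    corpus: DiseaseCorpus,
    disease: str,
    modality: str,
) -> list[tuple[str, float]]:
    """Drop features already recorded for the disease in this modality."""
    known = corpus.feature_set(disease, modality)
    return [(f, s) for f, s in features if f not in known]


def feature_carriers(
    corpus: DiseaseCorpus, modality: str, exclude: str | None = None
) -> dict[str, set[str]]:
    """Invert the corpus: feature -> set of carrying diseases (optionally
    excluding the target disease)."""
    carriers: dict[str, set[str]] = {}
    voc = corpus.vocab[modality]
    for d, toks in enumerate(corpus.tokens[modality]):
        name = corpus.diseases[d]
        if name == exclude:
            continue
        for v in set(toks.tolist()):
            carriers.setdefault(voc[v], set()).add(name)
    return carriers


def filter_related(
    features: list[tuple[str, float]],
    corpus: DiseaseCorpus,
    disease: str,
    modality: str,
    patterns: NamePatternSet,
    carrier_rule: str = "any",
) -> LatentFeatureSet:
    """Drop features derived from apparently related diseases.

    Under the strict default rule (``carrier_rule="any"``) a feature is
    removed as soon as one carrying disease matches the pattern set —
    derivation from any related disease taints the feature.  The lenient
    alternative (``"all"``) removes a feature only when every carrier
    matches.  Features with no carriers at all are dropped (no provenance
    to vouch for them).
    """
    if carrier_rule not in ("any", "all"):
        raise ValueError(f"carrier_rule must be 'any' or 'all', got {carrier_rule!r}")
    carriers = feature_carriers(corpus, modality, exclude=disease)
    kept: list[tuple[str, float]] = []
    provenance: dict[str, set[str]] = {}
    for f, s in features:
        carry = carriers.get(f, set())
        if not carry:
            continue
        hits = [c for c in carry if patterns.matches(c)]
        remove = bool(hits) if carrier_rule == "any" else len(hits) == len(carry)
        if remove:
            continue
        kept.append((f, s))
        provenance[f] = carry
    return LatentFeatureSet(disease, modality, kept, provenance)


def latent_similarity(latent: LatentFeatureSet, corpus: DiseaseCorpus) -> pd.DataFrame:
    """Latent disease-similarity table: per training disease, the number
    of the target's latent features it carries, descending (ties broken
    by name)."""
    counts: dict[str, int] = {}
    for f in latent.feature_ids():
        for carrier in latent.provenance.get(f, set()):
            counts[carrier] = counts.get(carrier, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["disease", "count"],
    )
    return df


def discover_latent_features(
    result: ImputationResult,
    corpus: DiseaseCorpus,
    threshold: float,
    patterns: NamePatternSet,
    carrier_rule: str = "any",
) -> LatentFeatureSet:
    """The full pipeline: Youden-positive -> drop known -> drop related."""
    feats = positive_features(result, threshold)
    feats = filter_known(feats, corpus, result.disease, result.modality)
    return filter_related(
        feats, corpus, result.disease, result.modality, patterns, carrier_rule
    )


# ---------------------------------------------------------------------------
# annotation enrichment
# ---------------------------------------------------------------------------

def chi_square_enrichment(
    features: set[str],
    annotations: pd.DataFrame,
    background: set[str],
    feature_col: str = "feature",
    category_col: str = "category",
) -> pd.DataFrame:
    """Per-category 2x2 chi-square enrichment of a feature set.

    For each category the contingency table
    ``[[in-set & in-category, in-set & out], [out-set & in-category,
    out-set & out]]`` is tested for independence with Yates continuity
    correction; Benjamini-Hochberg q-values are computed across the
    tested categories.  The background universe is an explicit argument —
    it is never inferred from the annotation table.
    """
    features = set(features)
    background = set(background)
    if not features <= background:
        raise ValueError("features must be a subset of the background")
    ann = annotations[annotations[feature_col].isin(background)]
    rows = []
    n_set = len(features)
    n_out = len(background) - n_set
    for category, sub in ann.groupby(category_col, sort=True):
        members = set(sub[feature_col])
        a = len(features & members)
        b = n_set - a
        c = len(members) - a
        d = n_out - c
        if a + c == 0:
            warnings.warn(
                f"category {category!r}: no members in the background, skipped",
                stacklevel=2,
            )
            continue
        if n_set == 0 or n_out == 0 or b + d == 0:
            # features == background (or the category covers it entirely):
            # the margins force independence
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = chi2_contingency(
                np.array([[a, b], [c, d]], dtype=float), correction=True
            )
        rows.append((category, a, float(chi2), float(p)))
    if not rows:
        return pd.DataFrame(columns=["category", "count", "chi2", "p", "q"])
    df = pd.DataFrame(rows, columns=["category", "count", "chi2", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["q", "p", "category"]).reset_index(drop=True)
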