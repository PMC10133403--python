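"""Reading, validation and assembly of multi-modal disease-omics corpora.

A corpus is built from long-format association tables (one row = disease,
feature), one table per omics modality — e.g. AlteredExpression (Ae),
Biomarker (Bm), GeneticVariation (Gv) exports from DisGeNET, or Microbiota
(Mb) from Disbiome.  Diseases kept in the corpus are those labeled in
*every* modality supplied; each modality has its own vocabulary, and the
per-disease token sets index into it.

Disease names may first be merged through a user-supplied synonym map
(many names -> one canonical id); with an empty map only exact string
matches merge, after normalising the possessive "’s" to a blank space.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODEL_FORMAT_VERSION = 1

_POSSESSIVE_RE = re.compile(r"[’']s\b")
_WS_RE = re.compile(r"\s+")


class TableFormatError(ValueError):
    """Raised when an association table is malformed."""


class CorpusBuildError(ValueError):
    """Raised when a corpus cannot be assembled from the given tables."""


class ModelIOError(ValueError):
    """Raised on malformed or incompatible serialized model state."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ModalityTable:
    """Deduplicated (disease, feature) association list for one modality."""

    modality: str
    rows: pd.DataFrame  # columns: disease, feature

    def __post_init__(self) -> None:
        self.rows = (
            self.rows[["disease", "feature"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    @property
    def diseases(self) -> set[str]:
        return set(self.rows["disease"])

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SynonymMap:
    """Many-to-one mapping from disease names to canonical identifiers."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, canon in self.mapping.items():
            if not str(canon).strip():
                raise ValueError(f"empty canonical id for name {name!r}")

    def resolve(self, name: str) -> str:
        return self.mapping.get(name, name)

    @classmethod
    def from_tsv(cls, path) -> "SynonymMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise TableFormatError(
                f"{path}: synonym map needs two columns (name, canonical id)"
            )
        name_col, canon_col = df.columns[:2]
        return cls(dict(zip(df[name_col], df[canon_col])))


@dataclass
class DiseaseCorpus:
    """Multi-modal token corpus over diseases.

    ``tokens[m][d]`` is an integer array of vocabulary indices for disease
    ``diseases[d]`` in modality ``m``; every retained disease carries at
    least one token in every modality.  Disease and vocabulary orderings
    are lexicographic so that fits are reproducible across platforms.
    """

    diseases: list[str]
    modalities: list[str]
    vocab: dict[str, list[str]]
    tokens: dict[str, list[np.ndarray]]

    def __post_init__(self) -> None:
        for m in self.modalities:
            v = len(self.vocab[m])
            for d, toks in enumerate(self.tokens[m]):
                if len(toks) == 0:
                    raise CorpusBuildError(
                        f"disease {self.diseases[d]!r} has no tokens in "
                        f"modality {m!r}"
                    )
                if toks.max() >= v or toks.min() < 0:
                    raise CorpusBuildError(
                        f"token index out of range for modality {m!r}"
                    )

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def disease_index(self, disease: str) -> int:
        try:
            return self.diseases.index(disease)
        except ValueError:
            raise KeyError(f"disease {disease!r} not in corpus") from None

    def vocab_size(self, modality: str) -> int:
        return len(self.vocab[modality])

    def feature_set(self, disease: str, modality: str) -> set[str]:
        """The disease's recorded feature identifiers in one modality."""
        d = self.disease_index(disease)
        voc = self.vocab[modality]
        return {voc[i] for i in self.tokens[modality][d]}

    def token_count(self, modality: str) -> int:
        return int(sum(len(t) for t in self.tokens[modality]))

    def to_tables(self) -> list[ModalityTable]:
        """Export back to long-format association tables (one per modality)."""
        tables = []
        for m in self.modalities:
            voc = self.vocab[m]
            recs = [
                (self.diseases[d], voc[i])
                for d in range(self.n_diseases)
                for i in sorted(set(self.tokens[m][d].tolist()))
            ]
            tables.append(
                ModalityTable(m, pd.DataFrame(recs, columns=["disease", "feature"]))
            )
        return tables


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_modality_table(
    path,
    modality: str,
    disease_col: str = "disease_name",
    feature_col: str = "feature_id",
) -> ModalityTable:
    """Read one modality's association TSV.

    The file must have a header naming `disease_col` and `feature_col`
    (configurable to match DisGeNET/Disbiome-style exports).  Rows with an
    empty disease or feature field are rejected with their row numbers;
    duplicated (disease, feature) pairs collapse to one row.  Feature-id
    casing is preserved: identifiers are opaque, case-sensitive strings.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty table") from None
    missing = [c for c in (disease_col, feature_col) if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    if len(df) == 0:
        raise TableFormatError(f"{path}: table has a header but no rows")
    bad = df.index[
        (df[disease_col].str.strip() == "") | (df[feature_col].str.strip() == "")
    ]
    if len(bad):
        # +2: 1-based line numbers, after the header line
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise TableFormatError(
            f"{path}: empty disease/feature field at line(s) {lines}"
        )
    rows = df[[disease_col, feature_col]].rename(
        columns={disease_col: "disease", feature_col: "feature"}
    )
    return ModalityTable(modality, rows)


def normalize_disease_name(name: str) -> str:
    """Replace the possessive "’s" by a blank space and collapse whitespace,
    e.g. "Alzheimer’s disease" -> "Alzheimer disease"."""
    return _WS_RE.sub(" ", _POSSESSIVE_RE.sub(" ", name)).strip()


def canonicalize_diseases(
    table: ModalityTable, synonyms: SynonymMap | None = None
) -> ModalityTable:
    """Merge disease names: normalise the possessive, then apply the synonym
    map (unmapped names pass through unchanged) and re-deduplicate."""
    synonyms = synonyms or SynonymMap()
    rows = table.rows.copy()
    rows["disease"] = rows["disease"].map(
        lambda s: synonyms.resolve(normalize_disease_name(s))
    )
    return ModalityTable(table.modality, rows)


def build_corpus(tables: list[ModalityTable]) -> DiseaseCorpus:
    """Assemble the multi-modal corpus from per-modality tables.

    Only diseases labeled in every supplied modality are retained; each
    modality's vocabulary is the union of its feature ids over those
    diseases, ordered lexicographically.
    """
    if len(tables) < 2:
        raise CorpusBuildError("need at least two modality tables")
    seen = [t.modality for t in tables]
    if len(set(seen)) != len(seen):
        raise CorpusBuildError(f"duplicate modality tags: {seen}")

    common = set.intersection(*(t.diseases for t in tables))
    if not common:
        worst = min(tables, key=lambda t: len(t.diseases))
        raise CorpusBuildError(
            "no disease is labeled in every modality; smallest coverage is "
            f"modality {worst.modality!r} with {len(worst.diseases)} diseases"
        )
    diseases = sorted(common)
    d_index = {d: i for i, d in enumerate(diseases)}

    modalities, vocab, tokens = [], {}, {}
    for t in tables:
        rows = t.rows[t.rows["disease"].isin(common)]
        voc = sorted(rows["feature"].unique())
        v_index = {f: i for i, f in enumerate(voc)}
        per_disease: list[list[int]] = [[] for _ in diseases]
        for dis, feat in rows.itertuples(index=False):
            per_disease[d_index[dis]].append(v_index[feat])
        modalities.append(t.modality)
        vocab[t.modality] = voc
        tokens[t.modality] = [np.array(sorted(x), dtype=np.int64) for x in per_disease]
    return DiseaseCorpus(diseases, modalities, vocab, tokens)


def save_corpus(corpus: DiseaseCorpus, out_dir) -> None:
    """Write one TSV per modality (columns disease_name, feature_id)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in corpus.to_tables():
        t.rows.rename(
            columns={"disease": "disease_name", "feature": "feature_id"}
        ).to_csv(out / f"{t.modality}.tsv", sep="\t", index=False)


def load_corpus(in_dir, modalities: list[str] | None = None) -> DiseaseCorpus:
    """Read a corpus directory written by :func:`save_corpus` (or any set of
    `<modality>.tsv` association tables)."""
    from pathlib import Path

    d = Path(in_dir)
    if modalities is None:
        modalities = sorted(p.stem for p in d.glob("*.tsv"))
    tables = [read_modality_table(d / f"{m}.tsv", m) for m in modalities]
    return build_corpus(tables)


# ---------------------------------------------------------------------------
# model-state serialization
# ---------------------------------------------------------------------------

def save_model(state, path) -> None:
    """Serialize a fitted sampler state (posterior means, imputation
    frequency counters) as JSON.  Floats round-trip exactly through the
    JSON decimal representation."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "modalities": state.modalities,
        "diseases": state.diseases,
        "vocab": state.vocab,
        "n_samples": state.n_samples,
        "theta": state.theta.tolist(),
        "phi": {m: state.phi[m].tolist() for m in state.modalities},
        "missing": None
        if state.missing is None
        else {
            "disease": state.missing[0],
            "modality": state.missing[1],
            "freq": state.freq.tolist(),
            "n_slots": state.n_slots,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Inverse of :func:`save_model`; raises :class:`ModelIOError` on
    truncated files or format-version mismatch."""
    from .topic_model import FittedModel

    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelIOError(f"cannot read model state from {path}: {exc}") from None
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"model format version {version!r} != supported {MODEL_FORMAT_VERSION}"
        )
    miss = payload["missing"]
    return FittedModel(
        diseases=payload["diseases"],
        modalities=payload["modalities"],
        vocab=payload["vocab"],
        theta=np.asarray(payload["theta"], dtype=float),
        phi={m: np.asarray(p, dtype=float) for m, p in payload["phi"].items()},
        n_samples=int(payload["n_samples"]),
        missing=None if miss is None else (miss["disease"], miss["modality"]),
        freq=None if miss is None else np.asarray(miss["freq"], dtype=float),
        n_slots=None if miss is None else int(miss["n_slots"]),
    )
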