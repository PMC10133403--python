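"""Leave-one-modality-out evaluation of imputation quality.

For a probed (disease, modality) pair the disease's tokens in that
modality are removed, the model is refitted, and the imputation
likeliness of every vocabulary item is scored against the binary label
"was this feature in the disease's original set".  AUC summarizes the
ranking; the Youden index J = TPR - FPR picks the likeliness cut-off used
downstream to binarize predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .corpus_io import DiseaseCorpus
from .topic_model import ModelConfig, run_gibbs


class DegenerateLabelsError(ValueError):
    """Raised when the label vector contains a single class."""


@dataclass
class RocResult:
    """ROC curve with the Youden-index operating point.

    ``thresholds`` descend; a threshold t admits every item with score
    >= t (the leading entry is +inf, the empty positive set).  ``auc`` is
    the trapezoidal area under (fpr, tpr), equal to the normalized
    Mann-Whitney concordant-pair count.  ``youden_threshold`` maximizes
    TPR - FPR over the finite thresholds, ties broken toward the highest
    threshold (the most conservative positive set).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_threshold: float

    @property
    def youden_index(self) -> float:
        return float(np.max(self.tpr - self.fpr))


def roc_with_youden(scores, labels) -> RocResult:
    """ROC/AUC and the Youden cut-off for one score/label vector pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if labels.min() == labels.max():
        raise DegenerateLabelsError(
            f"labels contain a single class ({labels[0]}); AUC is undefined"
        )
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    finite = np.isfinite(thresholds)
    j = tpr - fpr
    j_finite = np.where(finite, j, -np.inf)
    # argmax returns the first (= highest-threshold) maximizer
    youden = float(thresholds[int(np.argmax(j_finite))])
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     youden_threshold=youden)


def loo_modality_scores(
    corpus: DiseaseCorpus,
    disease: str,
    modality: str,
    config: ModelConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Imputation likeliness scores and presence labels for one probe.

    Returns (scores, labels) over the modality's full vocabulary: scores
    are the likeliness values of a fit with (disease, modality) held out,
    labels mark membership in the disease's original feature set.  Labels
    are data-determined; only scores depend on the sampler seed.
    """
    original = corpus.feature_set(disease, modality)  # also validates disease
    _, imp = run_gibbs(corpus, config, missing=(disease, modality))
    assert imp is not None
    labels = np.array(
        [1 if f in original else 0 for f in imp.vocab], dtype=int
    )
    return imp.likeliness.copy(), labels


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def evaluate_corpus(
    corpus: DiseaseCorpus,
    config: ModelConfig,
    test_diseases: list[str],
    modalities: list[str] | None = None,
) -> pd.DataFrame:
    """Leave-one-modality-out table over a test subset.

    One row per (test disease, modality) with AUC and Youden threshold.
    Only the probed modality of the probed disease is ever removed; all
    other diseases keep all modalities.  Per-probe failures (e.g. a
    disease whose held-out set spans the whole vocabulary, leaving a
    one-class label vector) are reported as flagged rows, not aborts.
    """
    if not test_diseases:
        raise ValueError("test_diseases must be non-empty")
    modalities = modalities or list(corpus.modalities)
    rows = []
    run = 0
    for disease in test_diseases:
        for modality in modalities:
            cfg = ModelConfig(
                K=config.K,
                alpha=config.alpha,
                beta=config.beta,
                iterations=config.iterations,
                burn_in=config.burn_in,
                seed=_child_seed(config.seed, run),
                include_imputed_in_phi=config.include_imputed_in_phi,
            )
            run += 1
            try:
                scores, labels = loo_modality_scores(corpus, disease, modality, cfg)
                roc = roc_with_youden(scores, labels)
                rows.append(
                    (disease, modality, roc.auc, roc.youden_threshold, "")
                )
            except (DegenerateLabelsError, KeyError, ValueError) as exc:
                rows.append((disease, modality, np.nan, np.nan, str(exc)))
    return pd.DataFrame(
        rows, columns=["disease", "modality", "auc", "youden_threshold", "error"]
    )
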