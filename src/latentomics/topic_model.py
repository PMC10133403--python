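"""Multi-modal generative topic model of diseases and its Gibbs sampler.

The model is a multi-modal extension of latent Dirichlet allocation:
diseases play the role of documents and omics features (genes, biomarkers,
microbes) the role of words, with one vocabulary and one topic-feature
distribution phi_k per modality but a single shared per-disease topic
weight vector theta_d.  Sharing theta across modalities is what couples
them — every modality of a disease is forced to exhibit the same topic
profile, so diseases are soft-clustered by the co-occurrence structure of
all their modalities at once rather than by a concatenated bag of mixed
features.

Generative process, per disease d and modality (·):

    theta_d        ~ Dirichlet(alpha)                (K topics)
    phi_k(·)       ~ Dirichlet(beta(·))              (V(·) features)
    z_di(·)        ~ Categorical(theta_d)
    w_di(·) | z=k  ~ Categorical(phi_k(·))

Inference is explicit (uncollapsed) Gibbs sampling of the full
conditionals:

    p(z_di(·)=k | w=v)  ∝ theta_dk * phi_kv(·)
    theta_d | z         ~ Dirichlet(alpha_k + n_dk)        (n pooled over
                                                            all modalities)
    phi_k(·) | z, w     ~ Dirichlet(beta_v + n_kv(·))
    w'_di(·) | z=k      ~ Categorical(phi_k(·))

where w'_di(·) are the imputed tokens of a deliberately missing
(disease, modality) pair.  The number of missing slots is drawn once at
initialization from Binomial(V, p_hat) with p_hat the mean observed
per-disease token count divided by V, and held fixed; after burn-in the
sampler counts how often each vocabulary item lands in a missing slot.
The normalized counts ("likeliness") are the imputation scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .corpus_io import DiseaseCorpus

DEFAULT_ALPHA = 0.1
DEFAULT_BETA = 0.1
DEFAULT_ITERATIONS = 5000
DEFAULT_BURN_IN = 2000


class ConfigError(ValueError):
    """Raised on inconsistent sampler configuration."""


class DegenerateDistributionError(ValueError):
    """Raised when a conditional distribution has zero total mass."""


@dataclass
class ModelConfig:
    """Sampler configuration.

    K is the number of topics (see :mod:`latentomics.topic_number` for the
    Louvain-based selection rule).  ``alpha`` and ``beta`` are symmetric
    Dirichlet concentrations unless explicit vectors are given; both
    default to 0.1, a sparse prior under which surplus topics simply stay
    empty.  ``iterations`` defaults to 5000 sweeps with the first
    ``burn_in`` = 2000 discarded before averaging: the topic distribution
    converges within 1000-2000 sweeps on corpora of this kind, so 2000 is
    a conservative cut.  ``include_imputed_in_phi`` controls whether the
    currently imputed tokens feed back into the phi counts (the default;
    set False to condition phi on observed tokens only).
    """

    K: int
    alpha: float | np.ndarray = DEFAULT_ALPHA
    beta: float | dict[str, np.ndarray] = DEFAULT_BETA
    iterations: int = DEFAULT_ITERATIONS
    burn_in: int = DEFAULT_BURN_IN
    seed: int = 0
    include_imputed_in_phi: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigError(f"K must be >= 1, got {self.K}")
        if self.iterations < 1:
            raise ConfigError("iterations must be positive")
        if not (0 <= self.burn_in < self.iterations):
            raise ConfigError(
                f"burn_in ({self.burn_in}) must be in [0, iterations="
                f"{self.iterations})"
            )

    def alpha_vector(self) -> np.ndarray:
        a = np.broadcast_to(np.asarray(self.alpha, dtype=float), (self.K,)).copy()
        if (a <= 0).any():
            raise ConfigError("alpha must be positive")
        return a

    def beta_vector(self, modality: str, V: int) -> np.ndarray:
        b = self.beta[modality] if isinstance(self.beta, dict) else self.beta
        b = np.broadcast_to(np.asarray(b, dtype=float), (V,)).copy()
        if (b <= 0).any():
            raise ConfigError("beta must be positive")
        return b


@dataclass
class SamplerState:
    """Current draws and accumulators of one Gibbs run.

    ``z_obs[m]`` / ``z_mis`` hold the topic assignment of every observed
    and imputed token; ``theta`` and ``phi[m]`` are the current
    row-stochastic draws; ``mis_w`` the current imputed vocabulary
    indices; ``freq`` counts, per vocabulary item, the post-burn-in sweeps
    in which any missing slot sampled it.
    """

    theta: np.ndarray
    phi: dict[str, np.ndarray]
    z_obs: dict[str, np.ndarray]
    z_mis: np.ndarray | None
    mis_w: np.ndarray | None
    theta_sum: np.ndarray = field(default=None)  # type: ignore[assignment]
    phi_sum: dict[str, np.ndarray] = field(default=None)  # type: ignore[assignment]
    freq: np.ndarray | None = None
    n_samples: int = 0


@dataclass
class FittedModel:
    """Posterior-mean summary of a Gibbs run (serializable)."""

    diseases: list[str]
    modalities: list[str]
    vocab: dict[str, list[str]]
    theta: np.ndarray
    phi: dict[str, np.ndarray]
    n_samples: int
    missing: tuple[str, str] | None = None
    freq: np.ndarray | None = None
    n_slots: int | None = None

    def phi_for(self, modality: str) -> np.ndarray:
        if modality not in self.phi:
            raise KeyError(f"modality {modality!r} not in fitted model")
        return self.phi[modality]


@dataclass
class ImputationResult:
    """Likeliness scores for a deliberately missing (disease, modality).

    ``likeliness[v]`` is the number of post-burn-in sweeps in which
    vocabulary item v was sampled into any missing slot, divided by the
    number of post-burn-in sweeps; with more than one slot values can
    exceed 1, and only the ranking/thresholding is consumed downstream.
    """

    disease: str
    modality: str
    vocab: list[str]
    likeliness: np.ndarray
    n_slots: int

    def to_frame(self):
        import pandas as pd

        order = np.argsort(-self.likeliness, kind="stable")
        return pd.DataFrame(
            {
                "feature": [self.vocab[i] for i in order],
                "likeliness": self.likeliness[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


# ---------------------------------------------------------------------------
# elementary sampling operations (the full conditionals)
# ---------------------------------------------------------------------------

def conditional_topic_probs(theta_d: np.ndarray, phi_col_v: np.ndarray) -> np.ndarray:
    """Topic posterior of one token: theta_dk * phi_kv, normalized over k."""
    num = np.asarray(theta_d, dtype=float) * np.asarray(phi_col_v, dtype=float)
    total = num.sum()
    if total <= 0:
        raise DegenerateDistributionError(
            "zero total mass in the token's topic conditional (degenerate phi)"
        )
    return num / total


def sample_theta(
    alpha: np.ndarray, topic_counts_d: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw theta_d ~ Dirichlet(alpha + n_dk), n pooled over all modalities."""
    return rng.dirichlet(np.asarray(alpha, float) + np.asarray(topic_counts_d, float))


def sample_phi(
    beta: np.ndarray, feature_counts_k: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw phi_k(·) ~ Dirichlet(beta_v + n_kv) for one topic of one modality."""
    return rng.dirichlet(np.asarray(beta, float) + np.asarray(feature_counts_k, float))


def sample_missing_token(phi_k: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one imputed vocabulary index from Categorical(phi_k)."""
    p = np.asarray(phi_k, dtype=float)
    return int(rng.choice(len(p), p=p / p.sum()))


def draw_missing_count(
    observed_counts: np.ndarray, V: int, rng: np.random.Generator
) -> int:
    """Number of missing-token slots for one disease/modality.

    Drawn from Binomial(V, p_hat) where p_hat is the maximum-likelihood
    per-feature labeling rate, mean(observed per-disease token count) / V
    — a disease cannot carry more distinct features than the vocabulary
    holds, so V is the natural number of trials.  Redraws until the count
    is at least 1 so the disease is scoreable.
    """
    counts = np.asarray(observed_counts, dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("cannot estimate the missing-token count: no observed tokens")
    p_hat = float(counts.mean()) / V
    p_hat = min(p_hat, 1.0)
    while True:
        n = int(rng.binomial(V, p_hat))
        if n >= 1:
            return n


# ---------------------------------------------------------------------------
# vectorised helpers
# ---------------------------------------------------------------------------

def _categorical_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of an (n, K) matrix of unnormalized
    non-negative weights."""
    cum = np.cumsum(prob_rows, axis=1)
    totals = cum[:, -1]
    if (totals <= 0).any():
        raise DegenerateDistributionError("zero total mass in a token conditional")
    u = rng.random(prob_rows.shape[0]) * totals
    return (u[:, None] >= cum).sum(axis=1).astype(np.int64)


def _dirichlet_rows(conc_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet draw per row of an (n, K) concentration matrix."""
    g = rng.standard_gamma(conc_rows)
    # gamma(a) for a ~ 0.1 can underflow to 0 on every component; re-anchor
    zero = g.sum(axis=1) == 0
    if zero.any():
        g[zero] = rng.standard_gamma(conc_rows[zero] + 1e-6)
        g[zero, 0] += 1e-300
    return g / g.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the Gibbs sweep
# ---------------------------------------------------------------------------

def run_gibbs(
    corpus: DiseaseCorpus,
    config: ModelConfig,
    missing: tuple[str, str] | None = None,
    on_sweep: Callable[[int, SamplerState], None] | None = None,
) -> tuple[FittedModel, ImputationResult | None]:
    """Fit the multi-modal topic model by uncollapsed Gibbs sampling.

    If ``missing=(disease, modality)`` is given, that disease's tokens in
    that modality are removed before fitting and replaced by imputation
    slots whose sampled contents are tallied after burn-in.

    Each sweep, in canonical order (modalities then diseases then tokens
    as stored): (1) resample every token's topic from the current theta
    and phi, (2) resample theta_d for all diseases from the pooled topic
    counts, (3) resample phi_k per modality from the feature counts,
    (4) resample each missing slot's token from its topic's phi.  Posterior
    means average the post-burn-in draws.  ``on_sweep(sweep_index, state)``
    is called after every sweep (for diagnostics).
    """
    rng = np.random.default_rng(config.seed)
    D, K = corpus.n_diseases, config.K
    alpha = config.alpha_vector()
    modalities = list(corpus.modalities)

    # flatten the token lists: per modality, token -> (disease idx, word idx)
    obs_d: dict[str, np.ndarray] = {}
    obs_w: dict[str, np.ndarray] = {}
    betas: dict[str, np.ndarray] = {}
    for m in modalities:
        d_idx = np.concatenate(
            [np.full(len(t), d, dtype=np.int64) for d, t in enumerate(corpus.tokens[m])]
        )
        w_idx = np.concatenate(corpus.tokens[m]).astype(np.int64)
        obs_d[m], obs_w[m] = d_idx, w_idx
        betas[m] = config.beta_vector(m, corpus.vocab_size(m))

    mis_modality = mis_disease_idx = None
    n_slots = 0
    if missing is not None:
        mis_disease, mis_modality = missing
        if mis_modality not in corpus.vocab:
            raise KeyError(f"modality {mis_modality!r} not in corpus")
        mis_disease_idx = corpus.disease_index(mis_disease)
        keep = obs_d[mis_modality] != mis_disease_idx
        obs_d[mis_modality] = obs_d[mis_modality][keep]
        obs_w[mis_modality] = obs_w[mis_modality][keep]
        per_disease = np.array(
            [
                len(t)
                for d, t in enumerate(corpus.tokens[mis_modality])
                if d != mis_disease_idx
            ],
            dtype=float,
        )
        n_slots = draw_missing_count(
            per_disease, corpus.vocab_size(mis_modality), rng
        )

    V = {m: corpus.vocab_size(m) for m in modalities}
    state = SamplerState(
        theta=np.full((D, K), 1.0 / K),
        phi={m: np.full((K, V[m]), 1.0 / V[m]) for m in modalities},
        z_obs={m: np.zeros(len(obs_d[m]), dtype=np.int64) for m in modalities},
        z_mis=np.zeros(n_slots, dtype=np.int64) if missing else None,
        mis_w=rng.integers(0, V[mis_modality], size=n_slots)
        if missing
        else None,
        theta_sum=np.zeros((D, K)),
        phi_sum={m: np.zeros((K, V[m])) for m in modalities},
        freq=np.zeros(V[mis_modality], dtype=np.int64) if missing else None,
    )

    for sweep in range(config.iterations):
        # (1) topic assignment of every token, observed then imputed
        for m in modalities:
            probs = state.theta[obs_d[m]] * state.phi[m][:, obs_w[m]].T
            state.z_obs[m] = _categorical_rows(probs, rng)
        if missing is not None and n_slots:
            probs = (
                state.theta[mis_disease_idx][None, :]
                * state.phi[mis_modality][:, state.mis_w].T
            )
            state.z_mis = _categorical_rows(probs, rng)

        # (2) theta from topic counts pooled over all modalities
        cnt_dk = np.zeros((D, K))
        for m in modalities:
            np.add.at(cnt_dk, (obs_d[m], state.z_obs[m]), 1.0)
        if missing is not None and n_slots:
            np.add.at(cnt_dk, (np.full(n_slots, mis_disease_idx), state.z_mis), 1.0)
        state.theta = _dirichlet_rows(alpha[None, :] + cnt_dk, rng)

        # (3) phi per modality from feature counts (imputed tokens included
        #     by default; see ModelConfig.include_imputed_in_phi)
        for m in modalities:
            cnt_kv = np.zeros((K, V[m]))
            np.add.at(cnt_kv, (state.z_obs[m], obs_w[m]), 1.0)
            if (
                config.include_imputed_in_phi
                and missing is not None
                and m == mis_modality
                and n_slots
            ):
                np.add.at(cnt_kv, (state.z_mis, state.mis_w), 1.0)
            state.phi[m] = _dirichlet_rows(betas[m][None, :] + cnt_kv, rng)

        # (4) imputed tokens from their topics' phi
        if missing is not None and n_slots:
            state.mis_w = _categorical_rows(state.phi[mis_modality][state.z_mis], rng)

        if sweep >= config.burn_in:
            state.theta_sum += state.theta
            for m in modalities:
                state.phi_sum[m] += state.phi[m]
            if missing is not None and n_slots:
                np.add.at(state.freq, state.mis_w, 1)
            state.n_samples += 1

        if on_sweep is not None:
            on_sweep(sweep, state)

    n_samp = state.n_samples
    fitted = FittedModel(
        diseases=list(corpus.diseases),
        modalities=modalities,
        vocab={m: list(corpus.vocab[m]) for m in modalities},
        theta=state.theta_sum / n_samp,
        phi={m: state.phi_sum[m] / n_samp for m in modalities},
        n_samples=n_samp,
        missing=missing,
        freq=None if missing is None else state.freq.astype(float),
        n_slots=None if missing is None else n_slots,
    )
    result = None
    if missing is not None:
        result = ImputationResult(
            disease=missing[0],
            modality=missing[1],
            vocab=list(corpus.vocab[mis_modality]),
            likeliness=state.freq / n_samp,
            n_slots=n_slots,
        )
    return fitted, result


def imputation_from_model(model: FittedModel) -> ImputationResult:
    """Rebuild the ImputationResult from a (de)serialized fitted model."""
    if model.missing is None or model.freq is None:
        raise ValueError("model was fitted without a missing (disease, modality)")
    _, modality = model.missing
    return ImputationResult(
        disease=model.missing[0],
        modality=modality,
        vocab=list(model.vocab[modality]),
        likeliness=np.asarray(model.freq) / model.n_samples,
        n_slots=int(model.n_slots or 0),
    )
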