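# Methods

## The multi-modal topic model

The model extends latent Dirichlet allocation to multi-modal
disease-omics data.  Each disease d has a single topic-weight vector
θ_d on the K-simplex; each modality (·) — AlteredExpression, Biomarker,
GeneticVariation, Microbiota, or any user-defined tag — has its own
vocabulary of size V(·) and its own topic–feature distributions
φ_k(·).  Tokens are feature occurrences: z_di(·) ~ Cat(θ_d),
w_di(·) | z=k ~ Cat(φ_k(·)).  Because θ_d is shared, the modalities are
coupled: evidence about a disease's topic profile in one modality
constrains the predicted features in every other, which is what makes
missing-modality imputation possible.  Concatenating modalities into
one vocabulary would instead average incomparable feature types
(transcripts vs microbial taxa) inside each φ.

Diseases enter the corpus only if they carry at least one feature in
*every* modality in play; each modality's vocabulary is the union of
feature identifiers over the retained diseases.  Duplicate
(disease, feature) rows collapse to one token: the source databases are
association lists, not counts.  Disease and vocabulary orderings are
lexicographic so runs are bit-reproducible across platforms.  Disease
names are merged by exact string match after normalising the
possessive ("Alzheimer's disease" → "Alzheimer disease"); an optional
synonym TSV (name → canonical id) supplies any further merging, since
general-purpose medical-terminology resources are license-gated.

## Gibbs sampling and imputation

Inference is explicit (uncollapsed) Gibbs sampling of the full
conditionals — not the collapsed sampler usual for plain LDA — because
the imputation step needs φ draws to sample missing tokens from:

* token topics:  p(z_di(·)=k | w=v) ∝ θ_dk · φ_kv(·)
* topic weights: θ_d | z ~ Dirichlet(α_k + n_dk), counts pooled over
  **all** modalities of disease d (observed and imputed tokens alike)
* feature distributions: φ_k(·) | z,w ~ Dirichlet(β_v + n_kv(·))
* missing tokens: w′_di(·) | z=k ~ Cat(φ_k(·))

Defaults: α = β = 0.1 (sparse priors; surplus topics simply stay
empty), 5000 sweeps with a 2000-sweep burn-in.  The topic distribution
converges within 1000–2000 sweeps on corpora of this kind, so 2000 is a
conservative cut; both are configurable, and the scaled-down runs used
by the tests and the acceptance script (1500 sweeps, 500 burn-in, on
60-disease corpora) sit safely past convergence for those sizes.
θ and φ are initialized uniform; missing tokens are initialized by
uniform draws.  Posterior means average the post-burn-in draws.

The number of imputation slots for a removed (disease, modality) is
drawn once at initialization from Binomial(V, p̂) and held fixed, with
p̂ = (mean observed per-disease token count in that modality)/V — the
maximum-likelihood per-feature labeling rate with the number of trials
pinned to V, since a disease cannot carry more distinct features than
the vocabulary holds (a binomial with both parameters free has no
stable MLE).  The draw is redrawn until ≥ 1 so the probe is scoreable.

Imputed tokens feed back into the φ counts by default (the conditional
for φ sums over all tokens without excluding imputed ones);
`ModelConfig(include_imputed_in_phi=False)` exposes the alternative.

The *likeliness* of vocabulary item v is the number of post-burn-in
sweeps in which any missing slot sampled v, divided by the number of
post-burn-in sweeps.  With s slots the values live in [0, s] and can
exceed 1; only their ranking and thresholding are consumed downstream.

Sweep order is canonical (modalities, then diseases, then tokens, in
corpus order) and all randomness flows from one seeded generator, so a
fixed seed reproduces every counter exactly.  The sampler is fully
vectorised (flat token arrays per modality; categorical draws by
row-wise cumulative sums; Dirichlet draws by row-wise gammas) — a
1500-sweep fit of a 60-disease, three-modality corpus takes well under
a second on one CPU.

## Topic-number selection

For each modality an undirected disease–disease graph is built with an
edge wherever two diseases share ≥ 1 feature, weighted by the shared
count.  Weighted Louvain modularity optimization (resolution 1.0) runs
20 times with distinct seeds; the modal community count is taken per
modality and K is the maximum over modalities.  Mode ties break toward
the larger count: overshooting K is benign under the sparse topic prior,
collapsing distinct clusters is not.  Isolated diseases count as
singleton communities; a completely edgeless graph returns the node
count with a warning.

## Evaluation and thresholding

A leave-one-modality-out probe removes one modality of one disease
(all other diseases keep everything), refits, and scores every
vocabulary item by likeliness against the binary label "was this
feature recorded for the disease".  AUC is computed with scikit-learn's
`roc_auc_score` (equal to the tie-corrected Mann–Whitney statistic);
the Youden cut-off is the ROC threshold maximizing TPR − FPR, ties
broken toward the highest threshold (the most conservative positive
set), with thresholds restricted to actual score values.  Probes whose
label vector is one-class (a disease carrying the entire vocabulary)
are reported as flagged rows, not failures.

## Latent features and latent disease similarity

Three filters, in order: (1) keep likeliness ≥ Youden cut-off;
(2) drop features already recorded for the disease in that modality;
(3) drop features *derived from* apparently related diseases — a
feature is removed as soon as **any** carrying disease matches the
name-pattern list (strict rule; `carrier_rule="all"` gives the lenient
variant).  Patterns are case-insensitive substrings; the `**` wildcard
notation of the shipped cardiovascular/renal list reduces to substring
matching.  Every retained feature therefore has at least one
non-matching carrier, and the latent-similarity table — per training
disease, the count of latent features it carries, descending, ties
broken by name — sums to the total carrier multiplicity by
construction.

The enrichment operation is a generic 2×2 chi-square test of
independence per category over any feature → category annotation table
(organ/cell expression classes being the motivating case), with Yates
continuity correction and Benjamini–Hochberg q-values across the tested
categories.  The background universe is an explicit argument, never
inferred.  A category absent from the background is skipped with a
warning; margins that force independence (features = background, or a
category covering the whole background) yield p = 1 rows.

## Path classifier

Paths are simple (node-repetition-free) walks from a drug-target node
to any outdegree-0 node, enumerated depth-first in sorted-neighbor
order with caps `max_len = 30` and `max_paths = 10⁴` — pathway graphs
contain cycles, so unbounded enumeration would not terminate.  Paths
inherit the TI/SE labels of the drugs targeting their start node.

Pairwise relatedness is `1 − EditDistance/max(len)`, with the unit-cost
Levenshtein distance over component identifiers computed by dynamic
programming (inner rows vectorised with a prefix-min scan).

**Method A** builds the similarity matrix between the paths under
consideration and the labeled reference paths (those whose start node
carries the TI/SE), then reduces it by PCA (column-mean centering, no
scaling — similarities share a [0,1] scale) keeping the smallest
component count reaching 99% cumulative explained variance.  One
numerical subtlety: because the reference paths are themselves training
paths, every training positive's feature row contains a similarity of
exactly 1 to itself — a spike a prediction-time query never exhibits.
Left in place, the spikes smear across all principal components and
gradient boosting keys on them, collapsing holdout accuracy.  Self
matches are therefore replaced by the row's best similarity to a
*different* reference (the nearest-labeled-neighbour value the feature
is meant to carry) before the PCA.  Raw-column Method B features are
empirically robust to the spike (isolating one sample in one column has
too little gain for a regularized tree split) and are left as plain
similarities.

**Method B** clusters each drug target's paths by the shape of their
similarity profile against all paths: Pearson correlations of the
profile rows, distance 1 − r, average-linkage hierarchical clustering
cut at distance 0.2 (paths with constant profiles have undefined
correlations and become singleton clusters, with a warning).  Each
labeled path is keyed by its (start node, cluster) pair; with n
distinct pairs, each pair's paths are down-sampled to at most ⌈500/n⌉
by seeded uniform sampling.  Features are the raw similarities to the
sampled reference set.

**Training**: a stratified 9:1 path-level holdout is split off first;
the feature recipe is frozen on the training side; each of ten models
receives an independent 1:1 under-sample (minority class kept whole)
and a LightGBM fit.  Hyperparameters are chosen once from a small fixed
grid by accuracy on a 20% slice of the first balanced sample, with
deterministic single-threaded boosting throughout.  **Prediction**
follows the voting rule exactly: a path is positive when ≥ 6 of the 10
models score it ≥ 0.5; the per-path vote fraction is also returned.

Reported holdout metrics (accuracy, precision, recall, F1) average the
ten models' own class predictions (strict p > 0.5, i.e. each model's
argmax); the voted verdict's metrics are reported alongside under
`voted_*` keys.  The distinction matters at the null: on data with no
label signal every model outputs ≈ 0.5, the inclusive ≥ 0.5 vote then
calls nearly everything positive and the voted F1 converges to 2/3
regardless of model quality, whereas the per-model F1 sits at the
chance level ≈ 0.5 that a holdout estimate should show.

## Synthetic data

The corpus generator draws from the model's own generative process.
Defaults — 60 diseases, three modalities of 50 features, K_true = 3,
α_gen = β_gen = 0.1, 5–15 recorded features per disease per modality —
mimic a small but structured multi-omics panel in which most diseases
are nearly single-topic, as real disease–gene profiles are.  Each
topic's feature distribution blends a Dirichlet draw restricted to the
topic's own vocabulary block with a uniform background,

    φ*_k = separation · Dir_block_k + (1 − separation)/V,

so `separation = 1` gives disjoint per-topic vocabularies and
`separation = 0` collapses every topic to the uniform distribution — a
corpus with no recoverable structure, where imputation can do no better
than chance.  The uniform background is essential for the null: a
skewed but topic-shared distribution would still let the model predict
globally frequent features (measured mean AUC ≈ 0.85 even with
identical topics).  The default `separation = 0.95` makes ~5% of
recorded associations background noise, roughly the residual
unpredictability real association databases exhibit; an ideal scorer
knowing the true parameters reaches mean leave-one-modality-out AUC
≈ 0.93 under these defaults, and the fitted sampler tracks that ceiling
within ~0.05.  Token counts per disease are uniform in the given range;
real association counts are heavy-tailed, so recovery numbers here are
cleaner than real-data ones would be — passing tests demonstrate
correctness of the machinery, not real-database performance.  Drawn
duplicate tokens collapse to their support, matching the
association-list reading of the corpus.

The hidden-twin fixture plants a latent disease similarity directly:
target and twin sit in the same topic block, but in the held-out
modality the target records only a small slice of the block while the
twin records nearly all of it, so the features the target is missing
are carried (almost) exclusively by the twin.  A decoy disease with a
pattern-matching cardiovascular name is the sole carrier of one planted
feature, which the related-disease filter must remove.

The pathway generator plants label ↔ motif associations: each drug
targets one node and carries one of the labels; a path from a drug's
target ends in its label's motif chain with probability 1 − noise_rate
and in another label's motif otherwise, so `noise_rate = 0.5` with two
labels carries no motif signal at all.  Fillers between target and
motif are unique per path, keeping extraction exact, and a back-edge
per target plants a cycle to exercise the simple-path rule.  The
default is one path per target over 200 targets: labels attach to
targets, so with several paths per start the start-node identity alone
predicts the label across a path-level holdout split; one path per
target keeps the planted motif the only cross-path signal, which the
null fixture must guarantee.

The annotation generator assigns features to categories at a base rate
with one optionally boosted (category, fold) pair among a designated
feature subset; fold = 1 is the null table.

## Numerical choices and degenerate inputs

* Dirichlet draws use row-wise gamma variates; rows whose gammas all
  underflow (possible at concentration ≈ 0.1) are redrawn with a tiny
  offset rather than producing NaNs.
* Categorical draws compare a uniform variate against row-wise
  cumulative sums; a zero-mass conditional raises rather than silently
  renormalising.
* Youden ties break toward the highest threshold; score ties use
  threshold-set semantics (a threshold admits every item scoring ≥ t).
* Model state serializes to JSON; floats round-trip exactly through
  their decimal representation, and a format-version field guards
  against incompatible files.
* Per-probe sampler seeds in batch evaluation derive from the base seed
  via `numpy` seed sequences, so tables are reproducible while probes
  stay independent.

## Known limitations

* Corpus operations hold everything in memory; corpora of ~10⁴
  diseases and ~10⁴-feature vocabularies are comfortable, but the
  similarity matrix of the path classifier is quadratic in path count.
* The classifier treats labels independently (one ensemble per TI/SE);
  no multi-label coupling, and no modeling of off-target effects.
* No variational inference, collapsed sampling, or hyperparameter
  optimization of α/β; K comes solely from the Louvain rule.
* Live database clients (DisGeNET, Disbiome, KEGG, DrugBank, SIDER) are
  out of scope: the readers consume the joined long-format TSV dialects
  the synthetic generators also write, which double as format
  documentation.
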