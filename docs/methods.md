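# Methods

This note records the models implemented, the defaults and why, what the
synthetic data does and does not emulate, and the choices made where the
design was genuinely open.

## De-skewing by profile-entropy minimization

A scanned page is modeled as a binary raster (0 = ink, 1 = background),
origin top-left. For a candidate rotation α the row profile is the black
fraction per pixel row of the rotated raster, and the page entropy is
H = −Σ P ln P over rows whose fraction is at least 0.10. The 10 % floor
matters: −P ln P *increases* on [0, 1/e), so faint rows — scanner pepper
noise, band edges — would otherwise dominate the sum, while genuine text
rows carry well above 10 % ink. The corrective angle is the grid minimizer
of H.

Choices the formulation leaves open, fixed here:

- **Log base**: natural log. Any base rescales H by a constant and leaves
  the argmin unchanged.
- **Grid**: coarse pass over ±20° at 1°, then a ±1° refinement at 0.1°
  around the coarse optimum. Ties break toward the smallest |α|, then
  toward the negative angle, so the estimator is deterministic.
- **Resampling**: nearest-neighbour for binary images (the raster stays
  {0, 1}), bilinear for grayscale; uncovered borders fill with background
  white. The profile is computed on the full rotated raster, without
  cropping rotation borders.
- **Binarization**: global Otsu by default, explicit threshold accepted.
- A blank page has no defined skew; the estimator returns 0° with a
  warning rather than an arbitrary grid point.

The synthetic form generator uses the *same* rotation primitive, so angle
recovery is tested without any convention mismatch: on 100 seeded forms with
1 % salt-and-pepper noise and true angles up to ±15°, the estimate lands
within twice the coarse step of the truth in at least 95 cases (the suite
runs this exact experiment).

## De-identification

Semi-structured referral forms keep personal information above a full-width
separator line. The detector convolves the page with the 3×3 Sobel kernel
pair (edge-replicated borders), sums gradient magnitude per row within the
top fraction of the page (default: top half), and returns the row of maximal
energy; ties go to the smaller row index. If no row reaches a configurable
multiple of the mean row energy (default 2×) the marker is declared absent
and the caller must supply a manual region — mirroring practice for
unstructured forms, where regions are manually specified. Redaction paints
the half-open rectangle black and is idempotent; pixels outside the region
are preserved bit-exactly.

## Lexical features

Tokenization lowercases, splits on every non-alphabetic character, and drops
stop words. The package ships a standard list of 174 common English function
words as its default and accepts any user-supplied list. Term frequency is
the raw in-document count (no length normalization); inverse document
frequency is ln(N/(1+df)) with the +1 smoothing kept exactly, which makes
idf *negative* for a term present in every training document — a real
property of this weighting that the tests assert rather than clip. The
n-gram family is bigrams plus trigrams in one matrix. Vocabularies keep
every term seen in training with no frequency cutoff, are ordered
lexicographically, and are always fitted on training folds only; test
documents are projected onto them, so no test vocabulary leaks into
training features.

## Topic model

LDA is fitted by collapsed Gibbs sampling — simple, exact in the limit, and
deterministic given a seed. Symmetric priors default to α = 50/T and
β = 0.01 (the common Griffiths–Steyvers settings). Count tables conserve the
corpus token count after every sweep; the suite checks this and the recovery
of planted topics (matched cosine ≥ 0.95 on a two-topic corpus with
well-separated vocabularies after 500 sweeps).

Embedding a document is ambiguous when described as "normalizing word
vectors by the word–topic probabilities"; both readings are provided:

- `word-avg` (default): L1-normalized mean of the document's words'
  posterior rows P(t|w) — the literal reading;
- `doc-posterior`: smoothed topic proportions from per-token hard
  assignments, the more common document-level reading.

Out-of-vocabulary tokens are skipped; an all-OOV document maps to the
uniform simplex point.

## Distributed representations

Word vectors are trained with CBoW and documents with PV-DM: the 2c context
word vectors (order-preserving, **concatenated**, not averaged) plus the
document's paragraph vector form the context representation h, scores are
y = W_out·h, and the objective is the average log-probability of the target
word under a full softmax. The full softmax is exact and tractable at
clinical-corpus vocabulary sizes; no hierarchical softmax or negative
sampling is used. Window positions that run off a document edge are padded
with a zero block. Defaults: window c = 5, initial learning rate 0.025 with
linear decay, 50 epochs; uniform(±0.5/dim) initialization. Gradients are
verified against central finite differences (< 1e-4 relative error).

Held-out documents receive vectors by gradient ascent on a *fresh* paragraph
vector with the word matrices frozen. This is the leakage-safe protocol:
whether the original study trained embeddings on all documents including
test folds is not documented, and fold-safe inference is the defensible
default. Per-epoch average log-probability is recorded during the epoch
(i.e. with parameters as of each step), which is the usual online
approximation of the objective trace.

## Upsampling

For each positive sample its k nearest positive neighbours are found
(Euclidean distance, self excluded, distance ties to the smaller index), and
`n_per_positive` artificial points are drawn per sample as
x + u·(neighbour − x), u ~ Uniform(0, 1), with the neighbour chosen
uniformly among the k. Defaults n_per_positive = 2 and k = 2: two artificial
samples per positive takes a 56:143 class ratio to 168:143, and k is matched
to n_per_positive since the method statement speaks of "nearest neighbours"
in the plural without fixing k. Artificial rows are always labeled positive,
lie on segments inside the positives' convex hull, and are generated inside
training splits only — inner as well as outer — so no artificial row is
ever scored. No feature standardization precedes upsampling (none is part
of the pipeline).

## Classifier and solver

The squared hinge max(0, 1−y·wᵀx)² is convex and continuously
differentiable, so both objectives are solved by monotone proximal gradient
descent: FISTA acceleration with backtracking line search, a monotonicity
safeguard (the incumbent is kept whenever the accelerated candidate is
worse, with a momentum restart), and the soft-threshold proximal map for the
L1 term. The iterate path is non-increasing in objective by construction.
On random small instances the solver matches an independent L-BFGS-B
reference (L1 handled by the exact split w = u − v, u, v ≥ 0) to well below
the 1e-3 relative gap the suite demands. A bias is handled by appending a
constant-1 feature, regularized with the rest. Penalty routing follows the
feature family: L1 for lexical matrices, L2 for LDA/doc2vec, carried by a
`penalty_hint` on each feature matrix. Prediction is sign(wᵀx) with the tie
at 0 resolved positive — the recall-favouring direction.

## Evaluation protocol

Stratified 7-fold outer cross-validation estimates performance; stratified
5-fold cross-validation inside each outer training split selects C from
{2⁻⁵, 2⁻³, …, 2⁵} by mean inner F2, ties to the smaller C. Headline metrics
pool confusion counts over outer folds (per-fold metrics are also emitted).
The report records fold assignments, and the suite audits that each document
is scored exactly once. F2 = 5PR/(4P+R) is 0 when 4P+R = 0.

## Synthetic data: what it emulates, and what it does not

The form generator renders n dark bands (one of them the full-width
separator line, one a personal-information band above it) on a white page,
rotates by a known angle with the same primitive the de-skewer inverts, and
flips pixels with a small symmetric salt-and-pepper probability. It does
*not* render handwriting, form typography, or non-rigid distortion —
distortion is exactly what entropy de-skewing cannot correct, and it remains
out of scope here as well.

The corpus generator plants a recoverable structure: shared topic–word
distributions drawn from a sparse Dirichlet, class separation obtained by
down-weighting the opposite class's half of the vocabulary by
exp(−divergence), per-document topic mixtures from a symmetric Dirichlet(1),
Poisson document lengths, i.i.d. topic-then-word token sampling. Divergence
0 makes documents label-independent; large divergence gives effectively
disjoint class vocabularies. Defaults are the study conditions where stated
— 56 positive and 143 negative documents — and otherwise values a small
clinical corpus makes plausible: vocabulary 60, mean length 80 tokens,
2 latent topics, divergence 4.0 (well-separated but not disjoint classes).

Consequently, passing tests show that the *methods* are implemented
correctly and behave as designed under known generative structure. They do
not show that real clinical language is this separable: synthetic i.i.d.
topic text carries none of the OCR noise, spelling variation, or semantic
subtlety of transcribed medical forms, and pooled scores on it are
correspondingly higher than any figure one should expect on real data.
Quantities that depend on the confidential 199-patient corpus (per-table
precision/recall values, the published feature counts, the number of
non-zero L1 weights) are treated as worked-example inputs, not as
reproduction targets.

## Problem sizes used by the default suite

The heavier checks run at sizes chosen to exercise the methods while keeping
the suite brisk on one CPU: 100 forms of 240×320 px for angle recovery; a
40-document, 40-word-vocabulary corpus with 500 Gibbs sweeps for topic
recovery; 199 documents with 32-dimensional paragraph vectors, window 2 and
12 epochs (fitted per outer fold, 7 times, with 20-step held-out inference)
for the end-to-end upsampling comparison; 20 random instances per penalty
for solver optimality. Defaults in the library itself (dim 150, window 5,
50 epochs, C grid 2⁻⁵…2⁵) remain the study-scale settings.

## Known limitations

- The Gibbs sampler and the SGD loops are pure Python/NumPy; they are sized
  for small corpora, not for large-scale training.
- `doc-posterior` embeddings for unseen documents use hard per-token
  assignments rather than a proper unseen-document Gibbs pass.
- The de-skewer assumes rigid rotation; warped pages keep their distortion.
- The marker detector assumes the strongest horizontal edge in the searched
  band *is* the separator; pages violating that need a manual mask.
- The upsampler densifies sparse matrices; at the intended corpus sizes
  (hundreds of documents) this is immaterial.
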