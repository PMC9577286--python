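# Methods

## Model

### Vocabulary and partition

The working lexicon is the intersection of the words that have a textual
embedding, a concreteness rating (1 = abstract … 5 = concrete), and visual
data — either a precomputed visual vector or at least `min_images`
per-image feature vectors (default 20, matching the standard
20-images-per-word retrieval setting). A word is **abstract** iff its
rating is strictly below the threshold θ_c; the representative operating
points are θ_c = 3.0 and θ_c = 4.0, and sweeps cover 1.5–5.0 in steps
of 0.1.

### Direct and indirect visual vectors

The direct visual vector v(w) is the centroid of the word's per-image
feature vectors (in real data: final-hidden-layer activations of a deep
convolutional network, 2048-dimensional). The grounded vector is

- g(w) = v(w) for concrete w;
- g(w) = mean of v(u) over u ∈ SN_k(w) for abstract w;
- no vector (textual-only) when SN_k(w) = ∅.

SN_k(w) is computed in two stages on textual cosine similarity: first the
N most similar words overall (the candidate pool, default N = 300), then
the k most similar concrete words within that pool (default k = 10). The
pool stage is essential, not an optimization: it lets highly abstract
words whose neighborhoods contain no concrete word end up with *no* visual
vector rather than being forced onto semantically distant images. N and
k = 10 < N are validated at construction.

Numerical conventions, chosen where the mathematical definition is silent:

- **Ties** in cosine are broken by descending cosine, then lexicographic
  word order, so neighbor lists are identical across platforms.
- **Zero-norm textual vectors** have no defined cosine; such words are
  never selected as neighbors, and as queries they yield SN = ∅.
- **Fewer than k concrete words** in the pool: the average is taken over
  the m < k neighbors actually found (divide by m). Dividing by k would
  shrink the vector toward zero by an arbitrary factor tied to pool
  composition, which contradicts the construction's intent of *averaging*
  neighbor content.

### Model variants

Six variants define per-word predictor inputs: `indirect_grounding`
(t, g), `hybrid` (t, v), `dual_coding` (t, v) for concrete and (t, —) for
abstract, `visual` (—, v), `textual` (t, —), `indirect_visual` (—, g).
Textual-only words under the grounded variants degrade to (t, —); under
`indirect_visual`, which has no textual fallback, they are an error.

Two consequences worth stating because tests rely on them exactly:
with θ_c at or below the minimum rating, g ≡ v vector-for-vector, so the
indirect-grounding and hybrid pipelines are *identical* end to end (fold
seeds never depend on the variant); with θ_c above the maximum rating,
V_C = ∅, every word is textual-only, and the indirect-grounding pipeline
collapses onto the textual one.

## Predictor

A feed-forward network with two input branches — textual
d_text→d_text_hidden and visual d_vis→d_vis_hidden, both ReLU — whose
concatenation feeds a linear output layer of d_out norm attributes.
Reference defaults: 300→150 and 2048→150 hidden units, d_out = 65.
Norm values live on a bounded scale (0–6), so the output is linear
rather than a saturating nonlinearity. `d_text_hidden` is configurable
to reproduce the textual-compression experiment (e.g. reducing it to 30
equalizes the two branches' compression rates).

Training minimizes mean squared error with Adam: learning rate 0.001,
β₁ = 0.9, β₂ = 0.999, ε = 1e-8, minibatches of 32 reshuffled per epoch
from a seeded generator, no weight decay, no early stopping — epoch
counts are fixed per variant by the reference grid search (hybrid 19,
dual coding 17, textual 17, visual 10, indirect grounding 20, indirect
visual 16; `VARIANT_EPOCHS`). Weights use Glorot normalized
initialization, U(±√(6/(fan_in+fan_out))); the output bias starts at
zero. Inputs are consumed as-is (no standardization).

**Modality masking.** An absent modality is fed as a zero vector, and the
branch hidden layers deliberately have **no bias terms** (only the output
layer has a bias). This single design choice makes the masking contract
exact in every training state: a zero input produces an exactly-zero
branch activation (zero contribution at the merge point) and exactly-zero
gradients for all of that branch's parameters — input weights see a zero
input, output-layer columns see a zero activation, and there is no hidden
bias to pick up gradient. Under Adam, zero gradients give zero updates,
so training exclusively on masked items leaves the branch bit-identical
to its initialization, and `predict(visual=None)` is literally the same
computation as predicting with an explicit all-zeros visual vector. With
hidden biases these two guarantees conflict as soon as a bias trains away
from zero (ReLU(b) ≠ 0); removing them costs a small amount of
expressiveness and buys an exact, testable contract.

## Evaluation

### Clusters and cross-validation

Words in featural-norm datasets are not uniformly spread in semantic
space, so random folds would reward words with many close neighbors in
training. Evaluation therefore uses **leave-one-cluster-out** CV:
k-means (k = 20) on the textual vectors, 100 restarts scored by the
**Dunn index** (minimum between-cluster distance over maximum cluster
diameter; all-singleton clusterings score +∞ and rank above any finite
value; ties go to the first restart), best restart kept; the whole
procedure repeated 10 times for 10 independent cluster sets. k-means is
Euclidean on raw vectors, 300 iterations max, tolerance 1e-6, one
initialization per restart so the Dunn index — not inertia — performs
the model selection.

For each cluster set and variant, each cluster is held out in turn, the
network trained from scratch on the rest, and the held-out words
predicted, so every word is predicted exactly once. The pass is repeated
3 times with fresh seeds; the run with the highest mean Pearson r across
all words is retained. Per-word scores are then averaged across the 10
cluster sets, and statistics are computed on those averaged scores.
Per-word scoring: Pearson r between predicted and target norm vectors
(Spearman ρ with average ranks, and MSE, as secondary measures);
zero-variance vectors make the correlations undefined and return NaN.

### Model comparison

The omnibus test is the tie-corrected Friedman chi-square, implemented
directly from its closed form (12/(nk(k+1)) · ΣR² − 3n(k+1), divided by
the tie-correction factor) so it also covers the two-model case; it is
cross-checked against an independent library implementation in the test
suite. Pairwise comparisons use the Wilcoxon signed-rank test (zero
differences dropped; exact distribution up to n = 25 without ties,
normal approximation with tie correction otherwise) under familywise
control at α = 0.05. The default multiplicity procedure is **Holm**
step-down over all pairwise p-values — formula-unambiguous and FWER
controlling. A **Ryan-style stepwise procedure** is available as an
option: pairs spanning s positions in the ordering of model means are
tested at nominal level 2α/(k(s−1)), widest spans first, and a retained
non-significant span blocks all pairs nested inside it. The two agree on
clear-cut patterns; the qualitative decision pattern, not a particular
adjusted α, is the scientific surface.

### Threshold sweep and diff(r)

The sweep rebuilds the partition and grounded space and reruns the CV at
each θ_c on a grid (1.5–5.0, step 0.1 → 36 rows), recording abstract /
concrete counts, per-variant mean r over abstract, concrete and all
words, and pairwise significance flags on abstract-word scores. The
diff(r) analysis localizes where indirect grounding helps:
diff(r) = r_indirect − r_baseline per word, its Pearson correlation with
concreteness (NaN sentinel when diff(r) has zero variance, e.g.
identical models), mean diff(r) per equal-width concreteness interval
(default width 0.25) with word counts, mean diff(r) per semantic
category restricted to categories with ≥ 4 words, and per-word
correlation-versus-θ curves.

## Synthetic worlds

The generator emulates the statistical situation the model addresses
without any external corpus, image set or rating norm. Per word, a latent
semantic vector z(w) ~ N(0, I_m); textual vectors t = A z + ε_text and
per-image features B(content) + ε_vis, with A and B random
**orthonormal-row** projections (scaled for unit-variance components).
Orthonormal rows preserve inner products exactly at zero noise, so the
latent-space and textual-space neighborhoods coincide in the noiseless
limit — which makes the recovery property "the indirect vector of an
abstract word matches its true grounded content" exact rather than
approximate, and leaves noise as the only (realistic) source of
neighborhood discrepancy.

Image content is the word's own z for concrete words and the mixture
ρ·z + (1−ρ)·u, u an independent draw, for abstract words: the
**tag-reliability knob ρ** makes an abstract word's own images
informative (ρ = 1) or pure noise about it (ρ = 0). The true grounded
content v*(w) is B z for concrete words and the mean of B z over the
word's nearest concrete latent-space neighbors (by cosine, default 10)
for abstract words. Norms are y = C z + scale·D v* + ε_out, with the
scale set so the grounded component carries 40% of the noise-free norm
variance — large enough that visual information measurably helps —
then affinely rescaled per attribute into [0, 6].

Defaults are desk-scale and define the simulation conditions: 500 words,
30% abstract, m = 8, d_text = 32, d_vis = 48, d_out = 16, 5 images per
word, noise sd 0.1 on all channels against unit-variance signal,
concrete ratings uniform on [3.5, 5] and abstract on [1, 2.5] (the gap
around θ_c = 3.0 keeps partition recovery out of the way of what is
being tested). The evaluation network for these worlds uses 16/16 hidden
units and 30 epochs for all variants; the regime experiment uses one
cluster set of 20 clusters selected from 20 restarts, 3 runs per
condition, 5 world seeds per regime — sizes chosen so a full two-regime
experiment runs in minutes on one CPU while preserving the statistical
structure.

What the worlds deliberately do **not** emulate: corpus text and its
frequency effects, real image statistics, rating-collection noise,
polysemy, and the absolute correlation levels of real norm datasets.
Passing the regime-discrimination test shows the pipeline recovers the
built-in grounding structure under the stated generative assumptions; it
does not by itself certify behavior on real embeddings and images.

## Known limitations

- The predictor's post-merge architecture (single linear layer after
  concatenation) is one reasonable reading of a two-branch design whose
  deeper structure is not fully pinned down; it is a declared stand-in,
  configurable in width but not in depth.
- Whether reference training was full-batch or minibatch is unknown;
  minibatch 32 is assumed.
- The exact span-adjusted formula behind "Ryan's procedure" varies across
  the literature; both the implemented stepwise version and Holm are
  documented above, and Holm is the default.
- Absolute correlation levels from real resources (COCA-trained
  embeddings, Flickr/ResNet features, Binder-style norms, Brysbaert-style
  ratings) are out of scope; the package evaluates structure, identities
  and simulation-recoverable contrasts.
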