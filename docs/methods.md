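# Methods

`planttf` identifies plant transcription factors (TFs) and assigns them to
families from protein sequence alone. The design follows a one-vs-rest
ensemble recipe: k-mer frequency encoding, univariate feature selection, one
binary feed-forward classifier per family, and a final voting stage — either
a simple max vote over the per-family probabilities or a two-stage stacking
meta-classifier — with a confidence threshold that rejects low-scoring
sequences as `unknown`. This note records the model, the defaults, and the
design decisions that were genuinely open, together with what the synthetic
benchmark does and does not demonstrate.

## Sequence representation

Each validated protein sequence is slid over with a window of length k
(supported k = 1–5, default 3). A window is *valid* when all of its residues
are among the 20 standard amino acids; the feature value of a k-mer is its
count among valid windows divided by the number of valid windows, so a clean
sequence of length L contributes L − k + 1 windows and its feature vector
sums to exactly 1. Sequences shorter than k yield an all-zero vector and a
warning. The vocabulary is the full lexicographic enumeration of the 20^k
k-mers over `ACDEFGHIKLMNPQRSTVWY` (400 for k = 2, 8 000 for k = 3, 160 000
for k = 4, 3.2 million for k = 5). The ordering is part of the persisted
model metadata, so masks and weights remain aligned across machines. For
k ≥ 4 the full matrix is assembled in CSR sparse form and only the masked
sub-matrix is densified; the k = 5 vocabulary's k-mer list is materialized
lazily and index lookup is arithmetic (base-20), so no multi-million-entry
hash map is ever built.

Normalizing by the number of valid windows (rather than, say, raw counts or
a fixed-length denominator) makes the embedding length-invariant, which is
the point of a fixed-width representation for proteins ranging from under a
hundred to several thousand residues.

## Feature selection

A single feature mask per k is computed on the training split by one-way
ANOVA: for every k-mer, F = between-family mean square / within-family mean
square, with the multi-class family label as the grouping factor. Unlabeled
(non-TF background) rows never enter the mask computation. Constant features
score 0; ties at the selection cutoff break toward the smaller vocabulary
index so the mask is deterministic. Defaults retain the 200 best features
for k = 2 and the 1 000 best for k = 3–5, overridable via `--features`.
The grouping is deliberately global (all families at once) rather than per
binary subset: one mask per k is what the persisted model bundle loads at
inference, and a shared input space is what lets the per-family outputs feed
a single meta-classifier.

## Input scaling

The classifier input for each masked k-mer is its binary presence indicator,
z-scored with training-split statistics (persisted beside the mask as
`scaler.json`). Two observations motivate this. First, a motif k-mer present
once in a sequence of length L contributes ≈ 1/L to the frequency vector, so
the identical biological signal varies several-fold across the 80–300+
residue range, whereas what separates families is overwhelmingly *which*
selected k-mers occur at all; the indicator removes the length dependence
entirely. Second, raw frequencies are of order 10⁻³, far below the unit
scale that standard network initialization assumes; z-scoring puts the
inputs there. Zero-variance columns pass through unscaled. The frequency
matrix itself (used for feature selection and available for export) retains
the relative-frequency values.

## Balanced binary subsets

For each family, a balanced training subset labels all of its training-split
members class 1 and draws an equal number of class-0 sequences from the
remaining families, proportionally to their sizes, without replacement.
Quotas use largest-remainder (Hamilton) rounding, which sums exactly to the
positive count and keeps every donor within one sequence of its real-valued
share. Negatives are drawn from the training split only, so test sequences
never influence training. Each (family, seed) pair has its own derived RNG
stream — adding or removing one family does not reshuffle the others'
draws. If a family outnumbers all others combined, all others become
negatives and the positives are down-sampled to match (with a warning).

## Classifiers

Base learners and the stacker share one architecture: four fully connected
hidden layers of 256, 128, 64 and 32 units, ReLU activations, 0.5 dropout
after every hidden layer. Base learners end in a single sigmoid unit trained
with binary cross-entropy; the stacker ends in a softmax over the family set
trained with multi-class cross-entropy, its input being the vector of all
base-learner probabilities. Both are optimized with Adam (learning rate
1e-3, default β and ε) in mini-batches of 64. The implementation is plain
numpy (He initialization, inverted dropout, explicit backward pass); a given
seed reproduces training bit for bit on one thread.

Schedule. Family subsets span two orders of magnitude in size, so epoch
counts are a poor budget unit: a 32-row subset sees one optimizer update per
epoch where a 640-row subset sees ten. The epoch budget and early-stopping
patience are therefore floored in *updates* — by default at least 12 000
updates, patience at least 3 000 — with `max_epochs=100`/`patience=10`
acting as the floor for large subsets. Early stopping monitors a validation
set and restores the best weights.

Validation composition. At inference every binary classifier scores every
sequence, not just a balanced sample, so validating on the balanced subset
alone rewards models that fire on out-of-family sequences they never saw.
The validation set therefore combines a stratified 10% of the subset with a
4× sample of training sequences from outside the subset (labeled 0), and the
validation loss weights the two classes equally so the enriched negatives do
not drown the positives.

Input jitter. With as few as 16 positive examples against 1 000 features, a
network this size memorizes single spurious features. Gaussian noise added
to the standardized training inputs (σ = 2.5 by default for base learners)
is a data-space regularizer that forces the decision onto the redundant
motif signal — a family's conserved domain spans several overlapping k-mers,
and noise makes any single one unreliable. For the stacker, whose inputs are
probabilities in [0, 1], the jitter scale is drawn per row from U(0, 0.4)
(noise-level randomization), exposing the meta-net to both crisp and fuzzy
probability vectors.

Stacker averaging. The final two-stage scorer is the softmax average of
three identically configured stacker networks trained from different
derived seeds. A single meta-net's behavior outside its training manifold —
notably on non-TF sequences, where every base learner is quiet — varies
erratically with initialization and is occasionally overconfident; averaging
a few seeds preserves confident agreement on real members while damping
spurious certainty elsewhere. Set `n_stackers=1` for a single net.

## Voting and open-set rejection

`max_vote` takes the argmax over the raw per-family sigmoid outputs; they
are deliberately *not* renormalized across families, since each is an
independent one-vs-rest probability. `two_stage` takes the argmax over the
stacker's normalized scores. In both cases the winning probability must
reach the confidence threshold (comparison is ≥, so a probability exactly at
the threshold is accepted); otherwise the sequence is labeled `unknown`.
Exact ties break toward the lower family index in canonical (first
appearance) order. Defaults: two-stage voting, threshold 0.5, k = 3. Raising
the threshold toward 0.95–0.99 turns the classifier into a TF detector:
non-TF input is increasingly rejected at the cost of rejecting some true
family members, which is the intended operating mode for whole-proteome
screening.

## Evaluation

Metrics are one-vs-rest per family: accuracy (TP+TN)/(TP+TN+FP+FN),
precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R), aggregated three
ways: micro (globally summed counts), macro (unweighted mean over families
with at least one true member), weighted (class-size weighted mean). An
`unknown` prediction counts as an error — a false negative for the true
family and a true negative elsewhere — so micro accuracy falls as the
threshold rises; this is the accounting under which a threshold sweep is
monotone. In single-label evaluation without rejections, micro precision,
recall and F1 all equal accuracy (a counting identity); they are reported
anyway so the metric grid is complete. 0/0 precision or recall is defined
as 0.

The Mann–Whitney U comparison of two per-family score vectors uses midranks
for ties; for n₁·n₂ ≤ 64 the two-sided p-value is computed by exact
enumeration of all C(n₁+n₂, n₁) group assignments (valid under ties), and
for larger samples by the normal approximation with tie correction. The
unpaired test is used even when the two vectors come from the same test set.

## Synthetic corpus

The generator emulates the structure that makes TF family classification
learnable: a conserved DNA-binding-domain-like motif embedded in variable
sequence, with a long-tail family-size distribution. Each family receives a
random 8-residue motif (pairwise Hamming distance between family motifs at
least half the motif length, so families are separable by 3-mer content);
each member is an i.i.d. background sequence of uniform random length
(80–300 by default) with the motif implanted at a random position, each
motif residue independently substituted with probability `mutation_rate`.
Unlabeled background sequences carry no motif (exact-substring collisions
are regenerated) and stand in for non-TF proteins. Everything derives from
one seed and regenerates byte-identically.

The fixed benchmark configuration is 8 families sized
400/300/200/150/100/60/40/20 (1 270 labeled sequences, a 20:1 largest-to-
smallest ratio), motif length 8, mutation rate 0.05, 500 background
sequences, seed 1337. At that mutation rate ~99% of members retain at least
two intact motif 3-mers, so near-ceiling accuracy is information-
theoretically attainable while single-k-mer shortcuts are unreliable.

What the benchmark does not emulate: real DBDs are longer, degenerate,
position-structured Pfam domains, not exact 8-mers; real proteomes have
biased residue composition and phylogenetic correlation between training
and test sequences; real families share homologous sub-domains. Passing the
synthetic benchmark therefore demonstrates that the pipeline's machinery —
encoding, selection, balancing, training, stacking, thresholding — works
end to end on a signal of realistic shape and class imbalance; it does not
certify accuracy figures on any real proteome.

## Problem sizes and runtime

The benchmark trains 8 binary classifiers and 3 stacker members on ~1 000
training sequences at k = 3 with 1 000 masked features, which completes in
roughly 8–10 minutes on a single CPU core. The test suite uses smaller
corpora (3 families, tens of members) for unit and property tests and the
full benchmark once. Training at k = 4 or 5 is supported (sparse encoding,
same mask sizes) and scales linearly in the number of families.

## Known limitations

- Splits are random per family; there is no sequence-identity-aware split
  hygiene, so on real data homologs can straddle the train/test boundary
  and inflate scores.
- The stacker is trained on in-sample base-learner outputs (no
  cross-fitting); the input jitter compensates for the resulting optimism
  but is a heuristic, not an out-of-fold guarantee.
- Negatives are drawn once per subset, not re-drawn per epoch.
- Thresholded rejection is the only open-set mechanism; there is no
  explicit non-TF training class.
- Binary training time is dominated by small-subset epochs; families below
  ~10 training members are close to unlearnable for a network of this size
  and are better served by the max-vote route over better-sampled families.
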