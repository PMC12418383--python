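# Methods

This note documents the models and procedures implemented in `utr5xpress`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

The 5' untranslated region (5'UTR) of an mRNA modulates translation
initiation: upstream AUGs can seed inhibitory upstream open reading frames,
stable secondary structure near the cap impedes ribosome scanning, and
composition biases correlate with expression. The toolkit models a
log-scale translation-efficiency (TE) label as a function of the 5'UTR
sequence (at most 200 nt), with two complementary predictors, and provides
the surrounding machinery a reporter-library study needs: dataset
filtering, redundancy-reducing clustering, evaluation diagnostics, and
normalization of plate-reader bioluminescence.

## Dataset semantics and filtering

Records carry a sequence (normalized to upper-case DNA, U→T at ingest, so
all downstream code sees one alphabet), an optional log-scale TE label, an
optional RPKM abundance, and a cell-line tag. Ambiguity codes are rejected
by default; a drop-with-warning policy exists for permissive ingest.
Training data keeps only records with a TE label present and RPKM
*strictly* greater than 10 (low-abundance transcripts have Poisson-noise-
dominated TE estimates; the strict inequality is a deliberate literal
reading of "exceeding 10"). Filtering is idempotent and never mutates
surviving records.

## Feature space

Three named groups feed the tree model:

* **SEQUENCE** — k-mer window frequencies for k = 1..6 (count divided by
  L−k+1, so each k-level sums to 1 for sequences of length ≥ k), GC
  metrics (`gc_content`, `at_ratio`, `cg_ratio` = #C/#G with a logged 0
  fallback for G-free sequences, keeping the matrix finite and dense), and
  the overlapping count of ATG triplets (`uAUG_count`).
* **CODON** — frequencies of the 64 triplets read non-overlapping in frame
  0 from the 5' end, normalized by the number of complete codons. A UTR
  has no canonical reading frame; frame 0 is a deterministic convention,
  flagged here because alternatives (e.g. computing codon usage on the
  downstream CDS) are equally defensible.
* **STRUCTURE** — from nearest-neighbor thermodynamic folding (ViennaRNA)
  at 37 °C (mammalian context; configurable): `MFE` (kcal/mol),
  `Gquad_energy` = MFE with G-quadruplex scoring enabled minus plain MFE
  (≤ 0 by construction — an extra stabilizing motif class can only lower
  the minimum), and `mean_distance`, the Boltzmann-ensemble expected
  base-pair distance, a structural-flexibility proxy on the nt scale.

Features are not standardized by default: trees are scale-invariant, and
the synthetic-label generator z-scores internally where it needs
comparability.

## Randomized-tree regressor

An ensemble of extremely randomized trees (random split thresholds, no
bootstrap by default; both switchable): 100 trees, `max_features` 0.8,
`min_samples_leaf` 1, unlimited depth, `min_samples_split` 2. The
prediction is the unweighted mean of tree outputs. The hyperparameter grid

    n_estimators ∈ {50, 100, 150} × min_samples_leaf ∈ {1, 2, 4} × max_features ∈ {0.5, 0.8}

(18 combinations) is searched by k-fold cross-validated mean squared
error; folds are contiguous splits of one seeded shuffle so the argmin is
reproducible, and ties break toward fewer trees, then larger leaves (the
simpler model).

## Soft-classification codec and network

Rather than regressing TE directly, the network predicts a probability
vector over 29 expression categories. A label e (in bin space) is encoded
through a latent ρ ~ Normal(e + 0.5, 0.5): category i receives
P(ρ ∈ [i, i+1)), with the first and last categories absorbing the tails.
The stated interval "(−∞, 1]" for category 0 conflicts with the half-open
[i, i+1) rule at the single point 1; the codec uses (−∞, 1), a
zero-probability-mass distinction resolved in favor of consistency.
Decoding is the expectation Σ iᐧprobs[i]; round-trip error is below 0.05
bins throughout the interior (verified against a Monte-Carlo oracle).
Because measured TE lives on an arbitrary log scale, an explicit affine
label map (dataset min → bin 0, max → bin 28 by default) is fitted,
serialized with the model and exactly inverted at prediction time; the
mapping is a declared choice, not a claim about any particular dataset.

The network is fully convolutional: a stem (conv k=7 → batch norm → SiLU)
into six convolutional blocks — a resizing block shaped like the stem
wherever the channel width changes, then a grouped conv k=7 (groups = 4 by
default; the depthwise-to-grouped substitution needs a group count and the
choice is logged in the config), batch norm, SiLU, and a
squeeze-and-excitation gate whose bilinear stage is the trained low-rank
two-factor form (C → r → C, r = C/4 by default) — with a per-channel
residual add. All convolutions are stride-1 "same"-padded; no positional
downsampling. A pointwise convolution to 29 channels, masked global
average pooling and a softmax produce the category distribution. Full
scale is 256 stem channels and [128, 128, 64, 64, 64, 64] block channels;
tests and desk-scale experiments use a reduced configuration
(64 / [32, 32, 16, 16, 16, 16]) for CPU budgets.

Inputs are one-hot encoded (channels A, C, G, T) with dynamic right
padding to the batch maximum — never truncation; sequences above 200 nt
are an error. Batch-norm statistics and the final pooling are computed
over real positions only, which makes predictions invariant to how much
padding a batch happens to carry (asserted to 1e-5 in tests); without
masking, batch composition would leak into predictions through the
padding width.

Training minimizes the batch-mean Kullback–Leibler divergence between the
encoded target distribution and the softmax output (predicted
probabilities floored at 1e-12 inside KL), using the sign-based Lion
optimizer (defaults lr 1e-4, betas (0.9, 0.99), decoupled weight decay
1e-2 — the optimizer's published recommendation; the choice is config,
not architecture). Training is seeded and bit-reproducible on one CPU.

The network runs on a small reverse-mode autodiff core written for this
package (`autodiff.py`): tensors over numpy arrays with broadcasting
arithmetic, exp/log/sigmoid/SiLU, axis reductions, matmul and a grouped
same-padded 1-D convolution. Every op's analytic gradient is verified
against central finite differences in the test suite.

## Greedy clustering and dataset compression

Sequences are sorted longest-first (ties broken lexicographically by id
for determinism) and processed once: each sequence joins the first
existing cluster whose representative it matches at or above the identity
threshold, else founds a new cluster as representative. A best-match
assignment mode exists behind a flag. An optional accelerated path is
deliberately absent: the single-pass implementation *is* the reference,
and the test suite holds it equal to an independently restated naive loop
on hundreds of random instances.

Identity is the number of identically aligned positions of an optimal
global alignment divided by the shorter sequence length (the greedy-
clustering tool family's convention; alignment-length normalization is
selectable). The alignment scoring matters at thresholds as low as 0.5:
under unit-cost edit-distance alignment, unrelated random DNA scores
~0.55–0.8 on this normalization, which would make a 0.5 threshold merge
everything. The default scoring (match +1, mismatch −2, gap open −15, gap
extend −0.2) penalizes chance co-linearity: unrelated ≥50-nt sequences
score ≲0.46 while 10%-substitution mutants score ~0.9, so a 0.5 threshold
separates families. A residual artifact of shorter-length normalization
remains: a short sequence aligned to a much longer representative
occasionally reaches ~0.5 by chance, so on variable-length libraries a
handful of members per thousand can land in the wrong (earlier-created)
cluster under first-match assignment; best-match assignment resolves
nearly all such cases (the stray scores ~0.9 to its own representative).
This is a property of operating this metric far below its usual ≥0.75
threshold range, and it is reported, not hidden, by the acceptance script's
membership-agreement metric.

Compression experiments hold out the representatives of all non-singleton
clusters as a diversity-maximal test set (singletons are excluded — with
no training neighbors there is nothing to learn them from), then select
training subsets per cluster either as ceil(fraction × remaining) members
(percentage mode; ceil so no non-empty cluster contributes zero) or
min(k, available) members (count mode, k = 6 default, which caps the
dominant clusters). A size-matched uniformly random subset is trained as
the control in every experiment, and `compression_rate = 1 − n_subset/n_full`,
`accuracy_restoration = r_subset/r_full` are reported.

## Evaluation

The headline metric is the Pearson correlation between predictions and
observations, averaged over the folds of a 10-fold cross-validation (the
pooled-prediction r is also reported for transparency). "Standard" CV
fixes the folds from one seeded shuffle and is deterministic; "randomized"
CV re-shuffles per repetition. Error structure is profiled as the mean
absolute error within unit-width TE intervals (empty intervals are
omitted, not reported as zero) and as two least-squares slopes —
predicted~observed and (predicted−observed)~observed — which satisfy
slope_error = slope_pred − 1 exactly, by linearity. Any CV-fitted
smoother shrinks toward the training mean, so slope_pred < 1 is the
expected regression-to-the-mean signature, and the tests assert it on
synthetic recovery data. Ablation runs share fold assignments across
feature subsets so comparisons are paired.

## ABI normalization

Bioluminescence plates carry one reference well each; technical duplicate
reads are averaged first (matching the stated order of operations), each
sample's per-plate signal is divided by its own plate's reference signal,
and the ABI is the mean of these ratios over the (default three) replicate
plates. This makes ABI invariant to plate-wide scale factors — the purpose
of the design — and exactly 1 for the reference sample. Plates missing a
sample reduce that sample's n with a warning rather than failing a run;
no background subtraction is applied by default (a hook exists).

## Synthetic data: what it emulates, and what it does not

Generators produce every input the toolkit consumes, as pure functions of
spec + seed:

* random UTRs with controllable GC bias and lengths uniform in a range
  (defaults 50–100 nt, GC 0.5);
* planted families: seed sequences redrawn until pairwise identity < 0.3,
  each expanded by i.i.d. per-base substitution (a substitution always
  changes the base, so expected member-to-seed identity is exactly
  1 − rate). Family sizes may be equal or skewed — real libraries are
  heavily skewed, and the advantage of count-based selection over random
  subsampling only exists in the skewed regime;
* TE labels: a linear combination of z-scored extracted features
  (default: MFE +1.0, gc_content −0.8, uAUG_count −0.6 — stable structure,
  high GC and upstream AUGs all suppress expression on the log scale),
  optionally plus a per-family Normal(0, family_sd) offset, plus Gaussian
  noise. The noise can be set directly or derived from a target population
  R². The family offset encodes the premise behind clustering-based
  compression — similar sequences share expression behavior beyond what
  global descriptors explain; without it (and with equal family sizes),
  count-based and random subsets of equal size are statistically
  indistinguishable, which the ledgered experiments confirmed;
* plate tables: a per-plate reference level (lognormal around 1e5 counts)
  scales all wells; experimental wells get multiplicative lognormal
  measurement noise; duplicates are emitted. The reference well defines
  the plate scale exactly — noise on the reference would propagate one
  shared error to every sample on its plate and not average out across
  samples.

Passing tests on this data demonstrates internal correctness and the
claimed orderings (feature recovery, selection-strategy ranking, codec
fidelity), not performance on real transcriptome-derived libraries: the
generator does not reproduce real 5'UTR composition, uORF grammar,
cell-line effects, or the actual TE noise process.

## Problem sizes and numerical choices

Desk-scale experiment sizes: codec checks over e ∈ [2, 26] in half steps;
clustering reference-agreement on instances of n ≤ 50 (lengths 20–60 nt);
planted recovery at 20 × 50 members; regression recovery at n = 1000 with
k ≤ 3 k-mers (155 features); selection experiments on a 980-sequence
skewed library over 10 replicates; network smoke training on 500
sequences of 60 nt for 20 epochs with the reduced configuration. Bin
distributions must sum to 1 within 1e-6 at validation (1e-9 at
construction); KL floors predictions at 1e-12; batch norm uses eps 1e-5
and momentum 0.1; Pearson r raises on zero-variance input rather than
returning NaN; grid-search and CV fold construction use seeded shuffles
only. Degenerate inputs (empty datasets, all-singleton clusterings,
constant folds) warn or raise as documented per module.

## Known limitations

* The network's full-scale configuration trains impractically slowly on
  one CPU with the in-package autodiff core; the architecture is the
  same, but large-scale training is outside the tested envelope.
* Codon usage on a UTR is a convention (frame 0), not biology.
* The identity metric below ~0.6 thresholds inherits the chance-alignment
  artifacts described above.
* TE→bin mapping is dataset-fitted and saved; applying a model to data
  outside the fitted label range clamps predictions to the bin range.
* ABI assumes one reference sample per plate after technical aggregation;
  multi-reference designs are not supported.
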