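# Methods

## Problem

A therapeutic peptide may carry several functional activities at once
(e.g. both anti-bacterial and anti-cancer).  Prediction is therefore a
multi-label task: given a sequence of 5–50 standard amino-acid residues,
score each of M function classes independently and return the subset whose
sigmoid score reaches 0.5.  Real curated benchmarks of this kind are heavily
imbalanced — the largest class can outnumber the smallest by ~37:1 — which
is the motivation for the class-weighting scheme at the core of the package.

## Model

Input tokens are the 20 standard amino acids in alphabetical order
(A=1 … Y=20); 0 pads every sequence to a fixed length L (default 50), with a
frozen zero embedding and no attention masking.  The forward path is

1. **Embedding** — learned, dimension `embed_dim`.
2. **Multi-scale CNN** — three 1-D convolutions with kernel sizes {2, 3, 8}
   ("same" zero padding), ReLU, each followed by non-overlapping max pooling
   (window 2); the three branches are concatenated along the feature axis at
   the shared pooled resolution.  The windows let the model see dipeptide,
   tripeptide and 8-mer context simultaneously.
3. **BiLSTM** — hidden size `recurrent_hidden` per direction; forward and
   backward hidden states are concatenated, so the sequence features have
   width d_m = 2·`recurrent_hidden`.
4. **Multi-head self-attention** — h heads; per head,
   `softmax(QKᵀ/√d_k)V` with Q = FW^Q, K = FW^K, V = FW^V, the head outputs
   concatenated and projected by W^O ∈ R^{h·d_k × d_m} back to d_m.  No
   residual connections or layer normalization are used.
5. **Classification** — global max pooling over sequence positions, dropout,
   and a dense layer with per-class sigmoid outputs.

Ablation variants (`no_cnn`, `no_bilstm`, `no_mhsa`) remove exactly one
block and let the neighbouring blocks connect directly; `no_cw` keeps the
architecture and replaces the class weights with 1.

The implementation rests on a small reverse-mode autodiff engine over numpy
(`prmftp.autodiff`).  Every operation's gradient is validated against
central-difference numerical differentiation in the test suite; apparent
mismatches at ReLU/max-pool kink points are an artifact of finite
differencing, not of the analytic gradients.

## Class-weight optimization (CW)

The training loss is class-weighted binary cross-entropy, averaged over
samples and labels, with

    W_i = phi * [log_10(N / n_i)]^theta

where N counts training peptides and n_i those carrying label i (a
multi-label peptide counts once for every label it carries).  theta is
constrained to `1 ≤ theta ≤ (ln X − ln Y)/ln(log_Y X)` with X = N/min(n),
Y = N/max(n); the default theta is the midpoint of that interval, recomputed
from the training counts of each run.

Numerical notes, all surfaced as explicit options or warnings:

* The log base of the weight formula is configurable (default 10); the
  theta bound uses natural logarithms throughout.
* The bound is undefined for balanced counts (X = Y) and, less obviously,
  drops below 1 whenever the largest class exceeds N/e instances — the
  constraint interval is then empty.  `default_theta` falls back to
  theta = 1 in both regimes.
* A class with n_i = N gets weight exactly 0, silencing its loss term; the
  implementation warns rather than silently flooring (a floor option
  exists in spirit via the `uniform` scheme; the formula is preserved
  exactly by default).
* Inside a CV fold a class can be entirely absent; its count is clamped to
  1 with a warning so the fold remains usable.
* Probabilities entering the cross-entropy are clipped to
  [1e-7, 1 − 1e-7].

Two generic baselines (`uniform`, `inverse_frequency` = N/(M·n_i)) are
provided for comparison; they are deliberately simple references, not
re-implementations of previously published weighting schemes.

## Evaluation

For true/predicted label sets L_i, L*_i over M classes: Precision, Coverage
and Accuracy are per-sample means of |L∩L*| over |L*|, |L| and |L∪L*|
respectively; Absolute true is the exact-match rate; Absolute false is the
per-sample mean of (|L∪L*| − |L∩L*|)/M.  Absolute false includes the 1/N
sample average: that is the only normalization consistent with the
magnitudes the metric is reported at in the literature this package follows.
A sample whose thresholded prediction is empty contributes 0 to Precision
(1 if its true set is also empty, impossible on curated data) — the
conservative convention for all-negative sigmoid rows.

The repeated-subsample protocol draws `reps` (default 5) random subsets of
80 % of the test set and reports the arithmetic mean of the per-subset
metrics; method comparisons on such shared subsets use a paired two-sided
t-test by default (the shared subsets induce the pairing), with the usual
star annotation for p < 0.05/0.01/0.001/0.0001.  A paired comparison whose
differences have zero variance (e.g. a constant shift) is rejected as
degenerate rather than given an infinite t statistic.

## Data handling

Curation applies three rules, in order, after multi-source merging:
(1) drop sequences with non-standard residues; (2) keep lengths 5–50;
(3) drop classes with fewer than 40 members (counted after rules 1–2) from
the vocabulary and from every record's label set, then drop label-less
records.  Curation is idempotent, and the class-count rule is applied to
post-filter counts.  Merging collapses identical sequences across per-class
sources into one record with the union of labels, deduplicating within each
source first; output order is lexicographic by sequence so the merge is
order-independent.  The train/test split is a simple (unstratified) seeded
random 80/20 partition; a stratified option is intentionally absent from
the default path.

The printed alphabet in the source description of the input encoding lists
18 letters while mapping to 20 numbers; this package uses the full 20
standard amino acids in alphabetical order, treating the omission of K and L
as typographical.

## Training protocol

Adam (lr default 1e-3), batch size 64, 60 epochs, no early stopping.
Ensembles of `repeats` models (default 10) differ only in the
initialization/shuffle seed; their probability matrices are averaged and
the 0.5 threshold is applied *after* averaging.  Hyperparameters are tuned
by grid search with 5-fold cross-validation on the training set, selecting
by mean CV Accuracy with Absolute true as tie-breaker.  Class weights are
always computed from the training split (or CV training fold) only.

Training is deterministic for a fixed seed: initialization, shuffling and
dropout masks all derive from it, and inference runs in pure numpy.

## Synthetic benchmarks

The generator plants a short class-specific motif (default: distinct random
4-mers, which cannot be substrings of one another) at a random position of
an otherwise i.i.d.-uniform random peptide.  Class sizes are exact primary
counts; with probability `co_occurrence` a record additionally receives a
second class's motif and label at a non-overlapping position, so realized
label counts exceed primary counts slightly.  A planted 4-mer arises by
chance in a 50-mer with probability ~3·10⁻⁴, keeping label noise
negligible.  Motif-planted signal was chosen over compositional bias so
that convolution kernels of sizes 2–8 can in principle detect class
evidence — the synthetic task matches the architecture's inductive bias.

What the synthetic data does *not* emulate: real peptide composition
statistics, homology structure between related peptides, label correlations
beyond pairwise co-planting, and ambiguous/partial motifs.  Passing the
synthetic experiments demonstrates that the implementation can learn
sequence-localized class evidence and that class weighting behaves as
designed under imbalance; it does not certify performance on real curated
benchmarks.

## Desk-scale study conditions

The library defaults are full scale (embed 128, 64 filters per kernel,
hidden 64 → d_m 128, 8 heads, d_k 16, dropout 0.5).  Tests and the
acceptance script use `ModelConfig.small()` — the same topology with
narrow layers (embed 20, 16 filters, hidden 24 → d_m 48, 4 heads, d_k 12,
dropout 0.5) — and learning rate 3e-3, selected by the package's own
CV-style sweep on the motif task (higher learning rate plus dropout
suppresses partial-motif false positives that plain lr 1e-3 training shows
at a few hundred training sequences).  Problem sizes used:

* **Learnability**: 3 balanced classes of 120 (300 train / 60 test),
  co-occurrence 0, 60 epochs, 5 seeds.
* **CW benefit**: primary counts {600, 300, 20} (30:1), co-occurrence 0.05,
  10 epochs, evaluated on an independently generated test set with 60
  minority-class records; CW vs uniform weighting compared on
  minority-class coverage (per-class recall) across 5 seeded replicates.
  The short training budget is the regime where weighting matters most —
  with enough epochs even unweighted training eventually masters a clean
  planted motif.

## Known limitations

* Pure-numpy training is single-process and practical up to a few thousand
  short sequences; the full-scale default configuration on a 10⁴-sequence
  benchmark is out of desk range.
* No attention masking over padding: for very short sequences the pooled
  features include pad-derived activations (constant biases); the model
  learns around this, but it is a departure from masked transformer
  practice, kept for fidelity to the described architecture.
* MHSA omits residual connections and layer normalization by design.
* The FASTA label dialect is package-specific (`>id|CODE1,CODE2`); no
  community standard exists for multi-label peptide FASTA.
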