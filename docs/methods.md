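# Methods

## The model

`convdti` predicts whether a small molecule binds a protein from two inputs:
the raw amino-acid sequence and a binary Morgan/circular fingerprint of the
drug (radius 2, 2,048 bits). The protein side is the interesting part. Each
residue is mapped through a trainable embedding table (22 tokens: the 20
canonical amino acids, a pad token `$` reserved at index 0, and an unknown
token for ambiguity codes such as B, Z, X, U, O), giving an `L x ES` matrix
for a sequence of length `L`. Banks of 1-D convolution filters — one bank
per *window size* `WS`, `F` filters per bank — slide along the sequence with
stride 1:

    (x * w)_j = sum_{a=1..ES} sum_{t=0..WS-1} w_{a,t} x_{a, j+t}

Each filter's response is reduced by **global max-pooling over the valid
positions** `j = 1 .. L - WS + 1`: a filter reports only its single best
match and where it found it. The pooled values, concatenated across filters
and window sizes (dimension `F x |WS|`), are a position-invariant protein
feature vector describing which learned local residue patterns occur
anywhere in the sequence. That vector passes through fully connected layers;
the drug fingerprint passes through its own dense stack; the two latent
vectors are concatenated and mapped through joint dense layers to a sigmoid
interaction probability. Hidden layers use batch normalisation followed by
ELU (`alpha * (e^x - 1)` for `x < 0`, identity otherwise).

Training minimises binary cross-entropy plus an L2 penalty
`lambda * sum_l ||W_l||^2` over dense and convolution kernels (embedding,
biases and batch-norm parameters are excluded — the conventional
weight-decay scope), optimised with Adam at its canonical defaults.
Probabilities are clipped at 1e-7 in the loss. Regularisation follows the
split the architecture implies: 1-D *spatial* dropout (whole embedding
channels) on the embedding layer, batch-norm everywhere else.

### Padding and masking

Sequences are encoded to a fixed maximum protein length (MPL, default
2,500) by padding with `$`. A trainable pad embedding could win a max-pool,
so by default window positions extending past the true length are set to
-inf before pooling (`mask_padding`). This makes the forward pass exactly
invariant to MPL for any MPL at or above the sequence length — an invariant
the test suite checks to 1e-10 — and it is why batch-norm for the
convolution stage is applied to the *pooled* feature vector rather than to
per-position convolution maps (per-position statistics would depend on how
much padding the batch carries). An unmasked mode reproduces the plain
pool-over-everything variant. Sequences longer than MPL are truncated to
their first MPL residues with a warning (configurable to reject):
head-anchored truncation is deterministic and keeps the N-terminal content.

### Numerical and tie-break conventions

- Convolution bias terms are on by default (`conv_bias=False` gives the
  pure double sum; the oracle tests run that way).
- Max-pool ties break to the earliest position, so attribution is
  deterministic.
- Batch-norm order is linear -> batch-norm -> ELU; running statistics use
  momentum 0.9 and are frozen at inference.
- A window size longer than the sequence has no valid position: the pooled
  value is defined as 0 and the argmax flagged -1.
- All weights are Xavier/Glorot-normal initialised; everything stochastic
  (init, minibatch order, dropout, negative sampling, Monte-Carlo nulls) is
  reproducible from a single integer seed.

The network is implemented directly in NumPy with analytic backpropagation
(including train-mode batch-norm); a finite-difference check in the test
suite verifies every parameter gradient of the penalised loss to 1e-4
relative error, with an absolute floor of 1e-7 absorbing parameters whose
true gradient is exactly zero (a bias feeding straight into batch-norm).

## Model selection and thresholding

Training keeps the parameter snapshot from the epoch with the best
validation AUPR (fixed epoch budget, no early stopping). Grid search trains
one model per Cartesian-product point with the learning rate held fixed,
compares by validation AUPR, and breaks ties toward the smaller parameter
count. The classification threshold is selected by the equal-error-rate
rule with cost ratio `gamma` (default 2):

    theta* = argmin_theta |1 - recall(theta)| + gamma * |1 - precision(theta)|

over all achievable thresholds (unique scores plus midpoints). The variant
with a minus sign between the terms is available behind a `literal` flag but
is degenerate — it rewards the threshold that makes precision worst — so
the summed form is the default.

Threshold metrics follow the standard confusion-matrix formulas
(Sen = TP/P, Spe = TN/N, Pre = TP/(TP+FP), Acc = (TP+TN)/(P+N)). Two F1
variants are reported: the standard `2*Sen*Pre/(Sen+Pre)` as the headline
and the halved form `Sen*Pre/(Sen+Pre)` (which maxes at 0.5) kept for
comparability with sources that print it; one is exactly twice the other.
Undefined metrics are reported as absent with a reason, never as 0. AUC is
the trapezoidal ROC area (equal to the normalised Mann-Whitney statistic,
ties counting one half); AUPR uses step-wise interpolation (average
precision), avoiding the optimistic linear interpolation of the PR curve.

## Binding-site attribution

If the model has learned binding-relevant local patterns, the argmax
windows of its filters should cover annotated binding residues more often
than chance. For each window size the observed statistic counts, over the
argmax windows of all `F` filters of that size, the (window, residue)
covering events against a 1-based residue annotation (mode `events`,
default; duplicate argmax positions count multiply). A `residues` mode
counting distinct covered residues, and a unique-starts option, are also
exposed. The null places the same number of windows uniformly with
replacement over the valid start positions, 10,000 replicates by default,
and fits a normal to the replicate counts; the observed count is scored by
the normal's upper tail (right-tailed; at 10,000 replicates the t
correction is negligible). Degenerate nulls (sd = 0, e.g. a single valid
start or an annotation spanning the whole sequence) give p = 1 / 0.5 / 0
below / at / above the mean. P-values are Benjamini-Hochberg adjusted
across window sizes within the entry — we do not know in advance which
window size detects a site — and the entry is summarised by its minimum
adjusted p-value, thresholded at 1%, 5% and 10%. The events mode has a
closed-form null expectation,

    E[count] = n_results * sum_{r in site} (#starts covering r) / (#valid starts),

which the tests verify against the Monte-Carlo mean to three standard
errors on random geometries.

### A calibration limitation

The uniform-placement null assumes the filters' argmax positions are
independent and uniform when the model knows nothing. They are not quite:
all filters of a bank share the sequence, and a window with atypical
embedding content attracts the argmax of many filters at once. This
positive dependence inflates the variance of the observed count relative
to the null, and the normal fit additionally underestimates the right tail
of the skewed discrete count. A control experiment that draws the observed
statistic from the same uniform process as the null calibrates correctly,
so the machinery is sound; with a real (untrained) model the significant
fraction at the 1% level runs slightly high (2-4% across seeds for a
16-filter bank), and the effect grows with the filter count (a 128-filter
bank reaches ~13% at the 5% level). Calibration and recovery experiments
therefore use the small 16-filter model, and attribution p-values near the
1% level should be read with this in mind. For visual summaries,
`top_k_coverage` counts, per residue, how many of the top-k pooled windows
per window size cover it (k = 5 by default).

## Synthetic data

The generator emulates the structure the method assumes, with defaults
chosen as the standard study conditions: 100 proteins of 80-250 residues
drawn uniformly over the 20-letter alphabet; three 8-residue motifs
implanted (overwriting the background, so recorded positions are exact) at
uniform non-overlapping positions, 0-2 motifs per protein; 80 drugs given
8 random fingerprint bits out of 2,048, half additionally carrying one
rule bit; a one-motif-one-bit rule defining label 1 exactly when the
protein carries a motif whose bit the drug has; 5% label flips; and one
uniformly sampled negative per positive, giving ~2,000 pairs. Drugs carry
fingerprints directly rather than generated SMILES — valid random SMILES
generation adds nothing to exercising the network.

What the generator does not emulate: real amino-acid composition and
homology structure, degenerate or partially conserved motifs, chemistry
(fingerprint bits are independent rather than hashed substructures), and
dataset-level biases such as hub drugs or proteins. Passing tests
therefore demonstrate that the implementation learns and attributes the
planted signal correctly at this scale, not that the architecture attains
any particular accuracy on real interaction databases.

## Reference experiment scale

The standard experiments (`convdti.experiments`) use a small model — window
sizes (5, 8), 16 filters per window, embedding size 16, dense stacks
32/32/16, MPL 300, batch 32, 20 epochs — that trains in well under a minute
on one CPU. Its learning rate (1e-3) was selected by validation AUPR,
following the protocol of fixing the learning rate first; the large-data
default (1e-4) learns the same task but needs more than 20 epochs. The
end-to-end run reaches validation AUPR around 0.88-0.95 across seeds
against a 0.50 positive-fraction baseline, with a permuted-label control
staying within a few points of the baseline; an idealised model whose
filters are set to the exact motif embedding templates recovers every
motif-bearing entry at the 5% level, while a trained model recovers a
smaller but clearly above-calibration fraction.

## Known limitations

- The NumPy implementation is single-threaded per BLAS call and intended
  for desk-scale experiments, not for training on millions of pairs.
- Batch-norm with a batch of one is degenerate; inference always uses
  frozen running statistics, and training expects batch sizes above ~4.
- The attribution null's mild anti-conservativeness at stringent levels is
  described above.
- Negative sampling assumes unlabelled pairs are negative; at a 1:1 ratio
  this mirrors the usual DTI training construction, not biological truth.
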