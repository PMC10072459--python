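# Methods

## Pipeline

The package implements compressed-domain heartbeat classification: beats are
compressed by a learned convolutional mapping and classified directly in the
compressed representation, skipping reconstruction entirely. The stages are
(1) beat segmentation and normalization, (2) AAMI label mapping and class
balancing, (3) compression to k = round(CR·n) samples, (4) four-class
classification, (5) metric reporting and CR-sweep benchmarking.

## Segmentation and preprocessing

A beat is the half-open window `[r − 130, r + 130)` around an annotated R
location, 0-based, with R at position 130 — exactly 260 samples at the
MIT-BIH sampling rate of 360 Hz. The database's beat-annotation indices are
used as R locations; no independent QRS detector runs (an optional
local-maximum refinement within ±10 samples exists, off by default, for
annotation streams whose fiducial is not the R apex). Windows crossing the
record boundary are skipped and tallied, never padded, so a record's beat
count can fall short of its annotation count by a handful of edge beats.

No filtering or denoising is applied anywhere; the classifier trains on raw
morphology. Each beat is independently min-max normalized to [0, 1]
(constant beats map to zeros; the map is idempotent). Min-max per beat was
chosen over z-scoring because the first network layer is a bounded-input
convolution and per-beat amplitude scale is a nuisance dimension here;
z-scoring is available as an alternative by normalizing externally and
passing `normalize=False`.

AAMI mapping groups MIT-BIH beat symbols into N/S/V/F/Q. The grouping places
paced (`/`) and paced-fusion (`f`) beats under N (with bundle-branch blocks,
escapes, and normals), supraventricular prematures (`S A J a`) under S,
ventricular ectopy (`V E r`) under V, ventricular-normal fusion (`F`) under
F, and unclassifiable (`Q ?`) under Q. Rhythm/quality/waveform marks are
excluded as non-beats; beat symbols outside the table are tallied as
unmapped rather than silently dropped. The four-class experiments discard Q
via the balancing targets.

Balancing draws exact per-class counts by seeded uniform sampling without
replacement (the reference counts: 1000 N, 1000 S, 1000 V, 802 F = 3802
beats); a manual curation step is inherently irreproducible, so a seeded
draw stands in for it. The train/test split is 0.8/0.2 via scikit-learn with
a fixed `random_state`; the train size is `round(0.8·n)` with Python's
round-half-to-even (3802 → 3042/760).

## Architectures and parameter accounting

Plans are declarative layer DAGs carrying output shapes and parameter counts
computed with the standard conventions: conv1d `(kernel·in_ch + 1)·filters`,
dense `(in + 1)·units`, batch-norm `4·channels` total (`2·channels`
trainable), LSTM `4·units·(in + units + 1)`. Convolutions are stride-1 with
length-preserving zero padding; max pooling is valid with stride equal to
the pool size, dropping any trailing remainder — the only reading consistent
with the published shape chain 260→130→65→13 and the 10,868-parameter dense
layer ((13·16+1)·52).

The classifier's two parallel branches (conv16 + batch-norm + pool2) are
concatenated **along the time axis**, restoring a k-long 16-channel sequence;
the channel-axis reading is inconsistent with the downstream printed shapes
(a 784-parameter convolution requires 16 input channels). The trunk is three
blocks of two identical convolutions each (16,16 then 64,64 then 64,64) with
pools 2/3/4 and dropout 0.5 after each block. Block rows printed as paired
ranges are implemented as two sequential identical convolutions; because
that reading of the source table is not fully unambiguous, per-layer counts
are asserted only for the unambiguous rows, and network **totals** are not
asserted anywhere.

For small k (CR = 0.05 gives k = 13) the fixed pools would exhaust the
sequence; each pool clamps to the current length (logged), keeping the whole
CR sweep runnable. Ablation variants: `no_parallel` feeds the trunk
directly from the input; `plus_lstm`/`plus_bilstm` insert a 64-unit
(Bi)LSTM — width matching the trunk, since no unit count is published —
returning its hidden sequence before the flatten.

## Training

Compressor and classifier are trained jointly on the classification
cross-entropy (negative log-likelihood; probabilities clipped at 1e-7 inside
the log). No pre-training and no reconstruction objective exist — the
absence of any decoder makes joint discriminative training the coherent
reading of the pipeline. Optimization is Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-7) at initial rate 0.001, batch size 64, 50 epochs. The learning rate
follows reduce-on-plateau — factor 0.8, patience 5 epochs, floor 1e-5,
monitoring the loss on an internal 10% validation split cut from the
training set — producing the characteristic stepped decay from 0.001 toward
~0.0005 by epoch 50; the exact published trajectory is not targeted, only
the non-increasing stepped shape, which is asserted.

The network engine is pure NumPy with hand-derived backward passes for every
layer (conv via shifted matrix products, pooling argmax scatter, batch-norm
with Keras conventions eps 1e-3 / momentum 0.99, full softmax
Jacobian-vector product, BPTT for the LSTM variants), verified against
central finite differences in the test suite. Everything draws from one
seeded generator, so training is deterministic by construction — there is no
separate "deterministic mode" to enable.

## Baselines

SVD projects beats onto the top-k right singular vectors of the raw training
matrix; PCA does the same after mean-centering (scikit-learn's exact
solver). Both fit on the training split only and feed the same classifier
architecture, trained classifier-only. PCA/SVD require k ≤ rank of the
training matrix; infeasible benchmark cells report NaN rather than aborting
the grid.

## Synthetic data

The generator emulates the gross morphology separating the AAMI classes with
per-class Gaussian-bump templates (P/QRS/T): N narrow QRS with normal P/T; S
with a premature ectopic bump and attenuated T; V wide tall QRS, absent P,
discordant T; F intermediate fused width. Defaults: 260-sample beats,
R-centering jitter SD 2 samples, relative amplitude scatter 5%, additive
noise SD 0.03 (≈3% of QRS amplitude — clean-recording regime). It does NOT
model rhythm context, inter-patient variability, baseline wander, electrode
noise or class overlap, so pipeline accuracy on it is an upper bound: passing
tests certify the machinery (shapes, gradients, convergence, CR trend), not
clinical performance. Separability is itself certified in-suite by a
nearest-centroid oracle (≥ 99% held-out).

Standard experiment size is 250 beats/class (1000 beats, 800/200 split),
trained for 50 epochs — about 35 s per run on one CPU core; benchmark-grid
tests use smaller sizes and fewer epochs since they check mechanics, not
accuracy.

## Numerical choices and edge cases

- k rounding: half-away-from-zero on cr·n, minimum 1.
- Pool remainders are dropped (no padding); pool sizes clamp to the current
  length and log when they do.
- Zero-denominator metric cells (a class never predicted or never present)
  report 0 with a warning; they arise only on degenerate tiny test sets.
- ROC/PR curves are one-vs-rest per class, skipped with a note for classes
  with single-valued truth; no micro-averaging.
- Reported "average" precision/sensitivity/F1 are macro (unweighted) means;
  Accuracy is trace/total of the confusion matrix; Score = (macro F1)².
- Beat-table CSV round-trips at 8 significant digits; WFDB fixture writing
  quantizes at the header gain (default 200 ADC units/mV).

## Known limitations

- The WFDB reader covers signal formats 212 and 16 (the MIT-BIH formats) and
  single-annotator `.atr` streams; exotic formats, multi-segment records and
  skew are out of scope.
- Which of the two MIT-BIH leads a published experiment used is generally
  unstated; channel 0 (MLII for most records) is the default and results can
  differ by lead.
- Laplacian-Eigenmaps and stacked-autoencoder compression baselines and
  third-party comparison classifiers are not implemented (no published
  configurations to implement).
- Training wall-clock depends on BLAS; no GPU path exists.
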