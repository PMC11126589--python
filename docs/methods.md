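# Methods

This note documents the models and procedures `squigselect` implements,
the defaults it ships with and why, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and conventions

All timing assumes the R9.4.1 direct-RNA configuration: **3012 samples/s**
and a nominal translocation speed of ~70 nt/s, i.e. **~43 samples per
nucleotide**. These two constants make the anchor correspondences exact:
1 s ⇔ 3012 samples, 4 s ⇔ 12,048 samples ⇔ ~280 nt. All indices are
0-based, all intervals half-open; a trim position is the index of the
first transcript sample.

A direct-RNA squiggle is modelled as three concatenated segments, in
sequencing (3'→5') order:

| segment | duration | mean (pA) | MAD (pA) | why |
| --- | --- | --- | --- | --- |
| sequencing adapter | U(1, 3) s | 80 | 25 | low mean, high dispersion |
| poly(A) tail | U(0.5, 3) s | 110 | 5 | homopolymer ⇒ low variance, elevated mean |
| transcript | length × dwell | k-mer levels | 25 (noise) | sequence-determined levels |

The poly(A)/adapter mean ratio (1.375) and the MAD values are chosen so
that the trimmer's start criterion (≥ 20% mean step, MAD < 20) and end
criterion (MAD > 20) are *satisfiable but not trivialized*: they sit at
roughly the contrast real squiggles show, and the generator enforces the
ratio ≥ 1.25 as an invariant. Transcript levels come from a seed-fixed
random 5-mer table (uniform 60–130 pA) **shared across classes**; class
identity enters only through the 3'-end sequence, whose first 400 nt are
concatenated motifs drawn from disjoint per-class pools (12 motifs of
8 nt each, by default). This mirrors the working premise of signal-based
RNA-class detection: classes differ in 3'-end composition, not in global
signal level. Per-nucleotide dwell is 43 samples with ±10% uniform
jitter. Per-transcript sequences are deterministic in (transcript id,
preset seed), so all copies of a transcript share a squiggle profile —
which is what makes per-transcript bias audits meaningful.

**Not emulated:** pore kinetics and dwell-time distributions, current
drift, stall/block artefacts, basecallable signal content, channel-level
effects. Consequently, passing tests demonstrate that the *system logic*
(trimming, incremental decision-making, curation, statistics) is correct
and that the classifier can recover class structure carried by 3'-end
composition; they do not demonstrate classification accuracy on real
squiggles.

## Real-time trimming

The boundary search scans consecutive non-overlapping windows of
R = 500 samples (~10 nt). Window *w* (index ≥ 2) marks the poly(A) start
when (1) mean(w) ≥ 1.2 × the mean of the two preceding windows combined
and (2) MAD(w) < T = 20 pA. The first later window with MAD > 20 pA
marks the trim position. If nothing is found within 6.2 s of signal, a
fixed 2.2 s trim applies (6.2 s = the fixed trim + the 4 s maximum model
input; 2.2 s is the lower quartile of adapter+poly(A) durations in the
original model-development data). The scan never inspects samples beyond
the 6.2 s boundary, and the result is prefix-stable: re-running on a
longer prefix of the same signal never changes a detected trim.

Two readings of "a 20% increase in mean amplitude compared to the
previous two windows" are possible: against *each* of the two windows
(equivalently their max) or against their *joint* mean. This package
uses the joint mean. The choice matters when the adapter/poly(A)
boundary falls mid-window: with the per-window (max) reading and the
default preset, a straddling window with poly(A) fraction between ~0.4
and ~0.75 raises the reference mean enough that neither it nor the first
full poly(A) window can pass, so roughly a third of reads (boundary
phase is uniform) would fall through to the fixed trim; with the joint
reading the criterion is satisfiable at every boundary phase. The joint
reading is also the natural estimator (mean over the combined 2R
preceding samples).

Normalization is (x − median)/MAD with outlier smoothing: values are
first clipped to median ± 3 MAD, and the scaling statistics are computed
before clipping. A constant signal maps to all zeros. "Outlier
smoothing" is not further specified anywhere; clipping at ±3 MAD is the
simplest robust scheme, and the classifier's convolutional design is
tolerant to the difference between clipping variants.

## Dataset curation

Reads keep their label only when the primary mapping biotype matches the
modal secondary mapping biotype (no secondaries ⇒ trivially confirmed;
modal *ties* are discarded — the conservative resolution of an
unspecified corner). Balancing proceeds in a fixed order:

1. designated biotype subgroups are equalized within their class,
   limited by the scarcest listed subgroup;
2. an optional per-gene cap (a fraction of the gene's class) is applied;
3. the majority class is undersampled, uniformly at random, to a 50/50
   balance;
4. each class is split 80/20 into train/test and 10% of train becomes
   validation, with identical per-class counts so the balance is exact
   in every split and splits are disjoint by read id.

Whenever a subset of a pool must be drawn (steps 1–2), reads are taken
one per gene per round (round-robin), so abundant genes cannot dominate.
Gene order within the round-robin is randomized once per seed and then
fixed, since only the one-per-gene property, not an order, is specified.

Training windows: each read's transcript signal is cut once per length
in {2, 3, 4} s and MAD-normalized; reads shorter than 4 s of transcript
signal are discarded entirely. By default the transcript start is taken
from the package's own boundary search run on the complete signal
(`trim_source="detected"`), the offline analogue of live trimming: the
production pipeline also trimmed training data with a (different,
HMM-based) offline trimmer rather than with ground truth. This matters:
training on exact generator boundaries and deploying behind the
real-time trimmer shifts the input distribution (windows may start up to
one window width from the true boundary and can include residual poly(A)
signal), which measurably depresses live rejection rates even when
held-out accuracy on exactly-trimmed windows is high. `"truth"` remains
available for experiments that need exact boundaries.

## Classifiers

Three convolutional families, each mapping a 1-channel normalized window
of variable length to one target-class probability (single logit +
sigmoid, matching the binary cross-entropy loss; not a 2-way softmax):

* **CNN** — l = 12 layers of [conv(k = 3, stride 1, same padding) +
  ReLU] each followed by max-pool(k = 2, s = 2); channels c₀ = 20,
  cᵢ = ⌊1.5·cᵢ₋₁⌋ (…, 1135, 1702); head = global average pooling + one
  fully-connected stage. Each layer halves the temporal length, so an
  input must supply ≥ 2¹² = 4096 samples: 1 s (3012) is rejected with an
  explicit length error, 2–4 s pass without rebuilding (the GAP head is
  length-agnostic). No stem beyond layer 1: the architecture is exactly
  the l repeated layers.
* **ResNet** — entry conv(k = 19, stride 3) + batch-norm + ReLU +
  max-pool(2, 2), then l = 10 layers of one *basic* residual block each
  (conv-BN-ReLU-conv-BN with identity shortcut, 1×1 conv + BN where
  channels change), channel schedule as above, GAP + FC head.
* **TCN** — l = 10 residual blocks of two dilated causal convolutions
  (k = 11, dilation 2ⁱ in block i, 32 channels, dropout 0.05), predicting
  from the last timestep. Receptive field of that timestep:
  1 + 2·Σᵢ₌₀⁹ 2ⁱ·(k − 1) = 20,461 samples ≥ 12,048, so the maximal 4 s
  window is fully covered. (Read with a *constant* exponent, the
  receptive-field formula would give 801 samples and the selected
  configuration could not satisfy its own coverage constraint; the
  per-layer-exponent reading is therefore implemented.)

The networks run on a small numpy layer framework (`_nn.py`):
convolutions are lowered to BLAS matrix products via an im2col gather
with one contiguous copy per kernel tap, with explicit backward passes;
this is what makes CPU training of the full-size CNN practical. All
tensors are float32. Weight init is He-scaled Gaussian except the final
linear head, which is zero-initialized so the untrained model outputs
exactly p = 0.5 — with a GAP head over an unnormalized 12-layer stack
the feature magnitude is large, and a randomly initialized head starts
training from confidently wrong, saturated logits.

Training: binary cross-entropy + Adam, batch size 32, every batch
homogeneous in window length, batch order shuffled per epoch so
consecutive batches alternate between 2/3/4 s at random; reproducible
per seed. With a validation set, the weights of the best-validation
epoch are restored at the end (default budget 30 epochs; the synthetic
class-recovery experiment in the test suite uses 5 epochs at learning
rate 3 × 10⁻⁴ — the production setting of 10⁻⁴ presumes roughly a
hundred times more optimizer steps per epoch than a desk-scale dataset
provides, and the scaled-up rate is the package's standing choice for
the synthetic demonstration). Checkpoints are single .npz containers
holding all weights and buffers plus the config, seed and a SHA-256
digest of the training data; loading rebuilds from the stored config,
refuses a family mismatch, and warns when an expected digest differs.

## Decision engine and playback

Signals stream in 1 s chunks. Per molecule: accumulate signal, update
the trim; once ≥ 2 s of transcript signal is available, normalize and
predict on whole seconds of transcript signal (2, 3 or 4 s — whole-
second windows both match how the confidence threshold was calibrated
and let the simulator batch model calls across reads); apply the
decision rule; retry on the next chunk while undecided, with one final
attempt on the *first 4 s* when a chunk overshoots the horizon; after
that the molecule completes unaffected. Decision rule (T = 0.9):
deplete ⇒ reject iff any target probability > T, accept iff all
< 1 − T; enrich (single target) ⇒ accept iff p > T, reject iff
p < 1 − T. Comparisons are strict: p = T is never confident. At most one
reject command is ever sent per molecule; a configurable per-reject
failure probability (default 0, modelling trans-side secondary
structure) lets the one-reject rule be exercised — a failed reject
completes forward.

The playback simulator services all active reads once per chunk period
(one global batch index), applies the even/odd channel split (channels
divisible by 2 = treatment; control reads are never assessed), and
models ejection latency as one extra chunk of delivered signal after a
reject (configurable; the real lag between command and voltage reversal
is hardware-dependent and outside the software's control). Reads that
end before the decision horizon simply finish ("escape"). Outputs: a
per-read table, a decisions CSV (read id, batch, channel, signal length
assessed, per-target probabilities, threshold, decision) and a log with
settings and decision tallies.

## Evaluation statistics

* Accuracy, precision, TPR, FPR at a 0.5 cut; TPR/FPR ratio with an
  infinite sentinel at FPR = 0; AUROC as the probability that a random
  positive outscores a random negative with ties counting ½ (computed
  via scikit-learn; the test suite keeps an independent brute-force
  pairwise oracle); per-biotype accuracy as group-wise mean correctness.
* Threshold replay: per candidate T ∈ {0.6, 0.75, 0.9}, the incremental
  2→3→4 s protocol is replayed per read with first-exceedance semantics;
  proportions {correct, incorrect, undecided} sum to 1.
* Probability of superiority PS = U₁/(x·y), with U₁ from pooled midranks
  (identical to the pairwise count with ½ per tie; cross-checked in the
  tests against both enumeration and scipy's rank-sum statistic).
  p-values use a one-tailed, continuity- and tie-corrected normal
  approximation and are reported descriptively; no multiple-testing
  correction is applied anywhere.
* Percent change per transcript, treatment vs control: restrict to the
  smallest control-sorted prefix holding ≥ 95% of control counts, drop
  transcripts with < 30 counts in **both** conditions ("both" read as
  AND — the literal reading of an ambiguous rule), optionally drop
  lncRNAs whose exons share any base with a coding exon, then
  100 × (treatment − control)/control. Order-invariant by construction.
  When counting from a playback run, a truncated read still counts as a
  read if it delivered ≥ 1 s of transcript signal (the minimum-mappable
  default) — shorter truncations would not survive basecalling/mapping,
  which reconciles per-molecule rejection with observed read-count
  reductions.
* Relative abundance: per-condition fractions over transcripts with
  ≥ 10 reads (same AND reading), Pearson correlation on the raw
  fractions (no log transform), undefined below 3 shared transcripts.
* Bias audit: per class and per transcript, proportions correctly /
  incorrectly decided / undecided, summing to 1.
* Coverage: 3'-anchored percent depth per position and per-read covered
  fraction; for simulated truncations the covered span is the delivered
  transcript samples ÷ 43 nt.

## Problem sizes and numerical choices

The scientific checks in `tests/test_acceptance.py` run at desk scale,
chosen as the smallest sizes at which the statistics are stable: 500
reads for trimmer boundary recovery (±1 window tolerance, ≥ 95% of reads
with ≥ 2R of poly(A)); ≥ 2000 training windows per class (1500 reads,
50/50) for class recovery with a 15% held-out split; 2000 reads at an
80/20 class mix for the depletion playback; 100 random instances of
n ≤ 200 for the exact rank-statistic equivalences. Determinism: every
stochastic component takes an explicit seed (generator, training, batch
order, playback); identical seeds reproduce identical catalogs, signals,
splits and loss trajectories. Degenerate inputs have defined behaviour
throughout: empty signals are "pending", constant signals normalize to
zeros, empty runs produce header-only decision files, zero-read requests
produce empty lists, and empty probability sets, empty samples or
single-class label vectors raise explicit errors.

## Known limitations

* Synthetic class separation is, by construction, stronger than between
  real RNA classes; held-out accuracies here say nothing quantitative
  about real libraries.
* The numpy training loop is single-process and CPU-bound; it is sized
  for the desk-scale experiments, not for production-scale datasets.
* The simulator abstracts the vendor streaming interface: no pore-health
  dynamics, no queueing effects, fixed ejection latency, simultaneous
  read starts.
* Poly(A)-length estimation is out of scope: the trimmer locates
  boundaries at window (±500 samples) resolution, which the translation-
  invariant classifiers tolerate; high-resolution segmentation methods
  exist but are too slow for real-time use.
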