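# Methods

## Model

One beat is represented by two views: its morphology — the 200-sample
baseline-corrected window `[R−90, R+110)` at 360 Hz (≈ 0.25 s before to
0.31 s after the R peak, covering P through T) — and its rhythm context,
four RR-interval features. A three-block 1D CNN encodes the morphology;
the flattened 320-dimensional code is concatenated with the 4 RR features
and classified by a one-hidden-layer MLP with softmax over the four AAMI
classes (N, SVEB, VEB, F; the indices 0–3 in that order everywhere: loss
targets, outputs, confusion-matrix axes).

Layer stack (valid padding throughout; lengths 200→64→31→27→13→11→5):

| block | layers | output | trainable | non-trainable |
|---|---|---|---|---|
| 1 | conv(k11, 16f, s3) + BN + ReLU + pool(3, s2) | 31×16 | 192 + 32 | 32 |
| 2 | conv(k5, 32f, s1) + BN + ReLU + pool(3, s2) | 13×32 | 2,592 + 64 | 64 |
| 3 | conv(k3, 64f, s1) + BN + ReLU + pool(3, s2) | 5×64 | 6,208 + 128 | 128 |
| head | flatten ⊕ RR → dense 64 (ReLU) → dense 4 (softmax) | 4 | 20,800 + 260 | — |

30,276 trainable parameters, 224 batch-norm running statistics. Block
order is convolution → batch-norm → ReLU (the reference layer table;
its accompanying prose lists ReLU before BN — the table was taken as
authoritative). The hidden dense layer uses ReLU; no activation is stated
for it in the reference table, and a linear hidden layer would collapse
the MLP, so ReLU is the package's choice.

The whole network — forward pass, backpropagation, Adam — is written in
NumPy. No deep-learning framework is involved; the analytic gradient of
every layer (and of all three losses with respect to the logits) is
checked against central-difference numerical differentiation in the test
suite. Convolution biases are exempted from that check: batch
normalization directly after a convolution makes the loss exactly
invariant to a bias shift, so their true gradient is ~0 and a finite
difference there measures rounding noise.

## Losses

With `p_t` the softmax probability of the true class:

* cross-entropy `CE = −log p_t`
* focal `FL = −(1 − p_t)^γ log p_t` (default, γ = 2)
* α-balanced focal `FL′ = −α_t (1 − p_t)^γ log p_t`

all reduced by the batch mean, natural log, probabilities clipped to
`[1e−7, 1]` before the log. The modulating factor `(1 − p_t)^γ` shrinks
the contribution of confidently correct examples; since ~89% of beats are
class N and quickly become easy, this keeps the minority classes visible
in the gradient. γ = 0 recovers cross-entropy exactly (tested to 1e−9),
and the loss at fixed `p_t` is non-increasing in γ.

## Preprocessing and feature choices

* **Median windows.** Widths are specified in milliseconds (200, 600); in
  samples we use `round(ms·fs/1000)` incremented to the next odd integer —
  73 and 217 at 360 Hz — so the median is always an actual signal value.
* **Edge handling.** Each median pass uses mirror (symmetric) padding of
  half a window at both ends; zero padding would fabricate edge dips. The
  estimator is verified elementwise against a brute-force sliding-median
  oracle with the same padding rule. Residual wander suppression holds in
  the interior; the first/last half-window is biased, the unavoidable edge
  cost of a finite filter.
* **Segmentation.** Beats whose 200-sample window would cross a record
  edge are dropped (and counted), never padded. No amplitude rescaling or
  z-scoring: the only conditioning is baseline subtraction, preserving the
  raw morphology for the CNN.
* **RR features** are in seconds. Edge policy: a record's first beat has
  no previous interval and its last no post interval — both fall back to
  the record mean RR; the local RR averages however many (≤ 10) preceding
  intervals exist, falling back to the record mean when none do. The
  record-wide mean RR subtracted from the interval features uses *all* of
  the record's intervals (the alternative — sinus intervals only — is not
  used, since interval classification is itself the task output). RR
  intervals are computed over every annotated beat, including beats later
  excluded from modelling (a paced beat still carries a real R peak).
  Everything is strictly per record, so no timing statistics cross
  patients or splits.

## Training schedule

Adam (β₁ 0.9, β₂ 0.999, ε 1e−7), batch 512, maximum 50 epochs, initial
learning rate 1e−3 multiplied by 0.1 every 10 epochs (0-based epochs:
decays at 10/20/30/40), l2 penalty 1e−3 applied to convolution and dense
weight kernels only (not biases, not batch-norm parameters). Epochs are
reshuffled from the single run seed; the final partial batch is kept.
Batch-norm uses ε 1e−3 and running-statistics momentum 0.9, which reaches
steady state within the short (10-epoch) schedules used in the tests.
Weight initialization is Glorot-uniform from the run seed; training is
bit-reproducible for a fixed seed on a fixed platform.

## Data accounting (MIT-BIH)

MIT-BIH beat symbols map onto AAMI classes as
N ← {N, L, R, e, j}, SVEB ← {A, a, J, S}, VEB ← {V, E}, F ← {F};
{Q, f, /} are excluded, as is any unrecognized symbol (with a warning).
The four paced records (102, 104, 107, 217) are removed, and the
remaining 44 records form the canonical disjoint DS1 (training) and DS2
(test) sets of 22 records each. The WFDB reader (.hea, format-212 .dat,
.atr) is implemented in this package and round-trip-tested against an
independently written encoder of the same published format; record counts
over the real database additionally verify the published per-split beat
totals when a local copy is present. Beats dropped at record edges (a
handful per record at most) may make edge-sensitive counts differ by a
few beats from published tables, whose edge policy is not documented.

## Synthetic data: what it emulates, and what it does not

The generator exists so that every stage — I/O dialect, baseline removal,
segmentation, RR features, training, inter-patient evaluation — runs and
is tested without any download. Per record it synthesizes:

* beats as sums of Gaussian bumps (P, Q, R, S, T) with class-specific
  parameters: N has the full complex; SVEB has a near-normal QRS with an
  attenuated P wave and, crucially, a shortened preceding RR interval
  (×0.65) followed by a compensatory pause, so its signature is mostly in
  the RR features; VEB is a wide bizarre QRS (broad R, deep S, discordant
  T) with no P; F is the equal-weight superposition of the N and VEB
  shapes — genuinely intermediate, hence the hardest minority class;
* class draws from the benchmark-like imbalance
  (0.895, 0.028, 0.069, 0.008), RR jitter (σ 0.04 s around a 0.8-s mean),
  two-component sinusoidal baseline wander (0.2 mV, periods ≥ 3 s — above
  the 600-ms filter width by construction) and white noise (σ 0.02 mV);
* inter-patient variation via per-record resting rate and amplitude
  scaling (both U(0.85, 1.15)) under independent child seeds, so held-out
  records behave like unseen patients.

Wave widths were chosen so that a clean record (no wander, no noise)
yields a near-zero cascaded-median baseline (< 5% of the R amplitude):
synthetic T and PVC waves must end before the next beat's P begins even
in premature couplets, else waveform — not wander — leaks into the
baseline estimate, which is exactly the failure mode the 200/600-ms
widths are designed to avoid on real ECGs.

What passing on synthetic data shows: the pipeline's plumbing, exact
accounting, gradient correctness, and that the model learns both
morphological and rhythm-borne class signatures from realistic imbalance
under a true inter-patient split. What it does not show: performance on
real ECGs. Real beats have far more within-class morphological diversity,
non-stationary noise, and genuinely ambiguous fusion beats; the synthetic
classes are separable by construction, so synthetic accuracies (≈ 99%)
sit far above the real benchmark (≈ 92.5% overall) and must not be
compared to it.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down conditions chosen as the
package's defaults for desk-scale verification: 18 training and 6 held-out
synthetic patients of 300 s (~6,700 / ~2,300 beats), 10 epochs — enough
for the learning-rate schedule's first stage and stable batch-norm
statistics. The focal-vs-cross-entropy comparison averages the F-class
recall over five seeds; it is a directional check (focal ≥ CE on minority
recall), not a reproduction of the benchmark tables, which would require
the full database and the full 50-epoch schedule. Ties at 100% recall are
common because the synthetic F class, while the hardest, is still
learnable.

Other conventions: 0-based sample indices and half-open windows
everywhere; argmax ties resolve to the lowest class index; F1 is defined
as 0 when PPV + SE = 0; displayed percentages are rounded to two decimals
while all internal comparisons use unrounded values.

## Known limitations

* R-peak detection is out of scope; labeled R peaks are required.
* Only one lead is used; records lacking the requested lead fail loudly
  rather than substituting another.
* The NumPy trainer is single-threaded BLAS-bound; the full 50-epoch,
  100k-beat schedule is feasible but slow compared to GPU frameworks —
  the package is sized for method verification, not production training.
* The α-balanced focal loss is implemented and tested but not the default
  (the plain focal loss with γ = 2 is).
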