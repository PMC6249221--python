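# Methods

## Problem and decision path

An automated external defibrillator (AED) must decide, from a short
single-channel ECG window, whether the rhythm is shockable (SH: ventricular
fibrillation, ventricular tachycardia, ventricular flutter) or non-shockable
(NSH: everything else).  The cost structure is asymmetric — shocking a
non-shockable rhythm can itself induce an arrest — which is why specificity
targets exceed sensitivity targets in AED guidance (Sp >= 95%, Se >= 90%).

The pipeline implemented here classifies one 8-s segment at 250 Hz as:

1. **Preprocessing** — 5-tap centered moving average; 1 Hz high-pass
   (5th-order Butterworth, forward-backward); 30 Hz low-pass (5th-order
   Butterworth, forward-backward).  Output: the pECG.
2. **Channel construction** — modified variational mode decomposition
   (MVMD) of the pECG into 10 modes with six center frequencies pinned at
   {0, 2, 3.5, 5, 6.5, 8} Hz.  The sum of the five nonzero pinned modes is
   the SH signal (VF/VT energy concentrates below 10 Hz, peaking near 4 Hz);
   the sum of the four free modes, whose centers settle above 10 Hz, is the
   NSH signal (QRS complexes peak between 4 and 20 Hz); the 0 Hz mode
   (drift/DC residue) is discarded.
3. **Deep feature learning** — a 1-D CNN over the 3-channel stack
   (pECG, SH, NSH).  The selected network has three sections of
   conv(kernel 101, stride 1, pad 50) + ReLU with 10/20/40 filters, each
   followed by maxpool(11, stride 2); then FC(100) + ReLU + dropout + FC(2).
   Temporal lengths run 2000 -> 995 -> 493 -> 242, so the first FC sees
   242 x 40 = 9680 inputs.  The 100 post-ReLU first-FC activations are the
   deep feature vector.
4. **Secondary classification** — a conventional learner on the feature
   vectors; the default is boosting (AdaBoost, 100 depth-1 trees).  Letting
   an independent learner re-fit the feature geometry outperforms the CNN's
   own softmax ("secondary learning"), chiefly on sensitivity.

## MVMD

Standard VMD minimizes the summed bandwidth of K analytic modes subject to
exact reconstruction, by ADMM in the frequency domain: a Wiener-filter mode
update `u_k <- (x - sum_{i!=k} u_i - lambda/2) / (1 + 2*alpha*(v - w_k)^2)`,
a power-centroid center update, and dual ascent on lambda.  The
modification is that pinned centers are never updated; free centers are
updated but confined to the band above 10 Hz (`free_init_lo_hz`), which
realizes the construction's premise that the free modes model supra-10 Hz
content and prevents a free mode from drifting down to camp on residual
sub-10 Hz energy when the input has little high-frequency power.

Numerical choices:

* `alpha = 2000` (bandwidth penalty on normalized frequency), `tau = 0.1`
  (dual step; tau > 0 enforces reconstruction), `tol = 1e-6` on the total
  relative mode change per sweep, `max_iter = 500`.  Non-convergence returns
  the best iterate with a warning; an all-zero input returns zero modes.
* The signal is mirror-extended by half its length on each side before the
  FFT and modes are cropped back, the standard VMD boundary treatment.
* All spectral work uses the half spectrum of the real signal; every update
  is linear in it, so modes invert to real signals directly.
* Free centers initialize evenly spaced in (10, 100) Hz.

On a 3 Hz + 15 Hz two-tone test the SH/NSH channels correlate > 0.99 with
the respective tones and the reconstruction residual is ~1%.  With an empty
pinned set the algorithm is plain VMD and recovers the tone frequencies of a
clean three-tone signal to < 0.1 Hz, the closed-form expectation.

## Preprocessing details

"Five-order moving average" is read as a 5-tap uniform FIR applied centered
(zero phase).  The high-pass type and both Butterworth orders are design
choices: 5th order, applied forward-backward so QRS morphology is not
phase-distorted; each IIR stage therefore contributes its magnitude
response squared.  Segments are filtered individually (with up to 3 s of
mirrored context on each side, cropped after filtering) — the 1 Hz
zero-phase stage has a multi-second memory, and without context its edge
transients would smear across the whole 8-s window.  The chain's theoretical
composite response is exposed as `chain_gain` and doubles as the test
oracle: 10 Hz passes at ~94% RMS (the moving average accounts for nearly
all of the loss), 0.3 Hz and 45 Hz are attenuated below 4% RMS.

Exclusion rules operate on annotation-derived segment rhythms: noise,
artifact, asystole and transition segments are dropped; VT segments whose
peak-detected rate (rectified signal, 150 ms refractory period) is below
150 beats/min are dropped (no defibrillation benefit); VF segments under
200 uV peak-to-peak are dropped.  The dominant rhythm of a window is the
annotation covering the most samples, ties broken toward shockable.

## CNN family and training

The family is indexed by (Ns, Nd, Lr, Mo, Re).  A block is one
conv + ReLU; section s holds Nd blocks at `10 * 2**(s-1)` filters and ends
in a max-pool.  Re is interpreted as the dropout probability on the first
FC — the published gloss (preventing reliance on single neurons) describes
dropout and the selected values (0.1–0.2) are typical dropout rates.
Training is plain SGD with momentum on softmax cross-entropy (the optimizer
is implied by the momentum parameter), batch size 32, 40 epochs by default,
He initialization, all seeded; `Lr = 0` provably leaves weights untouched.
Convolutions are evaluated by FFT in both passes (kernel 101 makes direct
convolution ~20x more expensive); a numeric-gradient test pins the backward
pass.  A ReLU after the first FC is assumed (the feature vector is read
post-ReLU, dropout disabled); class weighting is available but off by
default.

## Model selection and validation

Fold plans assign whole records (patients) to folds; a runtime guard raises
on any split where a record appears on both sides, and `validate_cv`
refuses an extractor that saw any evaluation record during training.

Grid search scores every configuration by record-wise 5-fold CV on the
training cohort: the fCNN route by the network's own softmax predictions,
and one route per selector classifier (SVM, KNN, RF) trained on fold-train
first-FC features.  The winner per route minimizes mean BER; ties break
toward fewer parameters, then lower learning rate.  A training run that
diverges (non-finite loss) scores BER 100 for that fold rather than
aborting the search.  "Nested" is realized as one inner CV layer inside the
outer grid loop; no second nesting level is used.

Validation extracts features once, then repeats the record-wise 5-fold CV
(fresh seeded fold plan per repetition, classifier retrained per fold,
folds pooled into one confusion table per repetition) and reports
mean ± std over repetitions.  Repetition seeds are `seed + rep` for
auditability.  For the full CNN, validation retrains the network per fold
from its configuration (`validate_fcnn_cv`).

## Synthetic data: what it does and does not show

The generator emulates the *spectral contracts* the method exploits, not
cardiac electrophysiology:

* NSH: Mexican-hat QRS wavelets (~80 ms, 1 mV peak-to-peak, spectral peak
  ~11 Hz, inside the 4–20 Hz QRS band) at 75 beats/min with a few percent
  RR jitter, small P/T bumps, baseline wander (0.05 mV at 0.3 Hz) and
  20 uV Gaussian noise.
* VF: a sinusoid whose instantaneous frequency follows an
  Ornstein–Uhlenbeck walk around 4 Hz (mean reversion 2/s, diffusion
  1 Hz/sqrt(s), clipped to 2–8 Hz) with slow amplitude modulation, 0.5 mV
  peak-to-peak — spectral peak at 4 ± 1 Hz, negligible power above 10 Hz.
* VT: an exactly periodic biphasic wide-complex train, 180 beats/min by
  default.

Record sets draw per-record seeds from one seed sequence; each record holds
a fixed number of segments with an exact per-record shockable count, making
all downstream label bookkeeping checkable by arithmetic.  Because the two
classes differ cleanly in spectral content, the synthetic task is easier
than real arrhythmia data: passing the end-to-end checks demonstrates that
the machinery (filtering, decomposition, feature learning, record-wise
validation) is wired correctly and that the channel construction separates
the bands it claims to separate — it does not certify clinical performance,
which requires the public arrhythmia databases.

## Scaled-down study sizes

The end-to-end checks use 20 records x 20 segments (25% shockable; chosen
as a realistic arrest-database mix), split 10 training / 10 evaluation
records; the extractor is the selected configuration
(Ns=3, Nd=1, Lr=0.005, Mo=0.9, Re=0.15) trained 25 epochs; validation uses
5 folds x 10 repetitions.  The secondary-learning comparison runs 20
replicates, each retraining the full-CNN configuration
(Ns=3, Nd=1, Lr=0.005, Mo=0.7, Re=0.1) for 8 epochs on the replicate's
train split.  Grid-search sanity uses the four selected configurations plus
a deliberately divergent Lr=0.5 variant, 5 inner folds, 4 epochs.  These
sizes are the package's own scaled-down study design; the full published
study (57 patients, 6320 segments, 432-point grids, 100 repetitions)
requires the public databases.

## Known limitations

* The synthetic NSH class is generic; real databases mix sinus rhythm, AF,
  paced rhythms and more, which the generator does not distinguish.
* WFDB binary records are not parsed (CSV is the interchange format); the
  rhythm-code mapping ({VF, VT, VFL} -> shockable, noise/asystole/
  transition -> excluded) is a module-level table rather than a learned
  mapping.
* The exact value lists of the published selection grid are not public;
  the grid is fully configuration-driven here.
* 5-s segments are supported via `seg_len_s`/`input_len` but not separately
  validated.
* Wall-clock latency depends on hardware and is logged, never asserted.
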