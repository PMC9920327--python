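# Methods

## Signal model and conditioning

Records are 15 simultaneous leads (I, II, III, aVR, aVL, aVF, V1–V6,
Vx, Vy, Vz) held in millivolts.  Conditioning is fixed as
band-pass → downsample → lead selection → windowing:

* **Band-pass 0.05–45 Hz**, realized as a 4th-order Butterworth applied
  forward-backward (`sosfiltfilt`).  Only the passband is prescribed by
  the problem; the zero-phase realization is our choice, because phase
  distortion of QRS morphology would corrupt downstream clinical
  reading.  The 0.05 Hz corner implies an impulse response with a tail
  of roughly 20 s, so the first/last few seconds of a filtered record
  carry an unavoidable transient; tests compare filter behaviour on the
  central portion of long records for this reason.
* **Downsampling 1000 → 200 Hz** is plain decimation (every 5th
  sample): the 45 Hz low-pass edge already anti-aliases for a 200 Hz
  rate, and decimating avoids filtering twice.  Non-integer rate ratios
  are an error rather than silently resampled.
* **Lead selection**: inputs are II, V2, V6 (quasi-orthogonal — their
  lead-field rows approximately span the dipole source space); targets
  are the remaining 12 leads in a fixed canonical order.
* **Sliding windows** of 17 s with 16 s overlap (1 s stride) for
  per-patient augmentation.  Window starts are anchored at integer
  samples and fractional durations floor to samples, so the window
  count is exactly `(n − win)//step + 1`.

Records with NaN or flat-line channels are rejected at load with a
diagnostic naming the offending lead — a mechanical generalization of
manually excluding corrupted recordings from a corpus.

The record-level train/test split is uniform random with `|train| =
round(0.8·n)` (546 records → 437/109).  The split is by record by
default, literally as specified for the corpus; a by-patient option
exists because records of one patient straddling the split is a
legitimate leakage concern.

## The LSTM regressor

The derivation network is a stack of standard LSTM cells (gate order
input / forget / cell-candidate / output; no peepholes, no attention)
with a per-time-step affine projection from the top layer to the 12
output channels.  The output head is the minimal choice for
sequence-to-sequence regression; nothing in the problem calls for more.

Initialization:

* input weights per layer: uniform, zero mean, variance
  `2/(fan_in + 4·H)` where `fan_in` is that layer's input width (3 for
  the first layer, the previous hidden width above);
* recurrent weights: orthogonal per gate block — the Q factor of a QR
  decomposition of a unit-normal matrix, with column signs fixed by the
  sign of diag(R) so the draw is unique given the seed;
* forget-gate biases 1, all other biases 0.

The per-sequence loss is `(1/2S)·Σ_t Σ_j (ŷ − y)²` — half the
time-averaged squared error **summed over the 12 channels**, not
averaged over them.  A minibatch contributes the mean of its
per-sequence losses (the per-batch aggregation is our choice; only the
per-sequence form is prescribed).  Gradients are exact
backpropagation through time, verified against central finite
differences to < 1e−4 relative error in float64.  Updates are Adam
with bias correction; the optional "piecewise" schedule multiplies the
learning rate by 0.1 every 10 epochs.  There is no gradient clipping —
instead a divergence guard aborts with an error if the loss becomes
non-finite.  Training runs in float32 (float64 is supported throughout
and used by the oracle-grade tests); minibatches contain only
equal-length windows so no padding or masking exists anywhere.

Generalized training consumes 17 s windows with stride = window (no
overlap) from the training records; uniform sequence length is what
makes minibatching trivial, and the overlap augmentation is reserved
for the per-patient stage where data is scarce.  The validation metric
during training — and the tuning objective — is RMSE in mV pooled over
all sequences, samples and leads.

The shipped default configuration is the tuned 4-layer reference
architecture: hidden units 27/22/23/46, minibatch 27, learning rate
0.028805, no schedule, β₁ = 0.90034, β₂ = 0.9175, 100 epochs.

## Hyperparameter search

Training hyperparameters are tuned by Gaussian-process Bayesian
optimization of the final validation RMSE.  The search space per layer
count: hidden units per layer (integer 10–50, linear), minibatch
(integer 16–32, linear), schedule (categorical none/piecewise),
learning rate (1e−3–1e−1, log), β₁ (0.9–0.999, log), β₂ (0.9–1, log).
The number of layers is *not* a dimension; independent searches run per
layer count 1–5, so a full campaign at budget 50 trains 250 networks.

The surrogate uses the ARD Matérn 5/2 kernel
`σf²(1 + √5r + 5/3 r²)e^{−√5r}` with `r² = Σ_m Δx_m²/σ_m²` over the
transformed unit cube; integers and the 0/1-coded schedule category are
relaxed to continuous values for the GP and rounded/thresholded at
decode (standard practice for mixed spaces).  Kernel amplitude, length
scales and observation-noise SD are refit each iteration by marginal-
likelihood maximization (L-BFGS-B in log space, 3 random restarts) —
the fitting scheme is our choice, as only the kernel family is
prescribed.

Acquisition is closed-form expected improvement against the lowest
posterior mean, maximized over 2 000 uniform candidates followed by a
coordinate-wise local polish of the best 10 (three shrinking grid
sweeps per coordinate, all posterior calls batched).  An exploration
constraint keeps the search from over-refining a basin already resolved
to the noise floor: a candidate is admissible only if its posterior
standard deviation is ≥ 0.8 × the fitted noise SD; when no candidate
passes, the constraint is dropped for that iteration with a logged
warning.  The search starts from 4 uniform points; failed objective
evaluations are logged and excluded from the GP rather than aborting
the search.

## Personalization by transfer learning

A personalized model inherits the generalized model's architecture,
hyperparameters and weights, and continues training (all layers — no
freezing by default, freezing is an option) for the same number of
epochs on one patient's overlap-augmented windows, split 80/20
train/validation by uniform randomization over windows.  The split is
deliberately the literal one — overlapping windows can land on both
sides; a no-leakage `block_split` option holds out a time-contiguous
tail instead.  The fine-tuning learning rate defaults to the parent's
own rate.  The parent checkpoint is never modified, and both the
inherited (epoch-0) and fine-tuned validation RMSE are recorded so the
personalization gain is directly readable.

## Linear baseline

Each derived lead regressed on (II, V2, V6) by least squares through
the thin QR factorization of the design matrix, fit per patient on the
same augmented windows used for personalization.  An intercept column
is included by default (real recordings carry residual baseline
offsets) and can be disabled; near-zero diagonal entries of R raise a
rank-deficiency error naming the collinear column.

## Metrics

RMSE, ρ and R² are implemented in their printed, **uncentered** forms:
ρ = Σŷy/√(Σy²·Σŷ²) and R² = (1 − Σ(ŷ−y)²/Σy²)·100.  For band-passed
(zero-mean) ECG these coincide with the conventional Pearson/centered
definitions; in general they do not, and the reported magnitudes depend
on the uncentered forms, so conventional variants exist only behind an
explicit `centered=True` flag.  R² can be negative; ρ is bounded in
[−1, 1] by Cauchy–Schwarz.  The identity
`R² = (1 − N·RMSE²/Σy²)·100` holds algebraically and is asserted to
1e−10.  Metrics are computed per (record, lead) cell on whole test
records after conditioning — matching how a clinician reads a full
strip, not a training window — and aggregated per lead and overall
(mean, SD, median, quartiles, min, max), all means taken cell-wise.

## Synthetic cohort

The generator emulates what the method needs from real data, with
known ground truth:

* **Source**: a 3-component dipole trajectory; each beat is a sum of
  five Gaussian bumps (P, Q, R, S, T) on a linearly advancing phase,
  each with amplitude, angular width, phase and a fixed 3-D direction;
  RR intervals are normal (mean 60/HR, configurable SD, truncated
  positive).  Defaults: 60 bpm ± 3, amplitudes giving ~1 mV R waves in
  lead II.  The per-record source mean is subtracted — surface ECG is
  AC-coupled and the baseline is arbitrary — which also keeps the
  0.05 Hz high-pass a near-no-op on synthetic data.
* **Lead field**: a 15 × 3 matrix; limb-lead rows lie on their
  conventional frontal-plane axes, precordial rows sweep the transverse
  plane, Vx/Vy/Vz are the source axes.  Rows for II, V2, V6 are
  verified well-conditioned so the inputs carry full source
  information.
* **Nonlinearity**: per-lead saturation `y → tanh(λy)/λ` (identity at
  λ → 0); default λ = 0.5, a mild ~8 % compression at 1 mV —
  enough that the linear baseline is no longer exact, mirroring the
  torso's departure from a linear volume conductor.
* **Noise**: additive white Gaussian, default SD 0.01 mV (10 µV),
  a typical resting-ECG noise floor.
* **Heterogeneity** `h`: per-patient lead-field perturbation of
  Frobenius norm `h·‖base‖`; anatomy varies, source morphology is
  shared — this matches the premise that personalization compensates
  individual anatomy.  `h = 0` means identical physics for all
  patients.  Default records: 3 × 120 s per patient at 1 kHz, echoing a
  corpus averaging ~200 s per recording.

What the generator does **not** emulate: pathological morphologies
(MI, bundle-branch block), electrode motion artefacts, baseline wander,
powerline interference, or within-patient drift over time.  Passing
tests therefore demonstrate the pipeline's correctness and the
direction of the personalization effect under controlled heterogeneity
— not clinical-grade performance on real patients.

## Scaled-down study sizes

The desk-scale comparison uses 8 patients at heterogeneity 0.5 with
1-layer × 16-unit networks trained 15 epochs on 3 × 120 s records —
sizes chosen so the full study runs comfortably on a single CPU while
leaving the personalization effect far larger than seed jitter.  At
these conditions the generalized model plateaus near 60 µV pooled RMSE
(its anatomy mismatch floor) while personalized models reach ~5 µV,
and fine-tuning wins for every patient; only the *direction* of this
comparison is the claim at desk scale, not the magnitudes.

## Numerical choices and limitations

* Kernel matrices get a 1e−10 diagonal jitter (escalated to 1e−6 once
  before failing) ahead of Cholesky factorization.
* GP posterior variances are clipped at zero before the square root.
* WFDB output uses format 16 at 2000 adu/mV (LSB = 0.5 µV, range
  ±16.38 mV); round-trips are exact to half an LSB.  Only format-16
  single-segment records are supported, and amplitude units must be
  resolvable to mV (mV, µV, V).
* Determinism: every stochastic step (splits, initialization,
  shuffling, cohort generation, acquisition candidates) draws from
  numpy's PCG64 `default_rng` with an explicit seed; training is
  bit-reproducible in single-threaded mode, and checkpoints reload
  bit-exactly.
* The LSTM runs on numpy with hand-derived BPTT; it is exact but not
  GPU-accelerated, so full-scale campaigns (100-epoch, 4-layer, 250
  networks) are outside desk scale by design.
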