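# Methods

This note documents the models and procedures implemented in `tugsae`, the
choices that were genuinely open, and what the synthetic cohort does and
does not establish.

## Problem setting

The timed-up-and-go test (TUG) is a standard clinical mobility assessment:
the subject rises from a chair, walks 3 m, turns, walks back and sits
down. The total time is a validated fall-risk proxy for community-dwelling
elderly; we use the published cut-off of 12.47 s (strictly greater ⇒ at
risk). A triaxial accelerometer at the lumbar spine (axes V = vertical,
ML = mediolateral, AP = anteroposterior; 45 Hz) records the movement. The
package compares two ways of classifying a subject's trace:

1. **Feature + LDA baseline** — 15 summary statistics screened by t-test,
   then linear discriminant analysis;
2. **Time–frequency + stacked autoencoder (SAE)** — a complex-Morlet
   energy image per axis, classified by a two-layer sparse autoencoder
   with a softmax head.

Both are evaluated by leave-one-out cross-validation (LOOCV), one subject
held out per fold, with the at-risk class positive.

## Synthetic cohort generator

Clinical TUG recordings of this kind are confidential, so the package
ships a seeded generator whose defaults encode the study conditions the
pipeline assumes. Each cohort has 22 subjects per class. TUG times are
truncated normals — no-risk 9.5 ± 1.2 s truncated at the 12.47 s cut-off,
at-risk 15.5 ± 2.0 s truncated above it — so labels are consistent by
construction. The trace is piecewise-stationary over the five TUG phases
(sit-to-stand, walk-F, turning, walk-B, stand-to-sit; mean duration
fractions 0.12/0.33/0.10/0.33/0.12 with Dirichlet jitter):

* **Walking phases** carry a sinusoid at a per-subject cadence drawn from
  1.5–2.5 Hz on all three axes. Amplitudes are class-dependent with
  no-risk strictly larger on every axis (V 2.0 vs 0.8; ML 1.2 vs 0.8;
  AP 1.7 vs 1.0), reproducing the walking-band energy separation the
  time–frequency analysis targets. The ML axis additionally carries a
  shared 1–1.3 Hz component (amplitude 0.8 in both classes) and a
  2.5–3.5 Hz arm-swing band that is strong only for no-risk subjects
  (1.0 vs 0.2).
* **Transition phases** carry a Gaussian-windowed low-frequency burst on
  the AP axis, stronger for no-risk subjects (2.5 vs 1.2), reflecting
  sit-to-stand/stand-to-sit power.
* Constant per-axis offsets (1.1, 1.0, 1.9) model gravity/posture, and
  15 % of the vertical walking amplitude appears as a DC shift
  (asymmetric vertical loading), which gives the no-risk class the higher
  vertical mean and standard deviation expected of stronger walkers.
* Additive white Gaussian noise, sd 0.25, throughout. Units are
  dimensionless accelerations of order ±1 to ±8; the pipeline is
  scale-covariant up to image normalisation.

The generator is a pure function of its config (including the seed):
identical configs give bit-identical cohorts. What it does **not**
emulate: realistic gait biomechanics (double support, impact transients,
asymmetry), sensor drift or saturation, heteroscedastic noise, or
correlations between axes beyond the shared cadence. Passing tests on
synthetic cohorts therefore demonstrate that the pipeline recovers
band-limited, class-separated spectral structure — the mechanism the
method relies on — not clinical performance on real patients.

## Time–frequency analysis

The complex Morlet wavelet at central frequency f_c is

    w(t, f_c) = A exp(−t² / 2σ_t²) exp(i 2π f_c t),

with constant quality ratio f_c/σ_f = 7, σ_t = 1/(2π σ_f), and
A = (σ_t √π)^{−1/2} (unit energy). Energy is the squared modulus of the
signal–wavelet convolution, swept over 0.05–5 Hz. Numerical choices:

* support truncated at ±6σ_t and sampled at the trace rate (Gaussian tail
  < 1e−8);
* convolution mode "same" with zero padding, via FFT on a power-of-two
  length covering linear convolution with the longest wavelet (the
  frequency-domain filter bank is cached since it is constant within a
  cohort); the discrete sum is scaled by Δt to approximate the integral;
* 100 linear frequency bins (the sweep range is prescribed; the count is
  ours). For a pure sinusoid at f₀ the continuous-frequency peak of
  time-averaged energy sits at ≈ f₀(1 − 1/98) because the unit-energy
  prefactor grows as σ_t ∝ 1/f_c; at f₀ = 4.5 Hz this bias (≈ 0.046 Hz)
  is comparable to the 0.05 Hz bin spacing, so localisation is asserted
  to the nearest-or-adjacent bin;
* rendering: per-image min–max normalisation (a global range is available
  as an option), the fixed "jet" rainbow colormap, bilinear resampling to
  28 × 28 × 3 with time → width and frequency → height (low frequencies at
  the bottom row). All-constant energy maps to the colormap's lowest
  colour. Resampling the time axis to a fixed width is also what maps
  traces of unequal TUG duration onto a common classifier input.

The classifier consumes the numeric [0, 1] array; PNG export is for
inspection only.

## Feature baseline

Per axis over the full trace: mean, standard deviation (divisor T−1),
maximum, minimum, and mean crossing rate. MCR counts consecutive sample
pairs strictly straddling the signal mean, divided by T−1 — a
dimensionless per-sample rate (at 45 Hz a 2 Hz gait gives ≈ 0.09, the
magnitude seen in practice). Screening uses the classic pooled-variance
two-sample Student t-test, two-sided, selecting p ≤ 0.05;
Kolmogorov–Smirnov normality p-values (per class, fitted normal) are
reported alongside but do not gate selection. Selection happens once on
the full table before cross-validation — this mirrors the sequential
protocol the package reproduces and carries the usual optimistic bias;
fold-internal selection would be the defensible alternative for new
studies. LDA uses a shared covariance and empirical class priors; a
singular pooled covariance raises an error suggesting feature reduction.

## Sparse stacked autoencoder

Each autoencoder layer is a logistic-sigmoid encoder/decoder pair trained
by minimising

    E = (1/N) Σ_n Σ_k (x_nk − x̂_nk)² + λ·½ Σ w² + β·Σ_i KL(ρ ‖ ρ̂_i),

where ρ̂_i is neuron i's mean activation over the batch. The L2 term spans
the layer's encoder and decoder weight matrices (biases excluded); the
softmax head is unregularised. Gradients are analytic, including the
sparsity term's dependence of ρ̂ on every example, and are verified
against central finite differences. ρ̂ is clipped to [1e−6, 1−1e−6]
inside the KL term against sigmoid saturation.

Default hyperparameters: n1 = 300, n2 = 30 neurons; λ = 0.004 / 0.002,
ρ = 0.015 / 0.01 for the first/second layer; β = 4 for both.

Training is deterministic and full-batch: seeded symmetric-uniform
fan-scaled initialisation, then scipy's conjugate-gradient or L-BFGS-B
minimiser (`TrainConfig.optimizer`). `convergence_tol` is a gradient-norm
tolerance; for L-BFGS-B the relative-decrease test is disabled because
the supervised phase can start on a plateau. Two numerical hazards are
handled explicitly:

* with β = 4 and small ρ, unsupervised training can drive a layer's codes
  to the constant ρ (the KL-optimal but uninformative solution) — this is
  a genuine optimum of the unsupervised cost at these settings, and it is
  the supervised phase's job to recover discriminative structure from it;
* at such a collapsed code with balanced classes, a zero-initialised
  softmax head sits on an exact saddle of the cross-entropy, so the head
  is initialised with small seeded random weights.

The stack is trained greedily (AE1 on images, AE2 on AE1 codes), the head
is trained with the encoders frozen, and then the whole encoder + head is
fine-tuned on the cross-entropy (`fine_tune=False` disables the last step
for ablation). The supervised loss trace records every cost evaluation,
line-search probes included, so it decreases monotonically only on
average.

The neuron-count grid search (n1 ∈ {100…500}, n2 ∈ {10…30}, ten runs per
cell by default) averages the stacked reconstruction error
x → z1 → z2 → ẑ1 → x̂, reported on the [0, 1] pixel scale as the summed
squared pixel error per example; ties break toward smaller n1, then n2.
Seeds for every cell/run derive from one master seed, making the table
bit-reproducible.

## Evaluation protocol

Per axis and per method, LOOCV trains on n−1 subjects and predicts the
held-out one; the n predictions form a single confusion matrix.
Sensitivity is the true-positive rate of the at-risk class. The full
experiment repeats the (stochastic) SAE training `n_repeats` times with
derived seeds inside the fixed LOOCV scheme and reports mean ± sd per
metric; the LDA branch is deterministic, so its sd is zero. The report is
a pure function of the experiment config.

## Problem sizes in tests and the acceptance script

The cohort-scale checks and the acceptance script run the narrower
100–10 stack with conjugate gradients capped at 20 unsupervised and 40
supervised iterations per phase. These are the package's chosen desk-scale
settings: the 100–10 stack is an explicitly supported configuration of
the architecture, and at the 44-subject scale the capped optimiser
reliably reaches perfect training accuracy while keeping a full LOOCV to
well under a minute per axis. Grid-search tests use small random images
and two runs per cell, which exercises the averaging/reproducibility
contract without the cost of the full ten-run search.

## Known limitations

* Synthetic-cohort results do not transfer to clinical accuracy claims;
  the generator encodes the intended class mechanism by construction.
* Feature selection outside the CV loop is optimistically biased (kept
  for protocol fidelity; documented above).
* The KL-sparsity collapse at β = 4 with small ρ makes headline accuracy
  depend on the supervised phase; reconstruction-quality conclusions at
  these hyperparameters should use the grid-search path, not the
  classifier path.
* LOOCV with a fold-retrained stochastic model is itself noisy; the
  repeat mechanism quantifies training stochasticity, not cohort
  resampling variance.
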