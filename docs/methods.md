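# Methods

`emgangle` estimates the continuous forearm pronation–supination angle from
five-channel surface EMG (sEMG) and corrects the estimate with an extended
Kalman filter (EKF). This note documents the models, the parameters that
matter, the synthetic-data generator, the numerical choices, and the known
limitations.

## Problem setting

A single degree of freedom — forearm rotation from palm-up (supination,
0°) to palm-down (pronation, 180°) — is driven by several muscles at once:
pronator teres and flexor carpi radialis recruit with pronation, supinator
and brachioradialis with supination, and extensor carpi radialis longus
stabilizes. Five surface electrodes over these muscles record
interference-pattern EMG whose amplitude tracks each muscle's activation.
The task is to map windowed features of those signals to the instantaneous
joint angle, as needed for myoelectric exoskeleton control. Two sensor
streams are involved: sEMG at a nominal 1,000 Hz and a reference joint
angle from an attitude sensor at 100 Hz with 0.1° accuracy. Processing is
offline.

Two angle conventions coexist and are related by a fixed +90° offset:
`palm_up_zero` (trial convention, 0–180°) and `neutral_zero` (ergonomic
convention, −90° to +90°). The package keeps all angles in degrees and
treats the offset transform as an exact bijection; the default convention
throughout is `palm_up_zero`.

## Preprocessing

The acquisition chain amplifies 700× and adds a 2.5 V DC offset, so
conditioning is: subtract 2.5 V, FIR bandpass 20–200 Hz, FIR band-stop
48–52 Hz against 50 Hz mains. The gain is a hardware property recorded in
`FilterSpec.gain`; the software chain does not re-apply it (it is available
for synthesizing raw-like inputs).

Numerical choices:

* Bandpass: 256-tap windowed linear-phase FIR (`scipy.signal.firwin`).
  At 1,000 Hz this gives ≥ −3 dB across 30–190 Hz and ≤ −20 dB at 10 Hz
  and 300 Hz.
* Notch: equiripple (Parks–McClellan) band-stop with 4 Hz transitions and
  stop-band weight 5, 257 taps (type-I symmetry is required for unit gain
  at DC and Nyquist). A windowed design of this length cannot realize a
  4 Hz-wide stop band (its transition width is ~13 Hz), which is why the
  notch uses `remez` while the bandpass keeps the simpler windowed design.
* Both filters are applied zero-phase (forward–backward,
  `scipy.signal.filtfilt`) with reflect padding of one filter length,
  since analysis is offline and group delay would misalign features and
  angle targets. Recordings shorter than one filter length are rejected
  rather than silently truncated.

## Features

Each channel of each 250 ms window (stride 125 ms, 50% overlap; a trailing
partial window is dropped) is reduced to three scalars, giving 15 features
for five channels in channel-major order:

* **MAV** `= (1/N) Σ |x(n)|` — the standard sEMG amplitude feature,
  computed on untapered samples.
* **DFT feature** — the in-band (20–200 Hz) spectral centroid (mean
  frequency, Hz) of the Hann-tapered magnitude-squared spectrum. The taper
  reduces leakage; a window with no in-band power returns the 110 Hz band
  midpoint with a logged warning. The underlying transform is the plain
  DFT pair, implemented with `numpy.fft` and verified in the tests against
  a brute-force direct sum.
* **WT feature** — `log(1 + Σ c²)` over the detail coefficients at level 3
  of a `db4` discrete wavelet decomposition in periodization mode
  (orthogonal, so coefficient energy equals band energy). The scalarization
  of the frequency- and time–frequency-domain transforms to one value per
  channel is a design choice of this package (standard sEMG practice);
  both the wavelet and the level are configurable.

Window count bookkeeping: a 5.0 s trial at 1,000 Hz yields 39 overlapping
windows; window centers timestamp the features.

## Regression network

A 15–6–1 feed-forward network: `tansig` (≡ tanh) hidden units, linear
(`purelin`) output. Training is full-batch gradient descent on the MSE
with fixed learning rate 0.01, stopping at goal MSE 0.001 or 10,000
epochs. No momentum by default (configurable), no early stopping beyond
the goal.

Inputs and targets are z-scored with training-set statistics, so the
hidden units operate in their sensitive range (tanh saturates outside
roughly ±2) and the 0.001 goal is on the standardized target scale, where
it means explaining 99.9% of target variance; a 0.001 deg² goal on raw
0–180° targets would be unreachable for noisy data. Standardization can be
disabled. Weights initialize uniformly in ±1/√fan_in from a seeded
generator; training is bit-reproducible given data and seed. Predictions
are de-standardized to degrees and clamped to the active convention's
range.

## Extended Kalman filter

The EKF is derived for general nonlinear state/measurement models
`x_k = f(x_{k−1}, u_{k−1}, w_{k−1})`, `z_k = h(x_k, v_k)` with mutually
uncorrelated noises (means q, r; covariances Q PSD, R positive definite).
First-order Taylor expansion around the last filtered state gives
Φ = ∂f/∂x, Γ = ∂f/∂w, U = f(x̂,u,q) − Φx̂, and around the prediction gives
H = ∂h/∂x, Λ = ∂h/∂v, y = h(x̂⁻,r) − Hx̂⁻; the standard discrete recursion
then runs on the linearized model. Jacobians are analytic when the model
supplies them and central finite differences (step `1e−6·(1+|x|)`)
otherwise. The posterior covariance is symmetrized every step; a
Joseph-form update is available behind a flag.

For angle correction the model is a constant-velocity random walk on
[θ, θ̇] with the network output as a direct angle measurement —
the minimal model consistent with correcting a smooth rotation. Defaults
(all configurable):

* `q_diag = (0.01, 1.0)` — per-step process-noise variance on angle
  (deg²) and angular velocity (deg²/s²) at the 125 ms stride;
* `r = 25` deg² — measurement variance of the network output, matched to
  the few-degree window-to-window scatter observed on synthetic trials;
* `p0_diag = (100, 10⁴)`, `x̂₀ = [z₀, 0]` — a diffuse start. The velocity
  prior is deliberately much wider than the angle prior: the trial rotates
  at 36°/s, and a velocity prior of sd 10°/s is informative enough to drag
  a multi-degree lag over dozens of steps, whereas sd 100°/s lets the
  filter lock onto the ramp within ten steps (a noise-free ramp is tracked
  to better than 0.1° from step 10).

The filter is causal-forward (no backward smoother), run offline over the
window-center sequence.

## Synthetic trials

No public recordings exist for this protocol, so a generator emulates it;
its defaults are the study conditions, not tuning knobs:

* 5.0 s trial, 0→180° at constant speed; reference angle at 100 Hz with
  Gaussian sensor noise of sd 0.1° (the sensor's stated accuracy); sEMG at
  1,000 Hz.
* Each channel: 2.5 V bias + 0.05 V, 50 Hz mains sine + activation-
  modulated band-limited (20–200 Hz) unit-variance Gaussian carrier + a
  fixed band-limited noise floor (sd 0.01 V). This is the standard
  amplitude-modulated interference-pattern model of surface EMG.
* Activation templates are anatomy-informed linear ramps in normalized
  trial phase p: pronator teres and flexor carpi radialis `0.1 + 0.8p`,
  supinator and brachioradialis `0.9 − 0.8p`, extensor carpi radialis
  longus constant 0.2. (Published muscle-function descriptions for this
  movement are partly contradictory; the templates follow standard
  anatomy: the supinator supinates.)
* SNR (default 10 dB; the high-SNR evaluation uses 20 dB) is defined
  in-band as the trial-average power of the activation-modulated component
  over the noise-floor power, at unit subject gain.
* Cohorts: per-subject log-normal per-muscle gain vectors (sd 0.2 on the
  log scale) model inter-individual variation; every trial draws fresh
  noise. All randomness fans out deterministically from one master seed
  via seed sequences, so subsets are stable under dataset-size changes.

What the generator does *not* model: motor-unit action-potential trains,
conduction velocity, fatigue-induced spectral compression, electrode lift
or motion artifacts, cross-talk between channels, and nonstationary mains.
Passing tests on this generator therefore demonstrate that the pipeline's
machinery is correct and that it recovers angle information carried by
amplitude modulation; they do not certify performance on real recordings.

## Evaluation

Tracking error between reference x₁ and estimate x₂ on a common grid (the
reference's 100 Hz timestamps restricted to the estimate's support, linear
interpolation): absolute error `Δ = |x₂ − x₁|` over the full trial;
relative error `δ = |x₂ − x₁|/x₁ × 100%` only over a 1–5 s window, because
early in the trial the reference is near 0° and the ratio degenerates
(a zero reference inside the window is an error, not an infinity).
Per-trial means are averaged over trials, then subjects. The "sd of the
whole process" is defined here as the standard deviation of the signed
error pooled over time, trials, and subjects. Error curves are reported
against movement time normalized to 0–100%.

The experiment design is leave-one-subject-out (LOSO): each subject's
trials are predicted by a network trained on all other subjects'
windows, then Kalman-corrected. Five seeded repetitions of the whole
8-subject × 5-trial experiment are averaged in the headline figures. These
problem sizes (8×5 cohort, 39 windows/trial, 5 repetitions) are the
protocol's own dimensions and keep a full run within a few minutes on one
CPU core.

## Known limitations

* Cross-subject transfer is limited by inter-subject gain variation: a
  ±20% per-muscle amplitude shift is nearly indistinguishable from an
  angle shift of order 10–20° for amplitude-driven features, producing a
  per-subject bias (observed sd ≈ 9° at 20 dB SNR) that neither the
  regressor nor the Kalman filter can remove. Pooled mean errors stay
  well inside the target bounds, but the pooled signed-error sd is
  bias-dominated.
* The Kalman correction helps when the estimation noise is close to white
  (within-subject use); it cannot reduce a constant per-trial offset.
* Full-batch gradient descent at a fixed 0.01 rate converges slowly near
  the optimum; on noisy cohorts training typically uses the whole
  10,000-epoch budget without reaching the 0.001 standardized goal.
* The DFT centroid carries little angle information under this generator
  (the synthetic spectrum's shape is activation-independent); it is
  retained as part of the three-domain feature set, which real sEMG,
  with its activation-dependent spectral shifts, would exploit.
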