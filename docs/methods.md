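# Methods

This note records the models, parameter choices and numerical decisions
behind `neurogait`, and what the synthetic experiments do and do not
demonstrate.

## Signal model

A recording is a channels × samples matrix at fs = 1.81 Hz, the acquisition
rate of the tomography instrument class this protocol assumes. The block
design is 30 s rest, 10 × (10 s walk + 20 s rest), 30 s rest — 300 s of
active protocol in a 360 s session.

The simulated ΔHbO signal per channel is

    amplitude · (boxcar ⊛ h) + Σ sinusoids + drift + white noise,

where `h` is the canonical double-gamma HRF: the difference of gamma
densities with shape parameters 6 (response) and 16 (undershoot), unit
scale, undershoot ratio 1/6, sampled over 30 s and normalized to unit sum.
This is the standard canonical form used by fNIRS/fMRI precoloring
pipelines; with unit scale the kernel peaks near 5 s.

Noise defaults (chosen once as the simulated study conditions; all
configurable, every stochastic call seeded):

| component   | frequency | amplitude (μM) |
|-------------|-----------|----------------|
| cardiac     | 1.2 Hz    | 0.20           |
| respiration | 0.5 Hz    | 0.10           |
| Mayer waves | 0.1 Hz    | 0.15           |
| drift       | —         | 1e-4 /sample   |
| white noise | —         | sd 0.10        |

The task-response amplitude has no canonical published value for treadmill
walking, so it is a free parameter; 1.0 μM is the default "clearly
responsive cortex" condition, giving a regressor correlation near 0.9 per
channel before averaging. ΔHbR is −1/3 of the task component plus
independent noise at one third amplitude; only ΔHbO is analysed downstream.

**Aliasing.** At fs = 1.81 Hz the Nyquist frequency is 0.905 Hz, so a true
1–1.5 Hz cardiac oscillation is not representable; the generator injects it
at its folded frequency |f − fs·round(f/fs)| (1.2 Hz → 0.61 Hz). Any
"heartbeat removal" at this sampling rate necessarily acts on aliased
components; the filter band 0.01–0.5 Hz still excludes the folded cardiac
line.

Channel phases of all sinusoids are independent, so spatial averaging
attenuates oscillatory noise by roughly √12 while preserving the common
task response. This is the main mechanism by which the pipeline reaches
high decoding accuracy at the default contrast.

## Beer–Lambert conversion

`mbll_convert` inverts ΔA = d·l·E·Δc per sample with the 2×2 extinction
matrix E (rows 760/830 nm, columns HbO/HbR). The shipped default matrix
holds widely used Cope-derived coefficients; because published tables vary
in unit convention, the absolute μM scale is not comparable across studies
and every quantitative use should pin its own table (`--extinction-csv`).
Defaults: l = 3 cm, d = 6.0. Forward model and inverse are exact inverses
to machine precision; singular extinction tables are rejected at a 1e-12
determinant threshold.

## Filter bank

All six methods are linear and per-channel.

- **Butterworth**: 4th order, 0.01–0.5 Hz, applied forward–backward
  (`sosfiltfilt`), so it is zero phase and its effective magnitude response
  is |H|². Offline analysis justifies non-causality: features must not be
  lag-shifted relative to the paradigm windows.
- **FIR**: a literal 4th-order (5-tap) FIR cannot realize a 0.01 Hz edge,
  so the design is a window-method band-pass whose default odd tap count
  covers two periods of the low edge (2/0.01 Hz of support); the tap count
  is exposed in the configuration. Also zero phase.
- **Kalman**: scalar random-walk state model x_k = x_{k−1} + w,
  y_k = x_k + v, causal filter, x₀ = first sample, P₀ = r. Defaults
  q = 1e-4, r = 1e-2 (smoothing of slow hemodynamics under measurement
  noise); the steady-state gain is reached within a few samples.
- **Wiener**: short-time Fourier transform (Hann window, 50% overlap,
  perfect-reconstruction inverse) with per-bin gain S/(S+N). N is the mean
  baseline periodogram over a designated rest segment (default: the 30 s
  lead-in); S is the per-frame excess power max(|X|² − N, 0). The default
  window is 16 s so that an integer number of windows fits the baseline.
- **Gaussian**: kernel smoothing with σ = FWHM/2.3548, default FWHM 4 s,
  reflected edges (exact DC preservation).
- **HRF**: convolution with the canonical kernel above (unit sum, reflected
  edges). Smearing the series with the expected response shape is a matched
  temporal prior and is the filter under which decoding is typically best.

## Features and windowing

The 12 channels are averaged, then windowed by session. Whole-session
windows give only 20 observations per subject; sub-windowing (default 6
sub-windows per 10 s task) yields 120 observations, the granularity at
which per-subject accuracies with ~1-point resolution are reportable. Rest
sub-windows are matched to task sub-windows in **both count and duration**:
if rest windows were longer, length-sensitive statistics (variance,
kurtosis, slope) would let a classifier separate the classes with zero
signal. This matters: with length-mismatched windows the zero-contrast
pipeline decodes at ~0.93 "accuracy"; with matched windows it sits at
chance, as it must.

Six statistics per window, all with population (1/N) moments: mean, slope
(least-squares line over time in seconds, so slope is μM/s; a sample-index
axis is available), peak, skewness, non-excess kurtosis (Gaussian → 3) and
variance. Min-max rescaling maps each training column onto [0, 1]; held-out
observations are scaled with the *training* bounds and clipped. Rescaling
globally before cross-validation would leak the test range into training,
so the CV loop refits the bounds per fold.

## Classifiers

- **Fisher LDA** (closed form): v ∝ S_w⁻¹(m₁ − m₂), pooled within-class
  scatter with each class centred on its own mean, unit-norm v, threshold at
  the midpoint of projected class means. A printed variant of the
  within-class scatter that mixes the two class means is treated as a typo
  for the standard form.
- **SVM**: soft margin, kernel (uᵀv + 1)³, C = 0.5 (libsvm via
  scikit-learn). The kernel offset c₀ = 1 and gamma = 1 are the
  plain inhomogeneous-polynomial choice and are configurable.
- **KNN**: Euclidean distances, inverse-rank similarity votes (1, 1/2, …),
  k = 1 by default (pure nearest neighbour). Distance/score ties resolve to
  the lowest-index class, deterministically.
- **QDA**: per-class Gaussian densities with maximum-likelihood (1/N)
  covariances, decision by density ratio against the prior ratio.
- **Naive Bayes**: per-feature class-conditional normals, frequency priors.

Singular scatter/covariance matrices receive a logged ridge of
1e-6·trace/dim; zero-variance features a relative floor. Cross-validation
is stratified, shuffled, seeded, 10-fold. Classifier comparison across
subjects uses a two-sided paired t-test by default (Wilcoxon signed-rank as
an option) at α = 0.01 after Bonferroni correction; which test the original
comparisons used is not documented, so neither is asserted as "the" test.

## Online trigger

The decoder is trained on 9 trials; the unseen trial's decision epoch is
randomly partitioned into 10 disjoint subsets (sizes differing by at most
one). Each subset votes by the majority of its observations' predicted
labels, with ties falling to rest — conservative by design, since the rule
exists to suppress false triggers. The command is `start_gait` iff at least
90% of subsets vote walk; the comparison is inclusive, so 9/10 passes.
With independent per-subset correctness p the trigger probability is the
binomial tail Σ_{j≥9} C(10,j)pʲ(1−p)^{10−j} (0.9139 at p = 0.95), and the
false-trigger probability at rest with 5% subset error is ≈ 2·10⁻¹¹.

Because one 10 s epoch contains only ~6 sub-window observations, the online
stage extracts sliding 3-sample windows (stride 1) over the epoch, giving
16+ observations so the 10-subset vote is well posed; training still uses
the offline sub-window features. Whether the original interface voted on
per-observation labels or per-subset mean features is unknown; both are
implemented (`subset_mode`).

## Leg dynamics

Absolute link angles q = (θ₁, θ₂) from the downward vertical. From the
two-link Lagrangian:

    M = [[m₁r₁² + m₂L₁² + I₁,   m₂L₁r₂ cos(θ₁−θ₂)],
         [m₂L₁r₂ cos(θ₁−θ₂),    m₂r₂² + I₂      ]]
    b = m₂L₁r₂ sin(θ₁−θ₂) · (θ̇₂², −θ̇₁²)
    g = ((m₁r₁ + m₂L₁) g sinθ₁,  m₂r₂ g sinθ₂)

M is symmetric positive-definite everywhere and the Christoffel
factorization satisfies the Ṁ − 2C skew-symmetry property. Generalized
forces conjugate to absolute angles are not the physical actuator torques:
by virtual work, τ_hip = Q₁ + Q₂ and τ_knee = Q₂ (the hip actuator carries
every moment transmitted through the knee — at the horizontal pose the
static hip torque is (m₁r₁ + m₂L₁ + m₂r₂)g, not (m₁r₁ + m₂L₁)g).
`inverse_dynamics` returns joint torques; `generalized_forces` the
Euler-Lagrange forces, which satisfy Q = Mq̈ + b + g identically.

Published torque expressions for this chain frequently carry sign/argument
typos (mixed sin(θ₁±θ₂) forms, stray negated accelerations); the Lagrangian
derivation is authoritative here and is verified against a
finite-difference Euler–Lagrange oracle to 1e-6 relative.

Geometry is fixed (L₁ = L₂ = 0.2 m thigh/shank, 0.03 m pelvic link);
masses and inertias are not part of that specification, so defaults use
anthropometric segment ratios on a 10 kg leg budget: m₁ = 4.5 kg,
m₂ = 2.5 kg, COM at 0.433·L from the proximal joint, moment of inertia
m(0.323·L)² about the COM. Prescribed anchor accelerations and a foot-tip
external force enter as additional generalized forces and default to zero
(their physical interpretation — ground reaction versus tip load — is left
open, so they are off unless configured). There is no ground-contact or
impact model; the base is fixed and the two legs are independent chains,
the right leg's reference phase-shifted by 180°.

Integration is fixed-step classical RK4. At dt = 1 ms a 5 s passive swing
conserves energy to better than 1e-6 relative, which bounds the integration
error budget for all closed-loop claims.

## Reference gait and control

The hip/knee reference is a truncated Fourier stand-in with
literature-typical ranges — hip 5° ± 20° over the stride, knee flexion
25° + two harmonics peaking near 60° in swing, stride period 1.2 s — with
analytic derivatives. It is explicitly *not* a digitized empirical mean
curve; conclusions about tracking therefore concern the controller, not
gait physiology.

The computed-torque law Q = M(q)(q̈* + Kv ė + Kp e) + b + g (+ optional
viscous friction term) is the standard inverse-dynamics controller; a
published variant with an inner term (q̈* + q̇* + q̇) is dimensionally
inconsistent with its own inverse-dynamics form and is resolved to the
standard law. With an exact model the error dynamics are exactly
ë + Kv ė + Kp e = 0 per joint. Default gains Kp = 100·I, Kv = 20·I
(critical damping at ω = 10 rad/s): a 0.3 rad standstill offset then decays
as e(t) = e₀(1 + ωt)e^{−ωt} and crosses 2% at ≈ 0.58 s, well inside the
2.5 s recovery expected of this controller class. "Settling" is
operationalized as the first time the error norm permanently drops below
2% of its initial value (the tolerance behind published "error minimized
within …" statements is rarely stated; 2% is this package's definition,
configurable). Under a 10% plant-mass mismatch the closed loop remains
stable with a residual oscillation of a few degrees — computed torque
degrades gracefully but is not robust control.

During a BCI session, `hold` freezes the reference at the current pose
(gravity-compensated hold) while retaining the gait phase; `start_gait`
resumes phase advance. Phase never rewinds.

## Seeds and problem sizes

A single global seed fans out to per-stage, per-subject seeds through
`numpy.random.SeedSequence([seed, stage, index])`, keeping stages
independently reproducible. Default experiment sizes — 9 subjects ×
6 filters × 5 classifiers × 120 observations for the offline table, 10 000
Bernoulli trials for trigger statistics, 5 s closed-loop simulations at
1 ms — were chosen so the full pipeline completes in well under a minute on
one core while keeping Monte-Carlo error an order of magnitude below every
tolerance tested.

## What the synthetic tests do not show

The generator has no motion-artifact spikes, no serially correlated
physiological noise, no scalp/anatomy variability, and its task response is
time-locked and stationary across trials. Decoding accuracies obtained on
it therefore validate the *pipeline machinery* (windowing, scaling
hygiene, CV stratification, voting arithmetic), not expected performance on
human data; published per-subject accuracies for this paradigm (mean 75%)
sit far below the synthetic default regime, and nothing here claims to
reproduce them.
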