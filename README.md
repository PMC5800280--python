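# neurogait

An end-to-end simulation and analysis framework for functional near-infrared
spectroscopy (fNIRS) brain-computer interfaces that start and stop the gait
cycle of a prosthetic leg. It is aimed at BCI and rehabilitation-robotics
researchers who want a fully testable pipeline — from photon attenuation to
joint torques — without access to subject recordings.

The chain it implements:

1. **Synthetic acquisition** — two-wavelength (760/830 nm) recordings for a
   block protocol of 10 trials × (10 s treadmill walk + 20 s standing rest)
   with 30 s lead-in/lead-out, sampled at 1.81 Hz over a 12-channel, 3 cm
   montage covering left primary motor cortex. The task response is a boxcar
   convolved with the canonical double-gamma hemodynamic response function;
   cardiac, respiratory and Mayer-wave oscillations, drift and white noise
   are superposed (cardiac injected at its aliased frequency, since
   1–1.5 Hz folds over at this sampling rate).
2. **Modified Beer–Lambert law** — ΔHbO/ΔHbR from optical-density changes:
   `[ΔcHbO; ΔcHbR] = E⁻¹ [ΔA(λ₁); ΔA(λ₂)] / (d·l)` with extinction matrix
   `E`, source–detector distance `l` and differential path-length factor `d`.
3. **Filter bank** — Butterworth and FIR band-pass (0.01–0.5 Hz, zero
   phase), random-walk Kalman, STFT Wiener with rest-baseline noise
   estimation, Gaussian-kernel and HRF-kernel smoothing.
4. **Features** — spatial average of all channels, task/rest windowing, and
   six statistics per window: signal mean (SM), slope (SS), peak (SP),
   skewness (SK), kurtosis (KR) and variance (SV), min-max rescaled to
   [0, 1].
5. **Classification** — five scikit-learn-compatible estimators (cubic-kernel
   SVM with C = 0.5, Fisher LDA, rank-similarity KNN with k = 1, Gaussian
   QDA, Gaussian naive Bayes) under stratified 10-fold cross-validation with
   leak-free per-fold rescaling, plus paired-test classifier comparison.
6. **Online trigger** — leave-one-trial-out training, random partition of the
   unseen trial into 10 disjoint subsets, one vote per subset, and a
   "≥ 90% true" gate before any gait command is issued (false triggers at
   rest are suppressed to a binomial-tail probability of ~2·10⁻¹¹ at 5%
   per-subset error).
7. **Leg model and control** — a planar 2-DOF thigh/shank chain (ankle
   fixed, base fixed) with Lagrangian dynamics `M(q)q̈ + b(q,q̇) + g(q) = Q`,
   driven by the PD computed-torque law with gravity compensation
   `Q = M(q)(q̈* + Kv ė + Kp e) + b + g`, which renders the tracking-error
   dynamics exactly linear (`ë + Kv ė + Kp e = 0`) when the model is exact.

## Worked example

```python
import neurogait as ng

paradigm = ng.default_paradigm()      # 10 x (10 s walk + 20 s rest), 1.81 Hz
montage = ng.default_montage()        # 12 channels, 3 cm separation
hbo, hbr = ng.simulate_hbo(paradigm, montage, response_amplitude_uM=1.0,
                           noise=ng.NoiseSpec(seed=0))

od = ng.hemo_to_od(hbo, hbr, ng.DEFAULT_EXTINCTION, 3.0, 6.0)
hbo_rec, _ = ng.mbll_convert(od)      # Beer-Lambert round trip

smoothed = ng.apply_filter(hbo_rec, ng.FilterSpec(method="hrf"))
fm = ng.extract_features(ng.spatial_average(smoothed), paradigm)
report = ng.cross_validate("svm", fm, folds=10, seed=0)
print(f"SVM 10-fold CV accuracy: {100 * report.mean_accuracy:.1f}%")

res = ng.simulate_tracking(ng.GaitTrajectory(), duration_s=5.0,
                           initial_error=0.3)
print(f"2% settling time: {res.settling_time_s:.3f} s")
```

Output:

```
SVM 10-fold CV accuracy: 100.0%
2% settling time: 0.584 s
```

The first line is the cross-validated walk/rest decoding accuracy at the
default synthetic contrast (a 1 μM task response over ~0.1–0.2 μM
physiological noise — an easy regime; at zero contrast the same pipeline
stays at chance). The second is how long the computed-torque controller
takes to bring a 0.3 rad joint offset below 2% of its initial size while
tracking the reference gait — comfortably inside the 2.5 s bound expected
of this controller family.

The same stages are scriptable from a shell:

```bash
neurogait simulate --seed 0 subject.csv
neurogait filter --method hrf subject.csv smoothed.csv
neurogait features smoothed.csv features.csv
neurogait classify --clf svm features.csv
neurogait run-all -o runs/demo          # full pipeline, all artifacts
```

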