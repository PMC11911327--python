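# Methods

This note documents the models, defaults and design decisions behind
`kneetorque`, in the order the pipeline runs.

## Signal conditioning

Raw sEMG of the seven knee-crossing muscles (medial/lateral gastrocnemius,
biceps femoris, semitendinosus, rectus femoris, vastus medialis, vastus
lateralis; 1,500 Hz) is processed per channel:

1. band-pass 20–450 Hz;
2. full-wave rectification;
3. low-pass 6 Hz (linear envelope), clipped at zero;
4. division by the peak of the identically processed MVIC reference, so 1.0
   means maximal voluntary effort;
5. linear-interpolation resampling onto the kinematic clock (100 Hz default).

Only the cutoff frequencies are prescribed by the method; the realization is
a design choice: 4th-order Butterworth filters applied forward-backward
(zero phase, reflected-edge padding), because zero-phase filtering keeps the
envelope aligned with the torque target, and the MVIC statistic is the peak
of the *processed* MVIC envelope so numerator and denominator share units.
The first and last 0.1 s of each aligned envelope are flagged as filter
transients and excluded from windowing and scoring.

## Hill-type NMS solver

A deliberately simplified, convex-calibratable EMG-driven muscle model:

* **Activation dynamics**: explicit-Euler integration of
  `da/dt = (u − a)/τ`, with `τ = τ_act` when `u > a` (default 15 ms) and
  `τ_deact` otherwise (default 50 ms), clipped to [0, 1], then the shape
  nonlinearity `a' = (e^{Aa} − 1)/(e^A − 1)` with `A = −1.5` (A → 0 is the
  identity). At 100 Hz and τ ≥ 15 ms Euler is stable (τ/Δt ≥ 1.5).
* **Force**: isometric Hill form `F = F_max · a' · exp(−((l̃−1)/w)²)`,
  Gaussian force-length width `w = 0.45`, rigid tendon, **no force-velocity
  term**. The simplification keeps per-subject calibration a bounded linear
  least-squares problem; force-velocity is an extension hook, not a claim.
* **Geometry**: normalized fiber length affine in knee flexion angle,
  `l̃ = 1 + k(θ − 45°)/90`, with per-muscle `k` (|k| ≤ 0.25; positive for
  extensors, negative for flexors); moment arms affine in angle (extensors
  a0 = 0.045 m, a1 = −2·10⁻⁴ m/deg; flexors a0 = 0.030 m,
  a1 = +1·10⁻⁴ m/deg). Extension torque is positive.
* **Calibration**: gains `g_m ∈ [0.25, 4]` on `F_max·r_m` products fitted by
  bounded least squares (`scipy.optimize.lsq_linear`) against measured
  isometric torque over ≥ 2 trials spanning ≥ 2 angles with both flexion and
  extension efforts. A muscle that never activates has a zero design column;
  it is flagged unidentifiable and keeps `g = 1`. The fitted gains absorb
  both true strength differences and the EMG-gain/envelope scale factor —
  exactly the role of individual calibration.

## Network

Input windows are 15 samples × C channels at 100 Hz (150 ms, stride 1,
causal: the target is the torque at the final sample, in Nm/kg so the MSE
loss is already body-mass normalized). C = 8 for the standard variant
(7 envelopes + θ/90) and 15 for the hybrid variant (+ 7 normalized forces
F/F_max from the calibrated solver). Only the kernel (3×3) and pooling
window (2×2) are prescribed; the remaining architecture is a default chosen
as the smallest configuration honoring alternating conv/pool stages: two
conv blocks (16 then 32 filters, same padding, ReLU, 2×2 max pool), the
pooled maps read time-major into a 64-unit GRU, additive
(tanh-scored softmax) attention over all hidden states, dense 64 → 1.
Additive attention is itself a design choice — the mechanism is named by the
method but not formulated.

The implementation is plain NumPy (float64) with hand-derived backward
passes; correctness rests on finite-difference gradient checks and
brute-force per-layer oracles in the test suite. Initialization is
variance-scaled uniform from a seeded generator; training is mini-batch
Adam (lr 1e-3, batch 512 — reduced to the dataset size when smaller), MSE
loss, ≤ 1000 epochs with patience-based early stopping on a held-out
validation trial, returning the best-validation weights. Everything is
driven by explicit seeds; two identical runs are bit-identical.

**Transfer learning**: the final (output) dense layer is reinitialized from
a seed; a single Adam optimizer at 1e-4 then fine-tunes *all* layers on the
target subject's adaptation trial, with early stopping on the last 20% of
that trial (temporal split — the protocol reserves the remaining trials for
testing, so validation must come from the adaptation trial itself). An
optional head-only warmup phase exists but is off by default. Fine-tuning on
a subject that contributed to pre-training is a protocol error.

## Evaluation protocols

* **Intra-subject**: per case (training movement), 2 trials train, 1
  validates; the model is tested on all trials of the other movements.
  Cases with < 3 trials are skipped with a log entry.
* **Inter-subject (LOSO)**: per fold and movement, all other subjects'
  trials train (the last trial of the last training subject validates);
  without transfer the pre-trained model predicts the test subject's
  held-out trials directly, with transfer it first adapts on the test
  subject's first trial. Both arms share the pre-trained weights and the
  same test trials, so they are directly comparable.
* **Reporting**: RMSE is computed over the concatenated test windows of a
  (subject, movement) cell, then averaged across subjects; paired
  comparisons use a two-sided paired t-test on per-subject mean RMSE at
  p < 0.05, without multiple-testing correction. Degenerate (zero-variance)
  differences are flagged instead of reporting a p-value.
* **Leakage**: split plans assert that test trials never appear in train,
  validation or adaptation sets, and windowed datasets are checked for
  disjoint (subject, trial) pairs.

## Synthetic cohort

The simulator emulates the *structure* the method assumes, not any real
recording:

* **Subjects**: body mass ~ N(70.9, 7.0²) kg truncated to [55, 90];
  per-muscle F_max log-normally dispersed (σ_log = 0.2) around canonical
  means; per-muscle EMG gains ~ U(0.7, 1.3). These differences make the
  envelope→torque map subject-specific — the premise transfer learning
  exploits.
* **Movements**: treadmill gait at 0.8/1.2/1.4 m/s (cycle periods
  1.4/1.1/1.0 s) with a two-bump knee trajectory (≈15° stance bump at 15%
  cycle, ≈60° swing bump at 72%, bounded in [0°, 70°]); isometric
  flexion-extension holds at 30–90° (12 s: submaximal extension effort then
  flexion effort, 0.5 s ramps, ~4 s holds); one MVIC trial per subject (all
  muscles ramp to 1.0, 5 s hold at 60°).
* **Excitations**: per-muscle Gaussian burst mixtures over the gait cycle
  (extensors early stance, plantar flexors at push-off, hamstrings late
  swing), scaled with speed; plus a 0.02 baseline. Isometric effort
  amplitudes vary smoothly and *differently per muscle* with joint angle —
  without this, same-group muscles would share one template and their
  calibration gains would be unidentifiable (collinear design columns).
* **Signals**: torque = Hill-solver torque from the true activations +
  N(0, 2 Nm) noise (noise floor ≈ 0.03 Nm/kg); raw EMG = gain ×
  excitation × band-limited (20–450 Hz) unit-variance noise carrier +
  2%-of-gain baseline noise, at 1,500 Hz. EMG and kinematics are stored as
  separate trials sharing t = 0, so the alignment path is always exercised.
* **Identifiability by construction**: the stored noise-free torque is an
  exact function of the stored ground-truth forces and angles, so a
  learner's irreducible error is the injected noise; and the force features
  carry activation-dynamics lag and force-length scaling absent from the
  envelope, which is why the hybrid variant has an information advantage
  (verified by a linear-probe test).

What the simulator does **not** model: biomechanically validated gait
curves, ground reaction forces, co-contraction strategies, electrode
placement variability, motion artefact, or fatigue. Passing tests therefore
demonstrate the pipeline's correctness and the direction of its effects
under the stated assumptions, not clinical performance on human data.

## Problem sizes and numerical choices

End-to-end tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which the studied effects are stable: intra-subject runs
use 1–2 subjects with 3 × 20 s (tests) or 3 × 15 s (acceptance script) gait
trials per speed, a reduced network (8/16 conv filters, GRU 32, attention
32, dense 32), ≤ 60 epochs, and stride-2 training windows (test windows are
always stride 1). Direction checks (hybrid vs standard; transfer vs none)
aggregate 5 cohort seeds; the transfer check uses 4-subject LOSO with 8 s
trials, a further reduced network (4/8 filters, GRU 16) and ≤ 400 fine-tune
epochs (many cheap epochs are needed because the reinitialized head trains
at 1e-4 on a single small batch per epoch). Tolerances: layer oracles agree
to ≤ 1e-8 relative, the RMSE formula to 1e-12; storage round trips are
exact because floats are written with 17 significant digits.

## Known limitations

* The Hill solver is isometric (no force-velocity, rigid tendon, no
  pennation); during fast gait its force estimates are biased — acceptable
  here because the network treats them as features, not truth.
* Explicit-Euler activation dynamics assume the kinematic rate is fast
  relative to τ; below ~50 Hz a smaller step or exact discretization would
  be needed.
* The affine moment-arm and fiber-length models are the smallest
  angle-dependent forms, not regression fits to anatomy.
* Training is CPU NumPy: practical for the desk-scale studies here, not for
  paper-scale hyperparameter searches.
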