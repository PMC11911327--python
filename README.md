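# kneetorque

EMG-driven prediction of knee joint torque with a hybrid CNN-GRU-Attention
network, a simplified Hill-type neuromusculoskeletal (NMS) solver, and
subject-to-subject transfer learning.

## The problem

Net knee torque is a key quantity in rehabilitation, injury prevention and
exoskeleton control, but measuring it requires inverse dynamics over motion
capture and force plates. Surface EMG (sEMG) is cheap and wearable, and muscle
electrical activity is causally upstream of joint torque — yet the mapping
from sEMG to torque is nonlinear, delayed, and subject-specific. This package
implements a hybrid approach for researchers in neuromusculoskeletal
biomechanics:

1. **Signal conditioning** — raw sEMG (7 knee-crossing muscles, 1,500 Hz) is
   band-pass filtered (20–450 Hz), full-wave rectified, low-pass filtered at
   6 Hz into a linear envelope, normalized to the maximal voluntary isometric
   contraction (MVIC) reference, and aligned to the kinematic clock (100 Hz).
2. **Hill-type NMS solver** — envelopes drive first-order
   excitation-to-activation dynamics ``da/dt = (u − a)/τ(u, a)`` followed by an
   exponential shape nonlinearity; isometric muscle force is
   ``F = F_max · a · exp(−((l̃ − 1)/w)²)`` with normalized fiber length affine
   in knee angle; torque is ``τ = Σ_m s_m r_m(θ) F_m`` with affine moment arms
   ``r_m(θ)`` and sign ``s_m`` (+1 extensor). Per-subject gain scales on
   ``F_max`` are calibrated by bounded linear least squares against measured
   isometric torque.
3. **CNN-GRU-Attention regressor** — sliding windows (time × channels) pass
   through 3×3 convolutions with ReLU and 2×2 max pooling, a GRU
   (``r_t = σ(ω_r·[h_{t−1}, x_t])``, ``z_t = σ(ω_z·[h_{t−1}, x_t])``,
   ``h̃_t = tanh(ω·[r_t∗h_{t−1}, x_t])``, ``h_t = (1−z_t)∗h_{t−1} + z_t∗h̃_t``),
   additive attention pooling (``α = softmax(v·tanh(W h_t + b))``) and dense
   layers to the torque at the window's final sample, in Nm/kg. The **hybrid**
   variant feeds envelopes + knee angle + the 7 calibrated normalized muscle
   forces (15 channels); the **standard** variant omits the forces (8 channels).
   Training: Adam (1e-3), batch 512, MSE loss, early stopping.
4. **Transfer learning** — for a new subject, the pre-trained model's final
   dense layer is reinitialized and the whole network fine-tunes at 1e-4 on
   one trial of the new subject.
5. **Evaluation** — intra-subject and leave-one-subject-out (LOSO)
   inter-subject protocols with body-mass-normalized RMSE and paired t-tests,
   plus structural leakage checks.

No public dataset accompanies the method, so the package bundles a seeded
synthetic multi-subject simulator (`kneetorque.synthetic`) whose trials have
the statistical structure the method assumes; ground-truth activations,
forces and noise-free torque are retained as test oracles.

The network is implemented directly in NumPy (hand-written forward and
backward passes, verified against finite differences and brute-force layer
oracles), so the whole pipeline is dependency-light and exactly reproducible
from a single seed.

## Worked example

```bash
kneetorque simulate --n-subjects 2 --seed 42 --out-dir ds --gait-duration 10
kneetorque evaluate --manifest ds/manifest.yaml --scenario intra \
    --variant hybrid --max-epochs 30 --train-stride 2 --out-dir out
```

The second command runs, per subject, one case per gait speed: a hybrid
model trains on two trials of that speed (a third validates) and is tested
on every other movement. It prints the long-format report; the
`gait_self`-case gait rows, for example:

```
scenario subject      case  movement  model  rmse_nmkg  n_windows
   intra     S01 gait_self gait_fast hybrid   0.078371       2928
   intra     S01 gait_self gait_slow hybrid   0.154357       2928
   intra     S02 gait_self gait_fast hybrid   0.110591       2928
   intra     S02 gait_self gait_slow hybrid   0.154254       2928
```

Each row is the concatenated-window RMSE between predicted and measured
torque for one (subject, test movement) cell, normalized by that subject's
body mass: ≈0.08–0.15 Nm/kg on unseen gait speeds, against a gait torque
signal whose standard deviation is ≈0.4 Nm/kg and a simulator noise floor of
≈0.03 Nm/kg. (Isometric test rows show much larger errors — a gait-trained
model has never seen sustained holds, the same cross-task degradation the
protocol is designed to expose.) The report is also written to
`out/report.csv` together with `out/run.json` (seed and configuration hash
for provenance).

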