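"""Seeded synthetic multi-subject gait / isometric trial generator.

Emulates the statistical structure the torque-prediction method assumes,
without claiming to reproduce any real recording:

* a cohort of subjects with body mass ~ Normal(70.9, 7.0) kg truncated to
  [55, 90], per-muscle maximum isometric forces log-normally dispersed
  (sigma_log = 0.2) around canonical means, and per-muscle EMG gains
  ~ Uniform(0.7, 1.3) — the inter-subject variation that motivates transfer
  learning;
* treadmill gait at 0.8 / 1.2 / 1.4 m/s (cycle periods 1.4 / 1.1 / 1.0 s)
  with a two-bump knee-flexion trajectory (stance bump ~15 deg near 15% of
  the cycle, swing bump ~60 deg near 72%), and isometric flexion-extension
  holds at 30–90 deg;
* per-muscle excitation templates (Gaussian burst mixtures over the gait
  cycle; ramp-hold efforts for isometric trials) driving the Hill-type
  solver of :mod:`kneetorque.nms`, so the stored torque is exactly the
  moment-arm-weighted sum of muscle forces plus Gaussian noise;
* raw sEMG at 1,500 Hz synthesized as the excitation-modulated, band-limited
  (20–450 Hz) unit-variance noise carrier plus baseline noise.  Kinematics
  and torque are stored at 100 Hz as a separate trial sharing t = 0, so the
  alignment path of the processing chain is always exercised.

Ground-truth activations, forces and noise-free torque are retained with
each generated trial so they can serve as oracles in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from . import nms
from .io_formats import (
    ANGLE_CHANNEL,
    GAIT_MOVEMENTS,
    ISO_MOVEMENTS,
    MUSCLES,
    TORQUE_CHANNEL,
    DatasetManifest,
    SubjectInfo,
    TimeSeriesTrial,
    TrialEntry,
    TrialRecord,
    save_manifest,
)

EMG_RATE_HZ = 1500.0
KINEMATIC_RATE_HZ = 100.0

#: Cohort body-mass distribution (kg), truncated to [55, 90].
BODY_MASS_MEAN_KG = 70.9
BODY_MASS_SD_KG = 7.0
BODY_MASS_BOUNDS_KG = (55.0, 90.0)
#: Log-normal dispersion of per-subject maximum isometric force.
FMAX_SIGMA_LOG = 0.2
#: Per-muscle EMG gain range.
EMG_GAIN_RANGE = (0.7, 1.3)
#: Baseline EMG noise SD as a fraction of the channel gain.
EMG_NOISE_FRAC = 0.02
#: Torque measurement noise SD (Nm).
TORQUE_NOISE_SD_NM = 2.0

GAIT_SPEED_MS = {"gait_slow": 0.8, "gait_self": 1.2, "gait_fast": 1.4}
GAIT_PERIOD_S = {"gait_slow": 1.4, "gait_self": 1.1, "gait_fast": 1.0}
ISO_ANGLE_DEG = {"iso_30": 30.0, "iso_45": 45.0, "iso_60": 60.0, "iso_75": 75.0, "iso_90": 90.0}

# Gait excitation templates: per muscle a list of (center phase, width, amplitude)
# Gaussian bursts over the cycle. Extensors burst in early stance (with a small
# pre-swing burst for rectus femoris), plantar flexors at push-off, hamstrings
# in late swing with a touch of early-stance co-contraction.
_GAIT_TEMPLATES: dict[str, list[tuple[float, float, float]]] = {
    "gastroc_med": [(0.40, 0.10, 0.70)],
    "gastroc_lat": [(0.42, 0.09, 0.55)],
    "biceps_fem": [(0.92, 0.08, 0.50), (0.05, 0.06, 0.20)],
    "semitend": [(0.88, 0.07, 0.45), (0.03, 0.06, 0.20)],
    "rectus_fem": [(0.10, 0.07, 0.55), (0.65, 0.06, 0.25)],
    "vastus_med": [(0.12, 0.08, 0.65)],
    "vastus_lat": [(0.13, 0.09, 0.60)],
}

_EXC_BASELINE = 0.02

ISO_DURATION_S = 12.0
MVIC_DURATION_S = 6.0
MVIC_ANGLE_DEG = 60.0
#: Submaximal effort level of calibration (isometric) trials.
ISO_EFFORT = 0.7


@dataclass
class SubjectProfile:
    subject_id: str
    body_mass_kg: float
    muscles: list[nms.MuscleParams]
    emg_gain: dict[str, float]
    emg_noise_sd: dict[str, float]
    torque_noise_sd_nm: float
    seed: int


@dataclass
class MovementScenario:
    movement: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.movement in GAIT_SPEED_MS:
            self.kind = "gait"
            self.speed_ms = GAIT_SPEED_MS[self.movement]
            self.cycle_period_s = GAIT_PERIOD_S[self.movement]
        elif self.movement in ISO_ANGLE_DEG:
            self.kind = "isometric"
            self.angle_deg = ISO_ANGLE_DEG[self.movement]
        elif self.movement == "mvic":
            self.kind = "mvic"
            self.angle_deg = MVIC_ANGLE_DEG
        else:
            raise ValueError(f"unknown movement {self.movement!r}")


def sample_cohort(n_subjects: int, cohort_seed: int) -> list[SubjectProfile]:
    """Draw a reproducible cohort of mutually distinct subject profiles."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(cohort_seed)
    subject_seeds = ss.spawn(n_subjects)
    canonical = nms.default_muscle_params()
    profiles = []
    for i, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        lo, hi = BODY_MASS_BOUNDS_KG
        mass = float(rng.normal(BODY_MASS_MEAN_KG, BODY_MASS_SD_KG))
        while not (lo <= mass <= hi):
            mass = float(rng.normal(BODY_MASS_MEAN_KG, BODY_MASS_SD_KG))
        muscles = [
            replace(p, f_max=p.f_max * float(np.exp(rng.normal(0.0, FMAX_SIGMA_LOG))))
            for p in canonical
        ]
        gains = {m: float(rng.uniform(*EMG_GAIN_RANGE)) for m in MUSCLES}
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                body_mass_kg=mass,
                muscles=muscles,
                emg_gain=gains,
                emg_noise_sd={m: EMG_NOISE_FRAC * gains[m] for m in MUSCLES},
                torque_noise_sd_nm=TORQUE_NOISE_SD_NM,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


def _bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    # Gaussian bump on the unit circle (periodic in phase).
    d = np.abs(phase - center)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / width) ** 2)


def knee_angle_trajectory(scenario: MovementScenario, t: np.ndarray) -> np.ndarray:
    """Knee flexion angle (degrees): two-bump gait pattern or constant hold."""
    t = np.asarray(t, dtype=float)
    if scenario.kind != "gait":
        return np.full(t.shape, scenario.angle_deg)
    phase = (t / scenario.cycle_period_s) % 1.0
    return 15.0 * _bump(phase, 0.15, 0.08) + 60.0 * _bump(phase, 0.72, 0.10)


def _ramp_hold(t: np.ndarray, start: float, stop: float, amp: float, ramp: float = 0.5) -> np.ndarray:
    up = np.clip((t - start) / ramp, 0.0, 1.0)
    down = np.clip((stop - t) / ramp, 0.0, 1.0)
    return amp * np.minimum(up, down)


def _iso_amplitude(muscle_index: int, angle_deg: float) -> float:
    # Recruitment varies smoothly with joint angle and differs per muscle so
    # the calibration design matrix is well conditioned (no two muscles share
    # one template across angles).
    theta = np.deg2rad(angle_deg)
    return ISO_EFFORT * (0.6 + 0.4 * np.sin(1.3 * theta + 0.9 * muscle_index) ** 2)


def excitation_profiles(scenario: MovementScenario, t: np.ndarray) -> np.ndarray:
    """Per-muscle neural excitation in [0, 1], shape (time x 7)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros((t.shape[0], len(MUSCLES)), dtype=float)
    if scenario.kind == "gait":
        phase = (t / scenario.cycle_period_s) % 1.0
        scale = min(1.2, scenario.speed_ms / 1.2)
        for j, name in enumerate(MUSCLES):
            for center, width, amp in _GAIT_TEMPLATES[name]:
                out[:, j] += amp * scale * _bump(phase, center, width)
    elif scenario.kind == "mvic":
        # all muscles ramp to maximum and hold 5 s
        u = _ramp_hold(t, 0.5, MVIC_DURATION_S - 0.1, 1.0)
        out[:] = u[:, None]
    else:
        # isometric flexion-extension: extensors effort first, flexors second
        for j, name in enumerate(MUSCLES):
            amp = _iso_amplitude(j, scenario.angle_deg)
            if nms.MUSCLE_ACTION_SIGN[name] > 0:
                out[:, j] = _ramp_hold(t, 0.5, 5.5, amp)
            else:
                out[:, j] = _ramp_hold(t, 6.5, 11.5, amp)
    return np.clip(out + _EXC_BASELINE, 0.0, 1.0)


def synthesize_emg(
    excitation: np.ndarray,
    t_excitation: np.ndarray,
    t_emg: np.ndarray,
    gain: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplitude-modulated band-limited carrier surrogate for raw sEMG.

    ``raw = gain * excitation_upsampled * carrier + baseline``, where the
    carrier is 20–450 Hz band-limited unit-variance noise — zero-mean, so
    the conditioning chain's rectification stage is meaningful.
    """
    fs = 1.0 / float(np.median(np.diff(t_emg)))
    exc_up = np.interp(t_emg, t_excitation, np.asarray(excitation, float))
    carrier = rng.standard_normal(t_emg.shape[0])
    sos = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, carrier)
    std = carrier.std()
    if std > 0:
        carrier = carrier / std
    noise = noise_sd * rng.standard_normal(t_emg.shape[0]) if noise_sd > 0 else 0.0
    return gain * exc_up * carrier + noise


@dataclass
class GeneratedTrial:
    record: TrialRecord
    truth: dict[str, np.ndarray] = field(default_factory=dict)


def generate_trial(
    profile: SubjectProfile,
    scenario: MovementScenario,
    seed: int,
    trial_id: str | None = None,
    torque_noise_sd_nm: float | None = None,
    emg_noise: bool = True,
) -> GeneratedTrial:
    """One trial: EMG at 1,500 Hz plus kinematics/torque at 100 Hz.

    The stored torque is the Hill-solver torque from the ground-truth
    activations plus Gaussian measurement noise; the noise-free torque,
    activations, forces and excitations are retained in ``truth``.
    """
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(child) for child in ss.spawn(len(MUSCLES) + 1)]
    dur = scenario.duration_s
    n_kin = int(round(dur * KINEMATIC_RATE_HZ))
    t_kin = np.arange(n_kin) / KINEMATIC_RATE_HZ
    n_emg = int(round(dur * EMG_RATE_HZ))
    t_emg = np.arange(n_emg) / EMG_RATE_HZ

    theta = knee_angle_trajectory(scenario, t_kin)
    exc = excitation_profiles(scenario, t_kin)

    act = np.empty_like(exc)
    force = np.empty_like(exc)
    for j, p in enumerate(profile.muscles):
        act[:, j] = nms.excitation_to_activation(exc[:, j], KINEMATIC_RATE_HZ, p)
        l_norm = nms.fiber_length_from_angle(theta, p)
        force[:, j] = nms.muscle_force(act[:, j], l_norm, p)
    series = nms.MuscleForceSeries(
        muscle_names=list(MUSCLES),
        activation=act,
        force_n=force,
        force_normalized=force / np.array([p.f_max for p in profile.muscles]),
    )
    torque_true = nms.joint_torque_from_muscles(series, theta, profile.muscles)
    noise_sd = profile.torque_noise_sd_nm if torque_noise_sd_nm is None else torque_noise_sd_nm
    torque = torque_true + (rngs[-1].normal(0.0, noise_sd, n_kin) if noise_sd > 0 else 0.0)

    emg = np.empty((n_emg, len(MUSCLES)), dtype=float)
    for j, name in enumerate(MUSCLES):
        emg[:, j] = synthesize_emg(
            exc[:, j],
            t_kin,
            t_emg,
            profile.emg_gain[name],
            profile.emg_noise_sd[name] if emg_noise else 0.0,
            rngs[j],
        )

    tid = trial_id or f"{profile.subject_id}_{scenario.movement}"
    emg_trial = TimeSeriesTrial(
        subject_id=profile.subject_id,
        movement=scenario.movement,
        sampling_rate_hz=EMG_RATE_HZ,
        channel_names=list(MUSCLES),
        time_s=t_emg,
        data=emg,
        name=f"{tid}_emg",
    )
    kin_trial = TimeSeriesTrial(
        subject_id=profile.subject_id,
        movement=scenario.movement,
        sampling_rate_hz=KINEMATIC_RATE_HZ,
        channel_names=[ANGLE_CHANNEL, TORQUE_CHANNEL],
        time_s=t_kin,
        data=np.column_stack([theta, torque]),
        name=f"{tid}_kin",
    )
    role = "mvic_reference" if scenario.movement == "mvic" else "train"
    record = TrialRecord(
        trial_id=tid,
        subject_id=profile.subject_id,
        movement=scenario.movement,
        role=role,
        emg=emg_trial,
        kinematics=kin_trial,
    )
    truth = {
        "excitation": exc,
        "activation": act,
        "force_n": force,
        "torque_true_nm": torque_true,
        "theta_deg": theta,
        "time_s": t_kin,
    }
    return GeneratedTrial(record=record, truth=truth)


def generate_records(
    n_subjects: int,
    cohort_seed: int,
    gait_movements: tuple[str, ...] = GAIT_MOVEMENTS,
    iso_movements: tuple[str, ...] = ISO_MOVEMENTS,
    gait_trials: int = 3,
    iso_trials: int = 1,
    gait_duration_s: float = 20.0,
) -> tuple[DatasetManifest, list[TrialRecord], dict[str, dict[str, np.ndarray]]]:
    """In-memory dataset: manifest + loaded records + per-trial ground truth."""
    profiles = sample_cohort(n_subjects, cohort_seed)
    ss = np.random.SeedSequence(cohort_seed + 1)
    records: list[TrialRecord] = []
    truths: dict[str, dict[str, np.ndarray]] = {}
    entries: list[TrialEntry] = []

    def add(profile, scenario, tid, seed):
        gen = generate_trial(profile, scenario, seed, trial_id=tid)
        records.append(gen.record)
        truths[tid] = gen.truth
        entries.append(
            TrialEntry(
                trial_id=tid,
                subject_id=profile.subject_id,
                movement=scenario.movement,
                role=gen.record.role,
                emg_path=f"{tid}_emg.sto",
                kinematics_path=f"{tid}_kin.sto",
            )
        )

    for profile in profiles:
        seeds = iter(int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(256))
        add(profile, MovementScenario("mvic", MVIC_DURATION_S), f"{profile.subject_id}_mvic_01", next(seeds))
        for mv in iso_movements:
            for k in range(iso_trials):
                add(profile, MovementScenario(mv, ISO_DURATION_S),
                    f"{profile.subject_id}_{mv}_{k + 1:02d}", next(seeds))
        for mv in gait_movements:
            for k in range(gait_trials):
                add(profile, MovementScenario(mv, gait_duration_s),
                    f"{profile.subject_id}_{mv}_{k + 1:02d}", next(seeds))

    manifest = DatasetManifest(
        subjects=[SubjectInfo(p.subject_id, p.body_mass_kg) for p in profiles],
        trials=entries,
    )
    manifest.validate()
    return manifest, records, truths


def generate_dataset(
    n_subjects: int,
    cohort_seed: int,
    out_dir: str | Path,
    overwrite: bool = False,
    **kwargs,
) -> Path:
    """Write a full synthetic dataset (.sto trials + manifest.yaml) to disk.

    Regeneration with the same seed produces byte-identical files.  Refuses
    a non-empty output directory unless ``overwrite`` is set.
    """
    from .io_formats import write_sto

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty (pass overwrite=True)")
    manifest, records, _ = generate_records(n_subjects, cohort_seed, **kwargs)
    for rec in records:
        write_sto(rec.emg, out_dir / f"{rec.trial_id}_emg.sto")
        write_sto(rec.kinematics, out_dir / f"{rec.trial_id}_kin.sto")
    manifest_path = out_dir / "manifest.yaml"
    save_manifest(manifest, manifest_path)
    return manifest_path
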