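"""Simplified EMG-driven Hill-type neuromusculoskeletal solver.

Maps normalized EMG envelopes of the seven knee-crossing muscles to muscle
forces and a physics-based knee-torque baseline:

* first-order excitation-to-activation dynamics with asymmetric activation /
  deactivation time constants, followed by an exponential shape nonlinearity
  ``a' = (exp(A a) - 1) / (exp(A) - 1)`` with A in [-3, 0);
* an isometric Hill force model ``F = f_max * a * f_L(l)`` with a Gaussian
  active force-length curve (rigid tendon, no force-velocity term — the
  isometric form keeps per-subject calibration a convex linear problem);
* normalized fiber length affine in knee flexion angle;
* affine moment arms, extension torque positive;
* per-subject calibration of gain scales on ``f_max`` by bounded linear
  least squares against measured isometric torque.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import lsq_linear

from .io_formats import MUSCLE_ACTION_SIGN, MUSCLES

#: Reference knee flexion angle at which normalized fiber length is 1.
FIBER_REF_ANGLE_DEG = 45.0
#: Bounds on calibrated gain scales.
CALIBRATION_BOUNDS = (0.25, 4.0)

# Canonical per-muscle defaults: maximum isometric force (N), affine
# moment-arm coefficients (m, m/deg), fiber-length sensitivity k.
# Extensors: a0=0.045, a1=-2e-4; flexors: a0=0.030, a1=+1e-4.
_CANONICAL = {
    #              f_max   a0      a1      k
    "gastroc_med": (1500.0, 0.030, +1e-4, -0.12),
    "gastroc_lat": (700.0, 0.030, +1e-4, -0.12),
    "biceps_fem": (900.0, 0.030, +1e-4, -0.18),
    "semitend": (800.0, 0.030, +1e-4, -0.18),
    "rectus_fem": (1200.0, 0.045, -2e-4, +0.20),
    "vastus_med": (1400.0, 0.045, -2e-4, +0.15),
    "vastus_lat": (1900.0, 0.045, -2e-4, +0.15),
}


class CalibrationError(ValueError):
    """Raised when calibration preconditions are not met."""


@dataclass
class MuscleParams:
    """Hill-model parameters for one muscle."""

    name: str
    f_max: float
    l_opt: float = 1.0
    act_tau_s: float = 0.015
    deact_tau_s: float = 0.050
    shape_A: float = -1.5
    moment_arm_a0: float = 0.045
    moment_arm_a1: float = -2e-4
    action_sign: int = +1
    fl_width: float = 0.45
    fiber_k: float = 0.15

    def __post_init__(self) -> None:
        if self.f_max <= 0:
            raise ValueError(f"{self.name}: f_max must be positive")
        if not (0 < self.act_tau_s <= self.deact_tau_s):
            raise ValueError(f"{self.name}: need 0 < act_tau_s <= deact_tau_s")
        if self.fl_width <= 0:
            raise ValueError(f"{self.name}: fl_width must be positive")
        if self.action_sign not in (-1, +1):
            raise ValueError(f"{self.name}: action_sign must be +1 or -1")
        theta = np.linspace(0.0, 90.0, 19)
        if np.any(np.abs(self.moment_arm_a0 + self.moment_arm_a1 * theta) <= 0):
            raise ValueError(f"{self.name}: moment arm vanishes on [0, 90] deg")


def default_muscle_params() -> list[MuscleParams]:
    """Canonical parameter set for the seven muscles, in channel order."""
    out = []
    for name in MUSCLES:
        f_max, a0, a1, k = _CANONICAL[name]
        out.append(
            MuscleParams(
                name=name,
                f_max=f_max,
                moment_arm_a0=a0,
                moment_arm_a1=a1,
                action_sign=MUSCLE_ACTION_SIGN[name],
                fiber_k=k,
            )
        )
    return out


@dataclass
class MuscleForceSeries:
    muscle_names: list[str]
    activation: np.ndarray  # time x muscles, in [0, 1]
    force_n: np.ndarray  # time x muscles, Newtons
    force_normalized: np.ndarray  # force_n / f_max


@dataclass
class CalibrationResult:
    scales: dict[str, float]
    identifiable: dict[str, bool]
    residual_rmse_nm: float
    converged: bool


# ---------------------------------------------------------------------------
# Activation dynamics and Hill mechanics
# ---------------------------------------------------------------------------

def _shape_nonlinearity(a: np.ndarray, A: float) -> np.ndarray:
    if abs(A) < 1e-9:
        return a
    return (np.exp(A * a) - 1.0) / (np.exp(A) - 1.0)


def excitation_to_activation(
    u: np.ndarray, fs: float, params: MuscleParams, a0: float = 0.0
) -> np.ndarray:
    """First-order excitation-to-activation dynamics plus shape nonlinearity.

    Integrates ``da/dt = (u - a)/tau`` (explicit Euler at ``fs``; tau is the
    activation constant when u > a, else the deactivation constant), clips a
    to [0, 1], then applies the exponential nonlinearity.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("excitation contains non-finite values")
    u = np.clip(u, 0.0, 1.0)
    dt = 1.0 / fs
    a = np.empty_like(u)
    state = float(np.clip(a0, 0.0, 1.0))
    k_act = dt / params.act_tau_s
    k_deact = dt / params.deact_tau_s
    for i in range(u.shape[0]):
        k = k_act if u[i] > state else k_deact
        state = state + k * (u[i] - state)
        state = min(max(state, 0.0), 1.0)
        a[i] = state
    return _shape_nonlinearity(a, params.shape_A)


def active_force_length(l_norm: np.ndarray, fl_width: float = 0.45) -> np.ndarray:
    """Gaussian active force-length curve, 1 at optimal fiber length."""
    l_norm = np.asarray(l_norm, dtype=float)
    return np.exp(-(((l_norm - 1.0) / fl_width) ** 2))


def fiber_length_from_angle(theta_deg: np.ndarray, params: MuscleParams) -> np.ndarray:
    """Normalized fiber length, affine in knee angle around 45 degrees."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    return 1.0 + params.fiber_k * (theta_deg - FIBER_REF_ANGLE_DEG) / 90.0


def muscle_force(
    activation: np.ndarray, l_norm: np.ndarray, params: MuscleParams
) -> np.ndarray:
    """Isometric Hill force: ``f_max * a * f_L(l_norm)`` (Newtons)."""
    return params.f_max * np.asarray(activation, float) * active_force_length(
        l_norm, params.fl_width
    )


def moment_arm(theta_deg: np.ndarray, params: MuscleParams) -> np.ndarray:
    """Affine moment arm (metres) at the given knee angle(s)."""
    return params.moment_arm_a0 + params.moment_arm_a1 * np.asarray(theta_deg, float)


def muscle_forces_from_envelope(
    envelope: np.ndarray,
    theta_deg: np.ndarray,
    params_list: list[MuscleParams],
    fs: float,
) -> MuscleForceSeries:
    """EMG-driven force pathway: envelope -> activation -> Hill force."""
    envelope = np.asarray(envelope, dtype=float)
    theta_deg = np.asarray(theta_deg, dtype=float)
    if envelope.shape[0] != theta_deg.shape[0]:
        raise ValueError("envelope and angle lengths differ")
    n_m = len(params_list)
    if envelope.shape[1] != n_m:
        raise ValueError("envelope columns must match number of muscles")
    act = np.empty_like(envelope)
    force = np.empty_like(envelope)
    fnorm = np.empty_like(envelope)
    for j, p in enumerate(params_list):
        act[:, j] = excitation_to_activation(np.clip(envelope[:, j], 0.0, 1.0), fs, p)
        l_norm = fiber_length_from_angle(theta_deg, p)
        force[:, j] = muscle_force(act[:, j], l_norm, p)
        fnorm[:, j] = force[:, j] / p.f_max
    return MuscleForceSeries(
        muscle_names=[p.name for p in params_list],
        activation=act,
        force_n=force,
        force_normalized=fnorm,
    )


def joint_torque_from_muscles(
    forces: MuscleForceSeries, theta_deg: np.ndarray, params_list: list[MuscleParams]
) -> np.ndarray:
    """Net knee torque (Nm): sum of sign * moment_arm(theta) * force."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    if forces.force_n.shape[0] != theta_deg.shape[0]:
        raise ValueError("force series and angle vector lengths differ")
    tau = np.zeros(theta_deg.shape[0], dtype=float)
    for j, p in enumerate(params_list):
        tau += p.action_sign * moment_arm(theta_deg, p) * forces.force_n[:, j]
    return tau


# ---------------------------------------------------------------------------
# Isometric calibration
# ---------------------------------------------------------------------------

def calibrate_nms(
    envelopes: list[np.ndarray],
    thetas: list[np.ndarray],
    torques: list[np.ndarray],
    params_list: list[MuscleParams],
    fs: float,
    bounds: tuple[float, float] = CALIBRATION_BOUNDS,
) -> CalibrationResult:
    """Fit per-muscle gain scales on f_max by bounded linear least squares.

    ``envelopes``/``thetas``/``torques`` are per-trial aligned arrays from
    isometric trials.  The model torque is linear in the gains g_m:
    ``tau(t) = sum_m g_m * sign_m * r_m(theta) * F_m(t)`` where F_m uses the
    uncalibrated parameters.  Muscles that never activate are flagged
    unidentifiable and keep g = 1.
    """
    if len(envelopes) < 2:
        raise CalibrationError("calibration needs at least 2 isometric trials")
    if not (len(envelopes) == len(thetas) == len(torques)):
        raise CalibrationError("trial list lengths differ")
    distinct_angles = {round(float(np.median(th))) for th in thetas}
    if len(distinct_angles) < 2:
        raise CalibrationError("calibration trials must span at least 2 angles")

    cols = []
    ys = []
    for env, th, tq in zip(envelopes, thetas, torques):
        series = muscle_forces_from_envelope(env, th, params_list, fs)
        phi = np.stack(
            [
                p.action_sign * moment_arm(th, p) * series.force_n[:, j]
                for j, p in enumerate(params_list)
            ],
            axis=1,
        )
        cols.append(phi)
        ys.append(np.asarray(tq, dtype=float))
    phi = np.concatenate(cols, axis=0)
    y = np.concatenate(ys, axis=0)

    col_norm = np.linalg.norm(phi, axis=0)
    identifiable = col_norm > 1e-8 * max(1.0, float(col_norm.max()))
    g = np.ones(len(params_list))
    converged = True
    if identifiable.any():
        sub = phi[:, identifiable]
        offset = phi[:, ~identifiable] @ g[~identifiable] if (~identifiable).any() else 0.0
        res = lsq_linear(sub, y - offset, bounds=bounds, method="bvls")
        g[identifiable] = res.x
        converged = bool(res.success)
    residual = float(np.sqrt(np.mean((phi @ g - y) ** 2)))
    return CalibrationResult(
        scales={p.name: float(g[j]) for j, p in enumerate(params_list)},
        identifiable={p.name: bool(identifiable[j]) for j, p in enumerate(params_list)},
        residual_rmse_nm=residual,
        converged=converged,
    )


def apply_calibration(
    params_list: list[MuscleParams], result: CalibrationResult
) -> list[MuscleParams]:
    """Return parameters with f_max scaled by the fitted gains."""
    return [replace(p, f_max=p.f_max * result.scales[p.name]) for p in params_list]
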