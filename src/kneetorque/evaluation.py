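"""Evaluation framework: feature assembly, windowing, splits, and reports.

Implements the intra-subject and inter-subject (leave-one-subject-out,
without and with transfer learning) protocols.  Prediction error is the
root-mean-square error ``sqrt(mean((y_pred - y)^2))`` normalized by body
mass (Nm/kg); model targets are already in Nm/kg so training loss and
reported error share units.  Per-subject comparisons use a two-sided
paired-sample t-test at the 0.05 level.

Leakage is checked structurally: a test subject's (subject, trial) pairs
never appear in the train, validation or adaptation sets of any scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import nms
from .emg_processing import process_emg
from .io_formats import (
    ANGLE_CHANNEL,
    TORQUE_CHANNEL,
    DatasetManifest,
    TrialRecord,
)
from .network import NetworkConfig, TrainConfig, WeightSet, predict, train_model
from .transfer import TransferConfig, fine_tune

logger = logging.getLogger(__name__)

#: Default causal window: 15 samples at 100 Hz (150 ms), stride 1.
DEFAULT_WINDOW_LEN = 15
#: Sanity bound on body-mass-normalized torque targets (Nm/kg).
TARGET_SANITY_NMKG = 5.0
#: Knee-angle feature scaling (degrees / 90).
ANGLE_SCALE_DEG = 90.0


class SplitError(ValueError):
    """Raised when a split plan violates the evaluation protocol."""


class CalibrationPreconditionError(ValueError):
    """Raised when the hybrid pathway lacks isometric calibration trials."""


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

def rmse(y_pred: np.ndarray, y_meas: np.ndarray) -> float:
    """Root-mean-square error between prediction and measurement."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_meas = np.asarray(y_meas, dtype=float)
    if y_pred.shape != y_meas.shape or y_pred.size == 0:
        raise ValueError(
            f"inputs must be equal-length nonempty vectors, got "
            f"{y_pred.shape} vs {y_meas.shape}"
        )
    return float(np.sqrt(np.mean((y_pred - y_meas) ** 2)))


def normalize_by_mass(rmse_nm: float, body_mass_kg: float) -> float:
    """Convert an error in Nm to Nm/kg."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    return rmse_nm / body_mass_kg


def paired_ttest(errors_a: np.ndarray, errors_b: np.ndarray) -> dict:
    """Two-sided paired-sample t-test on per-subject errors.

    Returns ``{'t', 'p', 'significant', 'degenerate'}``; a zero-variance
    difference vector is flagged degenerate and reports no p-value.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return {"t": np.nan, "p": np.nan, "significant": False, "degenerate": True}
    res = stats.ttest_rel(a, b)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "significant": bool(res.pvalue < 0.05),
        "degenerate": False,
    }


# ---------------------------------------------------------------------------
# Feature assembly and windowing
# ---------------------------------------------------------------------------

@dataclass
class ProcessedTrial:
    """Aligned per-trial feature matrix and Nm/kg torque targets."""

    subject_id: str
    movement: str
    trial_id: str
    features: np.ndarray  # time x channels
    target_nmkg: np.ndarray  # time,
    valid: np.ndarray  # time, bool; False inside filter transients


@dataclass
class WindowedDataset:
    X: np.ndarray  # n x window_len x channels
    y: np.ndarray  # n,
    subjects: np.ndarray  # n, subject ids
    movements: np.ndarray  # n,
    trial_ids: np.ndarray  # n,

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def key_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.subjects.tolist(), self.trial_ids.tolist()))


def calibrate_subject(
    records: list[TrialRecord],
    subject_id: str,
    exclude_trial_ids: set[str] | None = None,
) -> tuple[list[nms.MuscleParams], nms.CalibrationResult]:
    """Per-subject Hill-model calibration on the subject's isometric trials."""
    exclude = exclude_trial_ids or set()
    mvics = [r.emg for r in records if r.subject_id == subject_id and r.movement == "mvic"]
    iso = [
        r
        for r in records
        if r.subject_id == subject_id
        and r.movement.startswith("iso_")
        and r.trial_id not in exclude
    ]
    if len(iso) < 2:
        raise CalibrationPreconditionError(
            f"subject {subject_id}: hybrid pathway needs >= 2 isometric "
            f"calibration trials, found {len(iso)}"
        )
    envs, thetas, torques = [], [], []
    for r in iso:
        kin = r.kinematics
        env = process_emg(r.emg, mvics, target_time=kin.time_s)
        envs.append(env.data)
        thetas.append(kin.channel(ANGLE_CHANNEL))
        torques.append(kin.channel(TORQUE_CHANNEL))
    params = nms.default_muscle_params()
    result = nms.calibrate_nms(envs, thetas, torques, params, fs=iso[0].kinematics.sampling_rate_hz)
    return nms.apply_calibration(params, result), result


def build_feature_trial(
    record: TrialRecord,
    mvic_trials,
    body_mass_kg: float,
    variant: str = "standard",
    calibrated_params: list[nms.MuscleParams] | None = None,
) -> ProcessedTrial:
    """Assemble one trial's model input and target.

    Channels: 7 MVIC-normalized envelopes, knee angle / 90, and — for the
    hybrid variant — the 7 calibrated normalized muscle forces (F / f_max).
    The target is measured torque / body mass (Nm/kg).
    """
    kin = record.kinematics
    if kin is None:
        raise ValueError(f"trial {record.trial_id} has no kinematics")
    env = process_emg(record.emg, mvic_trials, target_time=kin.time_s)
    theta = kin.channel(ANGLE_CHANNEL)
    cols = [env.data, (theta / ANGLE_SCALE_DEG)[:, None]]
    if variant == "hybrid":
        if calibrated_params is None:
            raise CalibrationPreconditionError(
                "hybrid variant requires calibrated muscle parameters"
            )
        series = nms.muscle_forces_from_envelope(
            env.data, theta, calibrated_params, kin.sampling_rate_hz
        )
        cols.append(series.force_normalized)
    elif variant != "standard":
        raise ValueError(f"unknown variant {variant!r}")
    features = np.concatenate(cols, axis=1)
    target = kin.channel(TORQUE_CHANNEL) / body_mass_kg
    if np.max(np.abs(target)) >= TARGET_SANITY_NMKG:
        raise ValueError(
            f"trial {record.trial_id}: |torque| exceeds {TARGET_SANITY_NMKG} Nm/kg"
        )
    return ProcessedTrial(
        subject_id=record.subject_id,
        movement=record.movement,
        trial_id=record.trial_id,
        features=features,
        target_nmkg=target,
        valid=~env.transient_mask,
    )


def build_features(
    records: list[TrialRecord],
    manifest: DatasetManifest,
    variant: str = "standard",
    movements: tuple[str, ...] | None = None,
    calibrations: dict[str, list[nms.MuscleParams]] | None = None,
) -> list[ProcessedTrial]:
    """Assemble features for every non-MVIC trial (optionally filtered)."""
    out = []
    calibrations = calibrations or {}
    if variant == "hybrid":
        for sid in {r.subject_id for r in records}:
            if sid not in calibrations:
                params, _ = calibrate_subject(records, sid)
                calibrations[sid] = params
    by_subject_mvic = {
        sid: [r.emg for r in records if r.subject_id == sid and r.movement == "mvic"]
        for sid in {r.subject_id for r in records}
    }
    for r in records:
        if r.movement == "mvic":
            continue
        if movements is not None and r.movement not in movements:
            continue
        out.append(
            build_feature_trial(
                r,
                by_subject_mvic[r.subject_id],
                manifest.body_mass(r.subject_id),
                variant=variant,
                calibrated_params=calibrations.get(r.subject_id),
            )
        )
    return out


def make_windows(
    trials: list[ProcessedTrial], window_len: int = DEFAULT_WINDOW_LEN, stride: int = 1
) -> WindowedDataset:
    """Sliding windows within trial boundaries; target = final-sample torque.

    Windows overlapping a flagged filter transient are dropped; trials
    shorter than the window are skipped with a warning.
    """
    Xs, ys, subj, movs, tids = [], [], [], [], []
    for trial in trials:
        T = trial.features.shape[0]
        if T < window_len:
            logger.warning("trial %s shorter than window, skipped", trial.trial_id)
            continue
        cummask = np.concatenate([[0], np.cumsum(~trial.valid)])
        for end in range(window_len - 1, T, stride):
            start = end - window_len + 1
            if cummask[end + 1] - cummask[start] > 0:
                continue  # window touches a transient
            Xs.append(trial.features[start : end + 1])
            ys.append(trial.target_nmkg[end])
            subj.append(trial.subject_id)
            movs.append(trial.movement)
            tids.append(trial.trial_id)
    if not Xs:
        raise ValueError("no valid windows produced")
    return WindowedDataset(
        X=np.stack(Xs),
        y=np.asarray(ys, dtype=float),
        subjects=np.asarray(subj),
        movements=np.asarray(movs),
        trial_ids=np.asarray(tids),
    )


# ---------------------------------------------------------------------------
# Split plans and leakage checks
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    scenario: str  # intra | inter_no_tl | inter_tl
    test_subject: str
    train: list[str] = field(default_factory=list)  # trial ids
    validation: list[str] = field(default_factory=list)
    adaptation: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)

    def check(self) -> None:
        test_set = set(self.test)
        for name, ids in (
            ("train", self.train),
            ("validation", self.validation),
            ("adaptation", self.adaptation),
        ):
            overlap = test_set & set(ids)
            if overlap:
                raise SplitError(f"test trials leak into {name} set: {sorted(overlap)}")


def loso_splits(manifest: DatasetManifest, movements: tuple[str, ...] | None = None) -> list[SplitPlan]:
    """One leave-one-subject-out plan per subject."""
    subjects = [s.subject_id for s in manifest.subjects]
    if len(subjects) < 2:
        raise SplitError("leave-one-subject-out needs at least 2 subjects")
    usable = [
        t
        for t in manifest.trials
        if t.role != "mvic_reference"
        and not t.movement == "mvic"
        and (movements is None or t.movement in movements)
    ]
    plans = []
    for test_subject in subjects:
        train = [t.trial_id for t in usable if t.subject_id != test_subject]
        test = [t.trial_id for t in usable if t.subject_id == test_subject]
        plan = SplitPlan(
            scenario="inter_no_tl", test_subject=test_subject, train=train, test=test
        )
        plan.check()
        plans.append(plan)
    return plans


def check_no_window_leakage(train: WindowedDataset, test: WindowedDataset) -> None:
    """Assert train/test windows share no (subject, trial) pair."""
    overlap = train.key_pairs() & test.key_pairs()
    if overlap:
        raise SplitError(f"window-level leakage between sets: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Long-format per-cell RMSE table with aggregation helpers."""

    table: pd.DataFrame  # columns: scenario, subject, case, movement, model, rmse_nmkg, n_windows

    def mean_rmse(self, **filters) -> float:
        df = self.table
        for key, value in filters.items():
            df = df[df[key] == value]
        return float(df["rmse_nmkg"].mean())

    def per_subject_means(self, model: str) -> pd.Series:
        df = self.table[self.table["model"] == model]
        return df.groupby("subject")["rmse_nmkg"].mean()

    def compare_models(self, model_a: str, model_b: str) -> dict:
        a = self.per_subject_means(model_a)
        b = self.per_subject_means(model_b)
        common = a.index.intersection(b.index)
        return paired_ttest(a.loc[common].to_numpy(), b.loc[common].to_numpy())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _trial_map(trials: list[ProcessedTrial]) -> dict[str, ProcessedTrial]:
    return {t.trial_id: t for t in trials}


def _evaluate_on_trials(
    weights: WeightSet,
    trials: list[ProcessedTrial],
    window_len: int,
) -> tuple[float, int]:
    """Concatenated-window RMSE (Nm/kg) over a set of test trials."""
    preds, meas = [], []
    for trial in trials:
        ends, p = predict(trial.features, weights, stride=1)
        keep = trial.valid[ends]
        preds.append(p[keep])
        meas.append(trial.target_nmkg[ends][keep])
    pred = np.concatenate(preds)
    measv = np.concatenate(meas)
    return rmse(pred, measv), pred.shape[0]


# ---------------------------------------------------------------------------
# Scenario runners
# ---------------------------------------------------------------------------

def run_intra_subject(
    records: list[TrialRecord],
    manifest: DatasetManifest,
    variant: str = "standard",
    cases: tuple[str, ...] | None = None,
    net_kwargs: dict | None = None,
    train_config: TrainConfig | None = None,
    window_len: int = DEFAULT_WINDOW_LEN,
    train_stride: int = 1,
    seed: int = 0,
) -> EvalReport:
    """Per-subject, per-case training and cross-movement testing.

    For each case (training movement) with at least 3 trials, 2 trials
    train and 1 validates; the model is tested on every other movement's
    trials.  Cases with insufficient trials are skipped with a log entry.
    """
    train_config = train_config or TrainConfig(seed=seed)
    trials = build_features(records, manifest, variant=variant)
    by_id = _trial_map(trials)
    rows = []
    subjects = sorted({t.subject_id for t in trials})
    for subject in subjects:
        mine = [t for t in trials if t.subject_id == subject]
        movements = sorted({t.movement for t in mine})
        case_list = cases if cases is not None else tuple(m for m in movements if m.startswith("gait"))
        for case in case_list:
            case_trials = [t for t in mine if t.movement == case]
            if len(case_trials) < 3:
                logger.info(
                    "intra: subject %s case %s skipped (%d < 3 trials)",
                    subject, case, len(case_trials),
                )
                continue
            train_trials = case_trials[:-1][:2]
            val_trials = case_trials[-1:]
            test_trials = [t for t in mine if t.movement != case]
            train_ds = make_windows(train_trials, window_len, train_stride)
            val_ds = make_windows(val_trials, window_len, train_stride)
            cfg = NetworkConfig(
                input_channels=train_ds.X.shape[2],
                window_len=window_len,
                seed=seed,
                **(net_kwargs or {}),
            )
            weights, _ = train_model(
                train_ds.X, train_ds.y, cfg, train_config, val_ds.X, val_ds.y,
                meta={"train_subjects": [subject], "pretrain_lr": train_config.lr,
                      "scenario": "intra", "case": case},
            )
            for movement in sorted({t.movement for t in test_trials}):
                cell = [t for t in test_trials if t.movement == movement]
                test_ds = make_windows(cell, window_len, 1)
                check_no_window_leakage(train_ds, test_ds)
                check_no_window_leakage(val_ds, test_ds)
                err, n = _evaluate_on_trials(weights, cell, window_len)
                rows.append(
                    {
                        "scenario": "intra",
                        "subject": subject,
                        "case": case,
                        "movement": movement,
                        "model": variant,
                        "rmse_nmkg": err,
                        "n_windows": n,
                    }
                )
    return EvalReport(table=pd.DataFrame(rows))


def _temporal_split(trial: ProcessedTrial, frac: float = 0.8) -> tuple[ProcessedTrial, ProcessedTrial]:
    cut = int(trial.features.shape[0] * frac)
    head = ProcessedTrial(
        trial.subject_id, trial.movement, trial.trial_id + ":head",
        trial.features[:cut], trial.target_nmkg[:cut], trial.valid[:cut],
    )
    tail = ProcessedTrial(
        trial.subject_id, trial.movement, trial.trial_id + ":tail",
        trial.features[cut:], trial.target_nmkg[cut:], trial.valid[cut:],
    )
    return head, tail


def run_inter_subject(
    records: list[TrialRecord],
    manifest: DatasetManifest,
    variant: str = "standard",
    with_transfer: bool = False,
    movements: tuple[str, ...] | None = None,
    net_kwargs: dict | None = None,
    train_config: TrainConfig | None = None,
    transfer_config: TransferConfig | None = None,
    window_len: int = DEFAULT_WINDOW_LEN,
    train_stride: int = 1,
    adaptation_trials: int = 1,
    seed: int = 0,
    _both: bool = False,
) -> EvalReport:
    """Leave-one-subject-out evaluation, optionally with transfer learning.

    Per fold and movement, a model pre-trains on every other subject's
    trials (the last trial of the last training subject validates).  Without
    transfer the pre-trained model predicts the test subject's held-out
    trials directly; with transfer the final dense layer is reinitialized
    and the model fine-tunes at reduced learning rate on the test subject's
    adaptation trial(s) before testing on the remaining trials (shared
    across both arms so they are directly comparable).
    """
    train_config = train_config or TrainConfig(seed=seed)
    transfer_config = transfer_config or TransferConfig(seed=seed)
    if movements is None:
        movements = tuple(
            sorted({r.movement for r in records if r.movement.startswith("gait")})
        )
    trials = build_features(records, manifest, variant=variant, movements=movements)
    by_id = _trial_map(trials)
    plans = loso_splits(manifest, movements)
    if len(plans) < 2:
        raise SplitError("inter-subject evaluation needs >= 2 subjects")
    rows = []
    for plan in plans:
        for movement in movements:
            train_ids = [t for t in plan.train if by_id[t].movement == movement]
            target_ids = [t for t in plan.test if by_id[t].movement == movement]
            if len(train_ids) < 2 or len(target_ids) < adaptation_trials + 1:
                logger.info("inter: fold %s movement %s skipped", plan.test_subject, movement)
                continue
            val_ids = train_ids[-1:]
            fit_ids = train_ids[:-1]
            adapt_ids = target_ids[:adaptation_trials]
            test_ids = target_ids[adaptation_trials:]
            fold_plan = SplitPlan(
                scenario="inter_tl" if with_transfer else "inter_no_tl",
                test_subject=plan.test_subject,
                train=fit_ids, validation=val_ids, adaptation=adapt_ids, test=test_ids,
            )
            fold_plan.check()
            train_ds = make_windows([by_id[t] for t in fit_ids], window_len, train_stride)
            val_ds = make_windows([by_id[t] for t in val_ids], window_len, train_stride)
            test_trials = [by_id[t] for t in test_ids]
            test_ds = make_windows(test_trials, window_len, 1)
            check_no_window_leakage(train_ds, test_ds)
            check_no_window_leakage(val_ds, test_ds)
            cfg = NetworkConfig(
                input_channels=train_ds.X.shape[2],
                window_len=window_len,
                seed=seed,
                **(net_kwargs or {}),
            )
            pretrained, _ = train_model(
                train_ds.X, train_ds.y, cfg, train_config, val_ds.X, val_ds.y,
                meta={
                    "train_subjects": sorted({by_id[t].subject_id for t in fit_ids}),
                    "pretrain_lr": train_config.lr,
                    "scenario": "inter",
                    "movement": movement,
                },
            )
            if (not with_transfer) or _both:
                err, n = _evaluate_on_trials(pretrained, test_trials, window_len)
                rows.append(
                    {
                        "scenario": "inter_no_tl",
                        "subject": plan.test_subject,
                        "case": movement,
                        "movement": movement,
                        "model": f"{variant}",
                        "rmse_nmkg": err,
                        "n_windows": n,
                    }
                )
            if with_transfer or _both:
                adapt_head, adapt_tail = _temporal_split(by_id[adapt_ids[0]])
                extra = [by_id[t] for t in adapt_ids[1:]]
                adapt_train = make_windows([adapt_head] + extra, window_len, train_stride)
                adapt_val = make_windows([adapt_tail], window_len, train_stride)
                check_no_window_leakage(adapt_train, test_ds)
                adapted, _ = fine_tune(
                    pretrained,
                    adapt_train.X, adapt_train.y, adapt_val.X, adapt_val.y,
                    target_subject=plan.test_subject,
                    transfer_config=transfer_config,
                    batch_size=train_config.batch_size,
                )
                err, n = _evaluate_on_trials(adapted, test_trials, window_len)
                rows.append(
                    {
                        "scenario": "inter_tl",
                        "subject": plan.test_subject,
                        "case": movement,
                        "movement": movement,
                        "model": f"{variant}",
                        "rmse_nmkg": err,
                        "n_windows": n,
                    }
                )
    return EvalReport(table=pd.DataFrame(rows))


def compare_transfer(
    records: list[TrialRecord],
    manifest: DatasetManifest,
    **kwargs,
) -> EvalReport:
    """Both inter-subject arms (with and without transfer) from shared
    pre-trained models, for direct per-fold comparison."""
    return run_inter_subject(records, manifest, with_transfer=True, _both=True, **kwargs)
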