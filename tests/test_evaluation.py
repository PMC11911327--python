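import numpy as np
import pandas as pd
import pytest

import oracles
from kneetorque import evaluation as ev
from kneetorque import io_formats as iof
from kneetorque.network import TrainConfig


class TestRmse:
    def test_exact_examples(self):
        assert ev.rmse(np.arange(4.0), np.arange(4.0)) == 0.0
        assert ev.rmse(np.array([2.0, 2.0, 2.0]), np.zeros(3)) == pytest.approx(2.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=7), rng.normal(size=7)
        assert ev.rmse(a, b) == pytest.approx(oracles.rmse_loops(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.rmse(np.zeros(3), np.zeros(4))


class TestNormalizeByMass:
    def test_arithmetic(self):
        assert ev.normalize_by_mass(14.0, 70.0) == pytest.approx(0.2)
        assert ev.normalize_by_mass(0.0, 55.0) == 0.0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            ev.normalize_by_mass(1.0, 0.0)

    def test_consistency_between_routes(self):
        rng = np.random.default_rng(1)
        pred_nm, meas_nm, mass = rng.normal(size=50) * 30, rng.normal(size=50) * 30, 72.5
        via_nm = ev.normalize_by_mass(ev.rmse(pred_nm, meas_nm), mass)
        via_nmkg = ev.rmse(pred_nm / mass, meas_nm / mass)
        assert via_nm == pytest.approx(via_nmkg, abs=1e-12)


class TestPairedTtest:
    def test_closed_form_example(self):
        # differences [1,2,3]: t = dbar / (s_d / sqrt(n)) = 2 / (1/sqrt(3))
        res = ev.paired_ttest(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res["t"] == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-4)
        assert res["t"] == pytest.approx(3.4641, abs=1e-4)

    def test_identical_inputs_degenerate(self):
        res = ev.paired_ttest(np.ones(4), np.ones(4))
        assert res["degenerate"] and not res["significant"]

    def test_sign_flip_negates_t_keeps_p(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(size=6)
        r1 = ev.paired_ttest(a, b)
        r2 = ev.paired_ttest(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])


def _processed(subject, movement, trial_id, T=40, C=3, seed=0, valid=None):
    rng = np.random.default_rng(seed)
    return ev.ProcessedTrial(
        subject_id=subject, movement=movement, trial_id=trial_id,
        features=rng.normal(size=(T, C)),
        target_nmkg=rng.normal(size=T) * 0.5,
        valid=np.ones(T, dtype=bool) if valid is None else valid,
    )


class TestMakeWindows:
    def test_window_count_stride_one(self):
        ds = ev.make_windows([_processed("S01", "gait_self", "t1", T=100)], window_len=15)
        assert ds.n == 100 - 15 + 1

    def test_no_window_crosses_trials_and_labels_constant(self):
        trials = [
            _processed("S01", "gait_self", "t1", T=30, seed=1),
            _processed("S01", "gait_fast", "t2", T=30, seed=2),
        ]
        ds = ev.make_windows(trials, window_len=10)
        assert ds.n == 2 * (30 - 10 + 1)
        for tid, mov in zip(ds.trial_ids, ds.movements):
            assert (tid, mov) in {("t1", "gait_self"), ("t2", "gait_fast")}
        # window content must come from a single trial: check targets map back
        for i in range(ds.n):
            trial = trials[0] if ds.trial_ids[i] == "t1" else trials[1]
            assert ds.y[i] in trial.target_nmkg

    def test_transient_windows_excluded(self):
        valid = np.ones(40, dtype=bool)
        valid[:12] = False
        ds = ev.make_windows([_processed("S01", "gait_self", "t1", T=40, valid=valid)], 10)
        # first permissible window ends at index 21 (starts at 12)
        assert ds.n == 40 - 12 - 10 + 1

    def test_short_trial_skipped(self, caplog):
        with pytest.raises(ValueError):
            ev.make_windows([_processed("S01", "gait_self", "t1", T=5)], window_len=10)

    def test_target_is_final_sample(self):
        trial = _processed("S01", "gait_self", "t1", T=25, seed=3)
        ds = ev.make_windows([trial], window_len=10)
        np.testing.assert_array_equal(ds.y, trial.target_nmkg[9:])


def _manifest(n_subjects=3, movements=("gait_self",), trials_per=2):
    subjects = [iof.SubjectInfo(f"S{i+1:02d}", 70.0) for i in range(n_subjects)]
    trials = []
    for s in subjects:
        trials.append(iof.TrialEntry(f"{s.subject_id}_mvic", s.subject_id, "mvic",
                                     "mvic_reference", "x.sto"))
        for m in movements:
            for k in range(trials_per):
                trials.append(iof.TrialEntry(f"{s.subject_id}_{m}_{k}", s.subject_id,
                                             m, "train", "x.sto"))
    return iof.DatasetManifest(subjects, trials)


class TestLosoSplits:
    @pytest.mark.parametrize("n", [3, 10])
    def test_one_plan_per_subject_and_exclusion(self, n):
        plans = ev.loso_splits(_manifest(n))
        assert len(plans) == n
        for plan in plans:
            train_subjects = {t.split("_")[0] for t in plan.train}
            assert plan.test_subject not in train_subjects
            assert len(train_subjects) == n - 1
            plan.check()

    def test_single_subject_rejected(self):
        with pytest.raises(ev.SplitError):
            ev.loso_splits(_manifest(1))

    def test_leak_detection(self):
        plan = ev.SplitPlan("intra", "S01", train=["a", "b"], test=["b"])
        with pytest.raises(ev.SplitError, match="leak"):
            plan.check()

    def test_window_leakage_check(self):
        t1 = _processed("S01", "gait_self", "t1")
        ds = ev.make_windows([t1], 10)
        with pytest.raises(ev.SplitError):
            ev.check_no_window_leakage(ds, ds)


@pytest.fixture(scope="module")
def tiny_run(small_cohort_dataset):
    manifest, records, _ = small_cohort_dataset
    tc = TrainConfig(batch_size=512, lr=1e-3, max_epochs=3, patience=2, seed=0)
    return ev.run_intra_subject(
        records, manifest, variant="standard", cases=("gait_self",),
        net_kwargs=dict(conv_filters=(4, 8), gru_units=8, attention_dim=8,
                        dense_units=(8,)),
        train_config=tc, train_stride=4, seed=0,
    )


class TestScenarioRunners:
    def test_intra_report_shape(self, tiny_run):
        df = tiny_run.table
        # 2 subjects x 1 case x 2 other gait movements (+ iso movements)
        assert set(df["case"]) == {"gait_self"}
        assert {"gait_slow", "gait_fast"} <= set(df["movement"])
        assert (df["rmse_nmkg"] >= 0).all()
        assert set(df["subject"]) == {"S01", "S02"}

    def test_intra_deterministic(self, small_cohort_dataset, tiny_run):
        manifest, records, _ = small_cohort_dataset
        tc = TrainConfig(batch_size=512, lr=1e-3, max_epochs=3, patience=2, seed=0)
        report2 = ev.run_intra_subject(
            records, manifest, variant="standard", cases=("gait_self",),
            net_kwargs=dict(conv_filters=(4, 8), gru_units=8, attention_dim=8,
                            dense_units=(8,)),
            train_config=tc, train_stride=4, seed=0,
        )
        pd.testing.assert_frame_equal(tiny_run.table, report2.table)

    def test_intra_insufficient_trials_skipped(self, small_cohort_dataset):
        manifest, records, _ = small_cohort_dataset
        # iso movements have a single trial each -> cases skipped, empty report
        tc = TrainConfig(batch_size=512, lr=1e-3, max_epochs=2, patience=1, seed=0)
        report = ev.run_intra_subject(
            records, manifest, variant="standard", cases=("iso_30",),
            train_config=tc, seed=0,
        )
        assert report.table.empty

    def test_inter_no_transfer_report(self, small_cohort_dataset):
        manifest, records, _ = small_cohort_dataset
        tc = TrainConfig(batch_size=512, lr=1e-3, max_epochs=2, patience=1, seed=0)
        report = ev.run_inter_subject(
            records, manifest, variant="standard", with_transfer=False,
            movements=("gait_self",),
            net_kwargs=dict(conv_filters=(4, 8), gru_units=8, attention_dim=8,
                            dense_units=(8,)),
            train_config=tc, train_stride=4, seed=0,
        )
        df = report.table
        assert set(df["scenario"]) == {"inter_no_tl"}
        assert set(df["subject"]) == {"S01", "S02"}

    def test_hybrid_without_isometrics_is_precondition_error(self, small_cohort_dataset):
        manifest, records, _ = small_cohort_dataset
        no_iso = [r for r in records if not r.movement.startswith("iso")]
        with pytest.raises(ev.CalibrationPreconditionError):
            ev.build_features(no_iso, manifest, variant="hybrid")
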