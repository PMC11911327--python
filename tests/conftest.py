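import numpy as np
import pytest

from kneetorque import evaluation as ev
from kneetorque import synthetic as syn

#: Small network used by end-to-end tests (problem sizes are documented in
#: docs/methods.md).
SMALL_NET = dict(conv_filters=(8, 16), gru_units=32, attention_dim=32, dense_units=(32,))
TINY_NET = dict(conv_filters=(4, 8), gru_units=16, attention_dim=16, dense_units=(16,))


@pytest.fixture(scope="session")
def one_subject_dataset():
    """One synthetic subject, 3 gait speeds x 3 x 20 s trials + calibration."""
    manifest, records, truths = syn.generate_records(
        1, cohort_seed=42, gait_trials=3, gait_duration_s=20.0
    )
    return manifest, records, truths


@pytest.fixture(scope="session")
def small_cohort_dataset():
    """Two synthetic subjects with short gait trials, for protocol tests."""
    manifest, records, truths = syn.generate_records(
        2, cohort_seed=7, gait_trials=3, gait_duration_s=6.0, iso_movements=("iso_30", "iso_60")
    )
    return manifest, records, truths


@pytest.fixture(scope="session")
def processed_one_subject(one_subject_dataset):
    manifest, records, _ = one_subject_dataset
    return manifest, ev.build_features(records, manifest, variant="hybrid")
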