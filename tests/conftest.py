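"""Shared fixtures: a seeded study-scale herd and its trained classifier.

The study herd mirrors the field campaign's conditions: 17 pregnant does,
labor onset 90 min before the first kid's birth, a 30 min lateral-recumbency
episode, counts on 0-255 with 0 g at 128. Simulated at 26 h per goat with
birth near hour 24 so every goat has a parturition day and a labor-free
control stretch.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import kidwatch as kw
from kidwatch import classify, preprocess, sensor_io

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

STUDY_SEED = 0


@pytest.fixture(scope="session")
def study_config():
    return kw.SimulationConfig(n_goats=17, duration_hours=26.0,
                               birth_offset_hours=24.0, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_herd(study_config):
    return kw.simulate_herd(study_config)


@pytest.fixture(scope="session")
def study_streams(study_herd):
    return [records for records, _ in study_herd]


@pytest.fixture(scope="session")
def study_truths(study_herd):
    return [gt for _, gt in study_herd]


@pytest.fixture(scope="session")
def study_dataset(study_streams, study_truths):
    intervals = sensor_io.intervals_from_ground_truth(study_truths)
    ds = sensor_io.build_dataset(
        {gt.goat_id: s for s, gt in zip(study_streams, study_truths)},
        intervals, balance=True, max_per_class=3938, seed=STUDY_SEED)
    cleaned, _ = preprocess.clean_dataset(ds)
    return cleaned


@pytest.fixture(scope="session")
def study_model(study_dataset):
    return classify.train(study_dataset, kind="tree",
                          spec=classify.SplitSpec(shuffle_seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_calibration(study_streams, study_truths, study_model):
    result, selection, comparison = kw.calibrate_herd(
        study_streams, study_truths, study_model, day_hours=12.0)
    return result, selection, comparison


@pytest.fixture()
def rng():
    return np.random.default_rng(STUDY_SEED)


def make_stream(seconds, active_mask, x=150, z=150, goat_id="goatXX",
                start="2024-01-01"):
    """Hand-build a minimal record frame for windowing tests."""
    n = len(active_mask)
    t0 = pd.Timestamp(start)
    return pd.DataFrame({
        "data_number": np.arange(1, n + 1),
        "gateway_id": goat_id,
        "timestamp": t0 + pd.to_timedelta(np.asarray(seconds), unit="s"),
        "rssi": -60,
        "battery": 100,
        "activity": np.asarray(active_mask, dtype=bool),
        "x": x, "y": 128, "z": z,
    })
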