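import dataclasses

import h5py
import numpy as np
import pytest

import nirsae as na


def make_snirf(path, data, rate_hz=8.0, labels=None):
    """Write a minimal processed-hemoglobin SNIRF file (HDF5) for tests."""
    data = np.asarray(data, dtype=float)
    n, c = data.shape
    labels = labels or ["HbO"] * c
    with h5py.File(path, "w") as fh:
        fh.create_dataset("formatVersion", data="1.0")
        g = fh.create_group("nirs/data1")
        g.create_dataset("dataTimeSeries", data=data)
        g.create_dataset("time", data=np.arange(n) / rate_hz)
        for i, lab in enumerate(labels):
            ml = g.create_group(f"measurementList{i + 1}")
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeLabel", data=lab)
    return path


@pytest.fixture
def small_cohort_config():
    """Short, quick cohort: 3 pianists vs 2 non-pianists, default planted effect."""
    return na.CohortConfig(n_group_a=3, n_group_b=2, seed=11)


@pytest.fixture
def small_recording():
    cfg = na.CohortConfig(n_group_a=1, n_group_b=1)
    return na.simulate_recording(cfg, "pianist", "score", subject_seed=7)


@pytest.fixture(scope="session")
def planted_pipeline_runs():
    """Ten master-seed runs of the planted-effect pipeline at desk scale.

    Cohort is the default 16 pianists vs 6 non-pianists with the effect in
    channels 1 and 15 (burst_amp_sd=10, variance_inflation=2); window size
    20, 30 epochs, 2 replicates.  Stride 25 keeps the run desk-sized.
    Shared (session scope) between the effect-recovery and
    anomaly-separation checks.
    """
    reports = []
    for seed in range(10):
        config = na.PipelineConfig(
            cohort=na.CohortConfig(seed=seed),
            window_candidates=(20,),
            stride=25,
            train=na.TrainConfig(epochs=30),
            n_replicates=2,
            n_permutations=2000,
            master_seed=seed,
        )
        reports.append(na.run_pipeline(config))
    return reports


@pytest.fixture
def tiny_pipeline_config():
    """Minutes-scale pipeline config for smoke/determinism tests."""
    return na.PipelineConfig(
        cohort=na.CohortConfig(n_group_a=3, n_group_b=2, seed=5),
        target_len=600,
        window_candidates=(15, 20),
        stride=40,
        train=na.TrainConfig(epochs=3, batch_size=256),
        n_replicates=2,
        n_permutations=200,
        master_seed=3,
    )


def tiny_model_spec(window_len=4, n_channels=2):
    return na.ModelSpec(
        window_len=window_len,
        n_channels=n_channels,
        encoder_recurrent_units=(5, 4),
        encoder_dense_units=(4, 3),
        decoder_dense_units=(4,),
        decoder_recurrent_units=(4,),
    )
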