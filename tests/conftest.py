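"""Shared fixtures: one simulated cohort processed end to end, reused by
the fingerprint / chemometrics / classification tests."""

import warnings

import numpy as np
import pytest

from soilprint.pipeline import RunConfig, build_fingerprint, process_chromatograms
from soilprint.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=7, outdir="scratch-unused")


@pytest.fixture(scope="session")
def cohort(run_config):
    return simulate_cohort(run_config.simulation)


@pytest.fixture(scope="session")
def peak_tables(cohort, run_config):
    chroms, _ = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return process_chromatograms(chroms, run_config)


@pytest.fixture(scope="session")
def fingerprint_result(peak_tables, run_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_fingerprint(peak_tables, run_config)


@pytest.fixture(scope="session")
def common_matrix(fingerprint_result):
    return fingerprint_result[1]


@pytest.fixture(scope="session")
def truth_area_matrix(cohort):
    _, truth = cohort
    X = truth.area_matrix().to_numpy(float)
    labels = truth.group_labels.to_numpy()
    return X, labels


def rng_matrix(seed, n, p):
    return np.random.default_rng(seed).normal(size=(n, p))
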