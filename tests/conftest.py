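import numpy as np
import pandas as pd
import pytest

from ctds import BinningScheme, SimulationConfig, simulate_dataset
from ctds.io import read_deployments


@pytest.fixture
def rng():
    return np.random.default_rng(20231004)


@pytest.fixture(scope="session")
def small_survey():
    """A quick simulated survey (short deployments) shared across tests."""
    cfg = SimulationConfig(seed=7, deployment_days=10.0, target_activity=0.5)
    detections, deployments, truth = simulate_dataset(cfg)
    return cfg, detections, deployments, truth


@pytest.fixture
def survey_files(tmp_path, small_survey):
    """The small survey written as the CSV schemas the pipeline reads."""
    _, detections, deployments, _ = small_survey
    det = tmp_path / "detections.csv"
    dep = tmp_path / "deployments.csv"
    detections.to_csv(det, index=False)
    deployments.to_csv(dep, index=False)
    return det, dep


@pytest.fixture
def deployment_frame(survey_files):
    return read_deployments(survey_files[1])


@pytest.fixture
def scheme10():
    """The study-style binning: 1-m bins on [0, 10)."""
    return BinningScheme.regular(1.0, 0.0, 10.0)
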