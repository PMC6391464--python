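"""Shared fixtures: the end-to-end synthetic study is expensive, so the
default-scenario pipeline run is computed once per session."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from mzsift import simulate as sim
from mzsift.io import PipelineConfig, run_pipeline

DATA_DIR = Path(__file__).parent / "data"

#: Session seed for the end-to-end fixture (arbitrary, fixed).
SESSION_SEED = 7


@pytest.fixture(scope="session")
def pipeline():
    """Full pipeline on the default synthetic incubation scenario."""
    return run_pipeline(PipelineConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def study(pipeline):
    return pipeline.study


@pytest.fixture(scope="session")
def reported_features() -> pd.DataFrame:
    """Published significant-feature tables (transcribed regression set)."""
    return pd.read_csv(DATA_DIR / "reported_features.csv")


@pytest.fixture()
def quiet_scenario():
    """Small noise-free scenario for exact-recovery checks."""
    return sim.default_scenario(noise=sim.NoiseModel.off(), n_background=5)
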