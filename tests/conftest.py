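import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from polyfoot.pipeline import run_scenario
from polyfoot.simulate import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_sync(tmp_path):
    """Three-site, two-pool sync file."""
    text = (
        "ctg1\t5\tA\t10:0:2:0:0:0\t7:0:5:0:0:0\n"
        "ctg1\t6\tC\t0:0:50:0:0:0\t0:0:49:1:0:0\n"
        "ctg2\t3\tG\t20:20:0:0:0:0\t30:10:0:0:0:0\n"
    )
    path = tmp_path / "tiny.sync"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def discordant_run(tmp_path_factory):
    """One full discordant-scenario pipeline run (300 genes, shared by tests)."""
    work = tmp_path_factory.mktemp("discordant")
    cfg = ScenarioConfig(scenario="DISCORDANT_ENGINEERED", n_genes=300, seed=42)
    return run_scenario(cfg, work)


@pytest.fixture(scope="session")
def neutral_run(tmp_path_factory):
    """One full neutral-scenario pipeline run (300 genes, shared by tests)."""
    work = tmp_path_factory.mktemp("neutral")
    cfg = ScenarioConfig(scenario="NEUTRAL_INDEPENDENT", n_genes=300, seed=42)
    return run_scenario(cfg, work)
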