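import numpy as np
import pandas as pd
import pytest

from netecol.panel import Panel, WaveNetwork
from netecol.synthetic import CohortConfig, GroundTruth, generate_cohort


@pytest.fixture
def tiny_panel() -> Panel:
    """Three students, two waves, hand-written ties."""
    attributes = pd.DataFrame(
        {"sex": [0, 1, 0], "ethnicity_majority": [1, 1, 0], "ses_high": [0, 1, 1]},
        index=["a", "b", "c"],
    )
    participation = pd.DataFrame(
        {"T1": [True, True, True], "T2": [True, True, False]},
        index=["a", "b", "c"],
    )
    waves = [
        WaveNetwork("T1", {("a", "b"): (1, 4), ("b", "a"): (0, 2), ("b", "c"): (0, 1)}),
        WaveNetwork("T2", {("a", "b"): (1, 5)}),
    ]
    return Panel("tiny", ["a", "b", "c"], attributes, waves, participation)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-student, 4-wave synthetic cohort shared across tests."""
    cfg = CohortConfig(n=60, n_waves=4, seed=11)
    panel, truth = generate_cohort(cfg)
    return panel, truth, cfg


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Fitted tie-fitness model and surface on the cohort's second wave."""
    from netecol.fitness import TieFitnessModel

    panel, _, _ = small_cohort
    res = TieFitnessModel.from_panel(panel, "T2").fit()
    return panel, res, res.fitness()
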