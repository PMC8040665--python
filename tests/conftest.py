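import numpy as np
import pandas as pd
import pytest

from inflamsig import simulate as sim


@pytest.fixture(scope="session")
def panel():
    return sim.generate_panel()


@pytest.fixture(scope="session")
def subjects():
    return sim.generate_subjects(seed=11)


@pytest.fixture(scope="session")
def small_panel():
    """Baseline-signaling-only panel: the 84 network nodes."""
    cfg = sim.PanelConfig(
        response_stimuli=(), serum_analytes=(), frequency_features=()
    )
    return sim.generate_panel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def single_cohort_config(n: int, cohort: str = "aging") -> sim.CohortConfig:
    """A config with n cases in one cohort and nothing else."""
    empty = sim.CohortSpec(0, 0, (20, 30), (20, 30))
    spec = sim.CohortSpec(n, 0, (20, 90), (20, 30))
    kwargs = {"aging": empty, "hiv": empty, "hcv": empty}
    kwargs[cohort] = spec
    return sim.CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def hcv_longitudinal(subjects, panel):
    return sim.simulate_longitudinal_hcv(subjects, panel, seed=11)
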