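import numpy as np
import pytest

from flocknet.config import AnalysisPlan, ScenarioConfig, scaled_demo_config
from flocknet.synthetic import simulate_scenario


@pytest.fixture(scope="session")
def scaled_scenario():
    """One desk-scale three-period experiment shared across the suite."""
    return simulate_scenario(scaled_demo_config(seed=1))


@pytest.fixture(scope="session")
def tiny_scenario():
    """A very small, fast scenario for pipeline smoke tests."""
    cfg = ScenarioConfig(
        n_individuals=30,
        n_sites=3,
        period_lengths_days=(4, 6, 3),
        event_rate_per_site_day=6.0,
        reads_per_visit_mean=1.5,
        rng_seed=7,
        patch_starts_pre=(1,),
        patch_starts_during=(2,),
        patch_days=2,
        n_patches=2,
        patch_event_rate_per_day=6.0,
        n_nest_boxes=6,
        nestbox_days_before_post=3,
        nestbox_total_days=6,
    )
    return simulate_scenario(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def fast_plan():
    return AnalysisPlan(n_perm=200, n_boot=50, seed=3, window_days=3)
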