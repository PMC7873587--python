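import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def oromia_profile():
    """High-OD Ethiopian region with large published effect sizes."""
    from cltsce import datasets

    return datasets.load_region_profiles()["Oromia"]


@pytest.fixture
def hew_ethiopia_totals():
    """Published cost-category amounts for the HEW-facilitated arm,
    Ethiopia combined (the canonical worked-example column)."""
    return {
        "management": 8690.0,
        "training": 17617.0,
        "facilitation": 4891.0,
        "local_actor_time": 1926.0,
        "community_time": 2546.0,
        "hired_labor": 0.0,
        "hardware": 1070.0,
    }
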