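import pytest
from hypothesis import HealthCheck, settings

from pmed.expression import Level, ZProfile
from pmed.synthetic import SimulationConfig, simulate_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study():
    """One complete synthetic study at the default conditions, seed 0."""
    return simulate_study(SimulationConfig(seed=0))


def make_profile(values: dict[str, float], level=Level.human_gene, sample="S1") -> ZProfile:
    return ZProfile(sample_id=sample, level=level, values=values)
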