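import pytest

from methylpath import MethylationPathwayModel, SimulationConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """One seeded reference study with a planted pathway."""
    return generate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fitted(study):
    """Full pipeline results on the reference study."""
    return MethylationPathwayModel.from_study(study).fit()
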