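import pytest

from phenorisk import CampaignDesign, GenerativeParams, generate_campaign


@pytest.fixture(scope="session")
def default_campaign():
    """Full reference design (3 states x 2 settings x 10 sites x 3 reps x
    2 seasons x 4 analytes), fixed seed."""
    return generate_campaign(CampaignDesign(), GenerativeParams(seed=123))


@pytest.fixture()
def tiny_design():
    return CampaignDesign(
        states=("Osun", "Oyo"),
        settings=("rural", "urban"),
        n_sites_per_cell=3,
        n_replicates=2,
        distance_bands_m=(50, 200, 500),
    )
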