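import numpy as np
import pytest

from bandcoloc import BandSet, ProfileSimConfig, simulate_profile


@pytest.fixture
def sim_config():
    return ProfileSimConfig(seed=7)


@pytest.fixture
def clean_profile(sim_config):
    """A simulated profile with mild noise and planted half colocalization."""
    return simulate_profile(sim_config)


def make_bands(positions, segment_id="seg", larva_id="larva", condition="",
               channel="channel_a"):
    positions = np.asarray(positions, float)
    return BandSet(
        channel=channel,
        positions=positions,
        heights=np.full(positions.size, 100.0),
        min_distance_um=0.6,
        threshold_frac=0.2,
        segment_id=segment_id,
        larva_id=larva_id,
        condition=condition,
    )


@pytest.fixture
def band_factory():
    return make_bands
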