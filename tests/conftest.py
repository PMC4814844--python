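import pytest

from dropquant import AmplitudeModel, assign_clusters, quantify_classes, simulate_well, spike_in_mix


@pytest.fixture
def model():
    return AmplitudeModel()


@pytest.fixture
def quiet_model():
    """Default cluster geometry with noise and rain switched off."""
    return AmplitudeModel().noise_free()


@pytest.fixture
def spike_well(quiet_model):
    """One 15,000-droplet well: 30,000 copies, 5% HDR + 5% NHEJ spike."""
    mix = spike_in_mix(27_000, 0.05, 0.05, 15_000)
    return simulate_well(mix, 15_000, quiet_model, seed=20160331)


def quantify_well(well, gates=None):
    counts, _ = assign_clusters(well, gates)
    return quantify_classes(counts)
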