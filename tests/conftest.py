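import pytest

from relaxcider import GroundTruthRegistry, generate_study_bundle


@pytest.fixture(scope="session")
def registry():
    return GroundTruthRegistry()


@pytest.fixture(scope="session")
def noiseless_bundle(registry):
    """Nine-sample study with zero noise (exact additive model)."""
    return generate_study_bundle(registry, seed=1, noise_rel=0.0)


@pytest.fixture(scope="session")
def noisy_bundle(registry):
    """Nine-sample study at the study conditions (3% noise on T1)."""
    return generate_study_bundle(registry, seed=20260521, noise_rel=0.03)
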