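import numpy as np
import pytest

import segmorph as sm


@pytest.fixture(scope="session")
def tree12():
    return sm.simulate_tree(12, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """Six species, ~30 larvae each: fast but structurally complete."""
    profiles = sm.default_species_profiles()[:6]
    return sm.simulate_study(profiles, n_range=(28, 34), seed=11)


@pytest.fixture(scope="session")
def small_rel(small_study):
    return sm.relative_positions(small_study)


@pytest.fixture(scope="session")
def noiseless_profile():
    return sm.SpeciesProfile(
        "noiseless", mean_length=1000.0, length_cv=0.0,
        segment_noise_sd=0.0, smooth_noise_scale=0.0,
    )


def spawn_seeds(seed, n):
    """Independent integer seeds for replicate experiments."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]
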