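import numpy as np
import pytest

from sfmap import model2d, synth
from sfmap.stimulus import GridSpec


@pytest.fixture(scope="session")
def vectors():
    from sfmap.stimulus import build_frequency_vectors

    return build_frequency_vectors()


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for numerical-oracle tests (keeps rendering cheap)."""
    return GridSpec(image_side=512, pixels_per_degree=21.0)


@pytest.fixture(scope="session")
def noiseless_subject():
    """500 voxels generated exactly from the model-9 template, no noise."""
    return synth.simulate_subject(
        "noiseless", synth.TEMPLATE_MODEL9, n_voxels=500, noise_scale=0.0, seed=11
    )


@pytest.fixture(scope="session")
def noisy_subject():
    """800 voxels at the realistic noise operating point."""
    return synth.simulate_subject(
        "noisy", synth.TEMPLATE_MODEL9, n_voxels=800, noise_scale=0.3, seed=12
    )


@pytest.fixture(scope="session")
def eligible_noisy(noisy_subject):
    keep = model2d.filter_voxels(
        noisy_subject.ecc, noisy_subject.prf_size, noisy_subject.betas
    )
    return noisy_subject.subset(keep)
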