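import numpy as np
import pytest

from dsareg.sequence_io import compute_minip
from dsareg.synthetic_dsa import PairConfig, make_pair


@pytest.fixture(scope="session")
def pair7():
    """Default-condition synthetic pre/post pair (seed 7)."""
    return make_pair(7, PairConfig())


@pytest.fixture(scope="session")
def pair7_minips(pair7):
    return compute_minip(pair7.pre_seq), compute_minip(pair7.post_seq)


@pytest.fixture(scope="session")
def clean_pair7():
    """Seed-7 pair without noise or vessel removal (for exact comparisons)."""
    return make_pair(7, PairConfig(noise_sd=0.0, removal_fraction=0.0))


def random_similarity(rng, center=(255.5, 255.5)):
    from dsareg.transform_models import Transform2D

    return Transform2D.from_similarity_params(
        scale=rng.uniform(0.9, 1.1),
        rotation_deg=rng.uniform(-15, 15),
        translation=rng.uniform(-50, 50, 2),
        center=center,
    )
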