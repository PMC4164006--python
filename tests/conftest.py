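import numpy as np
import pytest

from beelearn import build_cr_matrix
from beelearn.cr_data import ROLE_CONDITIONING, ROLE_RETENTION


@pytest.fixture
def toy_matrix():
    """Four animals, four conditioning trials: 0111, 0101, 0011, 0000.

    Known by hand: average curve [0, .5, .5, .75]; first-CR histogram
    {2: 2, 3: 1, none: 1}; subgroup stabilities {2: 0.75, 3: 1.0};
    overall stability 5/6; non-responder fraction 0.25.
    """
    return build_cr_matrix(
        [[0, 1, 1, 1], [0, 1, 0, 1], [0, 0, 1, 1], [0, 0, 0, 0]],
        [ROLE_CONDITIONING] * 4,
    )


@pytest.fixture
def retention_matrix():
    """Two conditioning trials plus a retention test: rows 01|1, 01|0, 00|0."""
    return build_cr_matrix(
        [[0, 1, 1], [0, 1, 0], [0, 0, 0]],
        [ROLE_CONDITIONING, ROLE_CONDITIONING, ROLE_RETENTION],
    )


def random_cr_matrix(rng, n=None, k=None, with_durations=False, with_grs=False):
    """Small random valid CR matrix for property tests."""
    n = n or int(rng.integers(1, 8))
    k = k or int(rng.integers(1, 6))
    responses = rng.integers(0, 2, size=(n, k))
    roles = [ROLE_CONDITIONING] * k
    if k > 1 and rng.random() < 0.5:
        roles[-1] = ROLE_RETENTION
    durations = None
    if with_durations:
        durations = np.where(responses == 1, rng.integers(1, 10, size=(n, k)).astype(float), np.nan)
    grs = rng.integers(0, 11, size=n) if with_grs else None
    return build_cr_matrix(responses, roles, durations=durations, grs=grs)
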