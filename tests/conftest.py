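import numpy as np
import pytest

from moodsig.encoding import MoodStream
from moodsig.synthetic import amoss_like_config, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small labeled synthetic cohort (6 per group, 20 weeks) with missingness."""
    cfg = amoss_like_config(
        seed=11, n_per_group={"BD": 6, "HC": 6, "BPD": 6}, weeks=20
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_path(rng, d, max_segments=5):
    n_seg = int(rng.integers(1, max_segments + 1))
    return rng.uniform(-1.0, 1.0, size=(n_seg + 1, d))


@pytest.fixture
def make_stream():
    def _make(scores, diagnosis="HC", pid="p0"):
        scores = np.asarray(scores, dtype=float)
        return MoodStream(
            participant_id=pid,
            weeks=np.arange(scores.shape[0]),
            scores=scores,
            diagnosis=diagnosis,
        )

    return _make
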