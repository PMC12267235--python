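import numpy as np
import pytest
from hypothesis import settings

from cutsync.io_formats import CutAnnotation, Recording

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def annotation():
    def make(pre="medium", post="medium", angle=10.0, film="filmA",
             cut="cut000", onset=5.0):
        return CutAnnotation(film_id=film, cut_id=cut, onset_s=onset,
                             pre_scale=pre, post_scale=post,
                             angle_delta_deg=angle)
    return make


@pytest.fixture
def small_recording(rng):
    """Three-channel, 20-s, 256-Hz noise recording."""
    samples = rng.standard_normal((3, 20 * 256)) * 15.0
    return Recording(subject_id="sub00", film_id="filmA",
                     sampling_rate=256.0,
                     electrode_labels=["Cz", "Oz", "P3"], samples=samples)
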