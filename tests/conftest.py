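import numpy as np
import pytest

from framecodec import PackingSpec, plan_codebook
from framecodec.packing import snap_codebook
from framecodec.synthetic import bandlimited_random_frames


@pytest.fixture
def rng():
    return np.random.default_rng(20170945)


@pytest.fixture
def codebook4():
    """Four planned carriers, snapped to a 160x160 grid (fringes periodic
    on the detector, so the codec round trip is leakage-free)."""
    cb = plan_codebook(
        PackingSpec(n_frames=4, filter_radius=0.03, baseband_radius=0.06)
    )
    return snap_codebook(cb, (160, 160))


@pytest.fixture
def frames4(rng, codebook4):
    """Four random frames band-limited inside the codebook's filter."""
    return bandlimited_random_frames(
        4, (160, 160), cutoff=0.8 * codebook4.filter_radius, rng=rng
    )
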